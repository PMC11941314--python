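# holterdyn

Repetition-range probability analysis of Holter heart-rate dynamics.

From beat-level heart-rate data (or a precomputed frequency table), the
package:

1. builds a **repetition profile** — the number of times each distinct
   integer heart rate (bpm) occurs over the recording, tagged with its
   nearest-multiple-of-5 label;
2. filters profile entries by **repetition ranges** (default
   P1 = [1000, 2000], P2 = [2001, 3000] repetitions) and forms the
   **within-range probability distribution**: each qualifying
   (label, heart-rate, count) pair contributes equally, so a label's
   probability is its share of qualifying pairs;
3. computes the **summed-top-probabilities statistic** (sum of the two
   largest per-label probabilities) per range;
4. classifies the dynamics as **normal / chronic / acute / pacemaker** with
   inclusive rule bands on pair counts, top sums, frequency labels and a
   0.3 peak-probability threshold, producing a full per-predicate audit
   trail (no unique match → `unclassified`);
5. evaluates predictions against gold-standard diagnoses with per-class
   **sensitivity, specificity and Cohen's kappa** (one-vs-rest).

A seeded synthetic generator emits beat series whose repetition profiles
match configurable targets — including four bundled reference prototypes —
so the whole pipeline is testable without clinical data.

## CLI

```bash
# Profile one recording (beat CSV: header time_s,hr_bpm or time_s,rr_ms)
holterdyn profile recording.csv --out out/
holterdyn profile counts.csv --kind table --out out/   # header hr_bpm,count

# Classify with the default bands (or --bands mybands.yaml)
holterdyn diagnose recording.csv --out report.json
holterdyn diagnose counts.csv --kind table

# Synthetic data: one prototype recording, or a labelled cohort
holterdyn simulate chronic --seed 7 --out sim/
holterdyn simulate --cohort 5 --jitter 0 --seed 1 --out cohort/

# Score predictions against gold labels
holterdyn evaluate cohort/manifest.csv --out eval/
```

Manifest columns are either `recording_id,gold,predicted` or
`recording_id,path,gold` (predictions then computed from the referenced
beat CSVs). Every report embeds the tool version, seed and a configuration
hash. Useful flags: `--ranges P1:1000:2000,P2:2001:3000`, `--column-mode
rr_ms`, `--strict-duration` (require ≥ 21 h).

## Layout

```
src/holterdyn/
  io.py          beat/frequency-table CSV reading, RR→HR conversion
  profiles.py    repetition profiles, 5-bpm labeling
  ranges.py      range filtering, probability distributions, top sums
  bands.py       rule-band classifier + YAML/JSON band configuration
  metrics.py     sensitivity/specificity/kappa, confusion matrices
  prototypes.py  bundled reference prototype data
  synthetic.py   seeded beat-series generator and cohort builder
  cli.py         profile / diagnose / simulate / evaluate subcommands
```
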