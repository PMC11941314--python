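from __future__ import annotations

from collections import Counter
from fractions import Fraction as F

import numpy as np
import pytest

from holterdyn import (
    EmptyInputError,
    LabeledCohort,
    SyntheticSpec,
    ValidationError,
    build_profile,
    classify,
    evaluate_cohort,
    extract_features,
    generate,
    generate_cohort,
    label_of,
    prototype_spec,
    write_beat_csv,
)
from holterdyn.prototypes import CLASS_NAMES
from holterdyn.ranges import RepetitionRange

SMALL_RANGES = (RepetitionRange("A", 10, 20), RepetitionRange("B", 21, 30))


class TestPrototypeSpec:
    def test_pacemaker_counts(self):
        spec = prototype_spec("pacemaker")
        assert {c for _, c in spec.target_pairs} == {1539, 1536, 1120, 1115, 2412, 2397}

    def test_normal_p1_pair_count(self):
        spec = prototype_spec("normal")
        assert sum(1 for _, c in spec.target_pairs if 1000 <= c <= 2000) == 11

    def test_chronic_p2_label_multiset(self):
        spec = prototype_spec("chronic")
        labels = Counter(
            label_of(hr) for hr, c in spec.target_pairs if 2001 <= c <= 3000
        )
        assert labels == Counter({70: 2, 75: 3, 80: 3, 85: 2})

    def test_labels_recoverable_from_hr(self):
        for cls in CLASS_NAMES:
            spec = prototype_spec(cls)
            hrs = [hr for hr, _ in spec.target_pairs]
            assert len(set(hrs)) == len(hrs)

    def test_unknown_class(self):
        with pytest.raises(ValidationError):
            prototype_spec("ventricular")


class TestSpecValidation:
    def test_overlapping_hr_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            SyntheticSpec(
                "custom",
                target_pairs=((70, 1500),),
                background_pairs=((70, 500),),
            )

    def test_target_count_outside_ranges(self):
        with pytest.raises(ValidationError, match="no analysis range"):
            SyntheticSpec("custom", target_pairs=((70, 500),))

    def test_background_count_inside_range(self):
        with pytest.raises(ValidationError, match="inside"):
            SyntheticSpec(
                "custom",
                target_pairs=((70, 1500),),
                background_pairs=((80, 1500),),
            )

    def test_jitter_margin(self):
        spec = SyntheticSpec("custom", target_pairs=((70, 1010), (80, 1990)))
        assert spec.jitter_margin() == 10
        with pytest.raises(ValidationError, match="jitter"):
            SyntheticSpec("custom", target_pairs=((70, 1010),), jitter=11)


class TestGenerate:
    def test_simple_pair(self):
        spec = SyntheticSpec(
            "custom", target_pairs=((60, 15),), ranges=SMALL_RANGES
        )
        rec = generate(spec)
        assert rec.series.n_beats == 15
        # Beat 0 at t=0; each later beat one RR (1 s at 60 bpm) after the last.
        assert rec.series.duration_h * 3600 == pytest.approx(14.0)

    def test_determinism_byte_identical(self, tmp_path):
        spec = prototype_spec("acute", seed=9)
        paths = []
        for i in range(2):
            rec = generate(spec)
            path = tmp_path / f"run{i}.csv"
            write_beat_csv(rec.series, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_seed_changes_order_not_profile(self):
        a = generate(prototype_spec("normal", seed=1))
        b = generate(prototype_spec("normal", seed=2))
        assert not np.array_equal(a.series.hr_bpm, b.series.hr_bpm)
        assert a.truth.entries == b.truth.entries

    def test_acute_round_trip_features(self):
        rec = generate(prototype_spec("acute", seed=5))
        feats = extract_features(build_profile(rec.series))
        assert feats.per_range["P1"].top_sum == F(6, 11)
        assert feats.per_range["P2"].top_sum == F(3, 4)

    def test_truth_matches_rebuilt_profile(self, class_name):
        rec = generate(prototype_spec(class_name, seed=13))
        rebuilt = build_profile(rec.series)
        assert rebuilt.entries == rec.truth.entries

    def test_round_trip_random_specs(self):
        # Parameter recovery on many random small specs (custom small ranges
        # keep the beat totals tiny).
        rng = np.random.default_rng(123)
        for _ in range(120):
            n_target = int(rng.integers(1, 8))
            n_bg = int(rng.integers(0, 4))
            hrs = rng.choice(np.arange(40, 160), size=n_target + n_bg, replace=False)
            target = tuple(
                (int(h), int(rng.integers(10, 31))) for h in hrs[:n_target]
            )
            background = tuple(
                (int(h), int(rng.integers(1, 10))) for h in hrs[n_target:]
            )
            jitter = int(rng.integers(0, 3))
            spec = SyntheticSpec(
                "custom",
                target_pairs=target,
                background_pairs=background,
                ranges=SMALL_RANGES,
                jitter=min(
                    jitter,
                    SyntheticSpec(
                        "custom", target_pairs=target, ranges=SMALL_RANGES
                    ).jitter_margin(),
                ),
                seed=int(rng.integers(0, 2**32)),
            )
            rec = generate(spec)
            rebuilt = build_profile(rec.series)
            assert rebuilt.entries == rec.truth.entries
            assert rebuilt.total_beats == rec.series.n_beats

    def test_jittered_counts_stay_in_range(self):
        spec = prototype_spec("chronic", jitter=10, seed=21)
        rec = generate(spec)
        target_hrs = {hr for hr, _ in spec.target_pairs}
        originals = dict(spec.target_pairs)
        moved = 0
        for e in rec.truth.entries:
            if e.hr_bpm in target_hrs:
                assert 1000 <= e.count <= 3000
                assert abs(e.count - originals[e.hr_bpm]) <= 10
                moved += int(e.count != originals[e.hr_bpm])
        assert moved > 0  # jitter actually perturbs something


class TestGenerateCohort:
    def test_zero_jitter_cohort_all_classified(self):
        recs = generate_cohort(2, jitter=0, seed=4)
        assert len(recs) == 8
        for rec in recs:
            diag = classify(extract_features(build_profile(rec.series)))
            assert diag.predicted == rec.gold

    def test_empty_cohort_error(self):
        with pytest.raises(EmptyInputError):
            generate_cohort(0)

    def test_reproducible(self):
        a = generate_cohort(1, seed=99)
        b = generate_cohort(1, seed=99)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.series.hr_bpm, rb.series.hr_bpm)
            assert np.array_equal(ra.series.time_s, rb.series.time_s)

    def test_excessive_jitter_refused(self):
        # The acute prototype holds a count of 2999 (margin 1 in [2001, 3000]).
        with pytest.raises(ValidationError, match="jitter"):
            generate_cohort(1, jitter=5, seed=0)

    def test_small_jitter_preserves_perfect_stats(self):
        recs = generate_cohort(1, jitter=1, seed=8)
        items = [
            (
                rec.series.recording_id,
                rec.gold,
                classify(extract_features(build_profile(rec.series))).predicted,
            )
            for rec in recs
        ]
        result = evaluate_cohort(LabeledCohort(items))
        for stats in result.per_class.values():
            assert stats["kappa"] == 1.0
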