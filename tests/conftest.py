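from __future__ import annotations

import pytest

from holterdyn import prototype_profile
from holterdyn.prototypes import CLASS_NAMES

# Published per-class results frozen as test expectations:
# qualifying-pair tallies and two-decimal top sums per range.
EXPECTED_N_PAIRS = {
    "normal": {"P1": 11, "P2": 1},
    "chronic": {"P1": 23, "P2": 10},
    "acute": {"P1": 11, "P2": 4},
    "pacemaker": {"P1": 4, "P2": 2},
}
EXPECTED_TOP_SUM = {
    "normal": {"P1": 0.45, "P2": 1.0},
    "chronic": {"P1": 0.43, "P2": 0.6},
    "acute": {"P1": 0.54, "P2": 0.75},
    "pacemaker": {"P1": 0.5, "P2": 1.0},
}


@pytest.fixture(params=CLASS_NAMES)
def class_name(request):
    return request.param


@pytest.fixture
def profiles():
    return {cls: prototype_profile(cls) for cls in CLASS_NAMES}


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
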