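import numpy as np
import pytest

from bbtval.cycle_model import Cycle, DailyRecord, LHResult


def build_cycle(temps, positives=(), negatives=(), cycle_id="C1", woman_id="W1"):
    """Cycle from a temperature list (None = missing) and LH-positive day indices."""
    records = []
    for d, t in enumerate(temps, start=1):
        if d in positives:
            lh = LHResult.POSITIVE
        elif d in negatives:
            lh = LHResult.NEGATIVE
        else:
            lh = LHResult.NOT_TESTED
        records.append(DailyRecord(d, None if t is None else float(t), lh))
    return Cycle(cycle_id=cycle_id, woman_id=woman_id, records=tuple(records))


@pytest.fixture
def make_cycle():
    return build_cycle


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
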