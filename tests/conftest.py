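import numpy as np
import pandas as pd
import pytest

from hypnorisk.core import Hypnogram, labels_from_runs
from hypnorisk.simulate import (
    SleepArchitectureParams,
    generate_hypnogram,
)


@pytest.fixture(scope="session")
def default_arch():
    return SleepArchitectureParams()


@pytest.fixture(scope="session")
def long_hypnogram(default_arch):
    """200 simulated days with ground truth, reused across trend tests."""
    return generate_hypnogram(default_arch, 200, seed=2020)


@pytest.fixture(scope="session")
def month_hypnogram(default_arch):
    """30 simulated days with ground truth, for analytics recovery tests."""
    return generate_hypnogram(default_arch, 30, seed=77)


def make_hypnogram(runs, start="2020-01-01 12:00:00"):
    """Toy hypnogram from (label, n_epochs) run-length pairs."""
    return Hypnogram(labels_from_runs(runs), start)


@pytest.fixture
def toy_night():
    """One 24-h day: wake, a 6-h night with two 10-min arousals, wake."""
    runs = [
        ("WAKE", 1320),  # noon to 23:00
        ("N2", 240),     # 2 h
        ("WAKE", 20),    # 10 min arousal
        ("N3", 240),     # 2 h
        ("WAKE", 20),    # 10 min arousal
        ("REM", 200),    # 100 min
    ]
    used = sum(n for _, n in runs)
    runs.append(("WAKE", 2880 - used))
    return make_hypnogram(runs)
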