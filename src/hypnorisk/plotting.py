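"""Quick-look plots: hypnograms and circadian polar histograms."""

from __future__ import annotations

import numpy as np

from .core import Hypnogram

_STAGE_Y = {"N3": 0, "N2": 1, "N1": 2, "REM": 3, "WAKE": 4}


def plot_hypnogram(hypnogram: Hypnogram, ax=None):
    """Step plot of stage depth over time; UNKNOWN epochs are gaps."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    y = np.array([_STAGE_Y.get(l, np.nan) for l in hypnogram.labels], dtype=float)
    ax.step(hypnogram.times, y, where="post", lw=0.8)
    ax.set_yticks(list(_STAGE_Y.values()), list(_STAGE_Y.keys()))
    ax.set_xlabel("time")
    return ax


def plot_polar_histogram(bin_masses: np.ndarray, ax=None, label=None, color=None):
    """Normalised 24-h polar histogram (midnight at the top, clockwise)."""
    import matplotlib.pyplot as plt

    n = len(bin_masses)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.arange(n) / n * 2 * np.pi
    ax.bar(theta, bin_masses, width=2 * np.pi / n, align="edge",
           alpha=0.6, label=label, color=color)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False),
                  [f"{h:02d}:00" for h in range(0, 24, 3)])
    return ax
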