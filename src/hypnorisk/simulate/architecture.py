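"""Hypnogram generation: nights built from shrinking sleep cycles.

Each simulated night is assembled from ``n_cycles`` cycles whose durations
decay geometrically and whose stage mixtures follow the configured
trajectories (N3 front-loaded, REM back-loaded). Wake-after-sleep-onset is
sprinkled into non-REM portions of the night as short arousal runs; naps
shorter than 2 h are placed in the afternoon; telemetry dropouts and
artefact flags are drawn independently per epoch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import EPOCH_S, Hypnogram, ParameterError
from .params import SleepArchitectureParams

EPOCHS_PER_DAY = 86400 // EPOCH_S  # 2880
EPOCHS_PER_HOUR = 3600 // EPOCH_S  # 120


def _night_labels(params: SleepArchitectureParams, n_sleep_epochs: int,
                  rng: np.random.Generator):
    """Build one night's label array and its ground-truth cycle table.

    Cycles are laid out as N1 | N2 | N3 | N2 | REM; cycle lengths follow the
    geometric decay, rescaled so the night has exactly ``n_sleep_epochs``
    epochs. Returns ``(labels, cycles)`` where ``cycles`` is a list of
    ``(start, end, rem_epochs, n3_epochs)`` in night-relative epochs.
    """
    k = params.n_cycles
    base = params.cycle1_duration * params.cycle_duration_decay ** np.arange(k)
    counts = np.floor(base / base.sum() * n_sleep_epochs).astype(int)
    counts[-1] += n_sleep_epochs - counts.sum()
    props = params.cycle_proportions()  # (k, 4): N1 N2 N3 REM

    labels = []
    cycles = []
    pos = 0
    for c in range(k):
        n = counts[c]
        n1 = int(round(props[c, 0] * n))
        n3 = int(round(props[c, 2] * n))
        rem = max(1, int(round(props[c, 3] * n)))  # REM appears in every cycle
        n2 = n - n1 - n3 - rem
        if n2 < 0:
            rem += n2
            n2 = 0
        half = n2 // 2
        labels.extend(
            ["N1"] * n1 + ["N2"] * half + ["N3"] * n3 + ["N2"] * (n2 - half)
            + ["REM"] * rem
        )
        cycles.append((pos, pos + n, rem, n3))
        pos += n
    return np.asarray(labels, dtype="U7"), cycles


def _insert_waso(labels: np.ndarray, waso_fraction: float,
                 rng: np.random.Generator) -> None:
    """Replace non-REM sleep epochs with short WAKE arousal runs, in place."""
    n_target = int(round(waso_fraction * labels.size))
    if n_target == 0:
        return
    eligible = np.flatnonzero((labels != "REM"))
    # keep the ends of the night asleep so onset/offset stay well defined
    eligible = eligible[(eligible > 4) & (eligible < labels.size - 5)]
    rng.shuffle(eligible)
    placed = 0
    for start in eligible:
        if placed >= n_target:
            break
        if labels[start] == "WAKE":
            continue
        run = int(rng.integers(1, 9))  # 0.5 to 4 min arousals
        run = min(run, n_target - placed)
        for i in range(start, min(start + run, labels.size - 5)):
            if labels[i] == "REM":
                break
            if labels[i] != "WAKE":
                labels[i] = "WAKE"
                placed += 1


def generate_hypnogram(
    params: SleepArchitectureParams,
    n_days: int,
    seed: int,
    start: str | pd.Timestamp = "2020-01-01 12:00:00",
) -> tuple[Hypnogram, dict]:
    """Simulate ``n_days`` of ground-truth 30-s epoch labels.

    The recording starts at noon and covers ``n_days`` noon-to-noon days.

    Returns
    -------
    hypnogram : Hypnogram
        True stage labels (no UNKNOWN; dropouts are returned as masks).
    truth : dict
        ``periods``: DataFrame of true sleep periods (onset, offset, kind,
        day_index); ``cycles``: DataFrame of true cycle boundaries with
        per-cycle REM/N3 proportions; ``dropout_mask`` / ``artifact_mask``:
        boolean per-epoch arrays; ``params``: the parameters used.
    """
    if n_days < 1:
        raise ParameterError("n_days must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    n_epochs = n_days * EPOCHS_PER_DAY
    labels = np.full(n_epochs, "WAKE", dtype="U7")

    period_rows = []
    cycle_rows = []
    last_end = 0
    for d in range(n_days):
        onset_clock = rng.normal(
            params.mean_sleep_onset_clock_time, params.onset_jitter_sd
        )
        onset_h_after_noon = (onset_clock - 12.0) % 24.0
        duration = float(
            np.clip(
                rng.normal(
                    params.night_sleep_duration_mean, params.night_sleep_duration_sd
                ),
                4.0,
                13.0,
            )
        )
        onset_idx = d * EPOCHS_PER_DAY + int(round(onset_h_after_noon * EPOCHS_PER_HOUR))
        onset_idx = max(onset_idx, last_end + EPOCHS_PER_HOUR)  # no overlap
        n_sleep = int(round(duration * EPOCHS_PER_HOUR))
        end_idx = min(onset_idx + n_sleep, n_epochs)
        n_sleep = end_idx - onset_idx
        if n_sleep < params.n_cycles * 4:
            continue  # truncated at the recording edge; skip this night

        night, cycles = _night_labels(params, n_sleep, rng)
        _insert_waso(night, params.waso_fraction, rng)
        labels[onset_idx:end_idx] = night
        last_end = end_idx
        period_rows.append(
            {
                "onset": start + pd.Timedelta(seconds=onset_idx * EPOCH_S),
                "offset": start + pd.Timedelta(seconds=end_idx * EPOCH_S),
                "kind": "main",
                "day_index": d,
            }
        )
        for ci, (c0, c1, rem, n3) in enumerate(cycles):
            n_c = c1 - c0
            cycle_rows.append(
                {
                    "day_index": d,
                    "cycle": ci + 1,
                    "start_epoch": onset_idx + c0,
                    "end_epoch": onset_idx + c1,
                    "duration_h": n_c / EPOCHS_PER_HOUR,
                    "rem_prop": rem / n_c,
                    "n3_prop": n3 / n_c,
                }
            )

        # afternoon naps for the *next* day window (daytime of day d+1)
        n_naps = rng.poisson(params.nap_rate_per_day)
        nap_lo = d * EPOCHS_PER_DAY + int(1.0 * EPOCHS_PER_HOUR)
        nap_hi = onset_idx - int(1.5 * EPOCHS_PER_HOUR)
        for _ in range(n_naps):
            dur_h = rng.uniform(*params.nap_duration_range)
            n_nap = max(2, int(round(dur_h * EPOCHS_PER_HOUR)))
            if nap_hi - n_nap <= nap_lo:
                continue
            s = int(rng.integers(nap_lo, nap_hi - n_nap))
            seg = labels[s - 2 : s + n_nap + 2]
            if np.any(seg != "WAKE"):
                continue  # would touch existing sleep; skip
            nap = np.full(n_nap, "N2", dtype="U7")
            nap[0] = "N1"
            labels[s : s + n_nap] = nap
            period_rows.append(
                {
                    "onset": start + pd.Timedelta(seconds=s * EPOCH_S),
                    "offset": start + pd.Timedelta(seconds=(s + n_nap) * EPOCH_S),
                    "kind": "nap",
                    "day_index": d,
                }
            )

    dropout = rng.random(n_epochs) < params.dropout_rate
    artifact = rng.random(n_epochs) < params.artifact_rate

    hyp = Hypnogram(labels, start)
    periods = pd.DataFrame(
        period_rows, columns=["onset", "offset", "kind", "day_index"]
    ).sort_values("onset").reset_index(drop=True)
    cycles_df = pd.DataFrame(
        cycle_rows,
        columns=[
            "day_index", "cycle", "start_epoch", "end_epoch",
            "duration_h", "rem_prop", "n3_prop",
        ],
    )
    truth = {
        "periods": periods,
        "cycles": cycles_df,
        "dropout_mask": dropout,
        "artifact_mask": artifact,
        "params": params,
    }
    return hyp, truth


def apply_dropout(hypnogram: Hypnogram, dropout_mask: np.ndarray) -> Hypnogram:
    """Observed hypnogram: epochs lost to telemetry dropout become UNKNOWN."""
    if dropout_mask.shape != hypnogram.labels.shape:
        raise ParameterError("dropout mask misaligned with hypnogram")
    labels = hypnogram.labels.copy()
    labels[dropout_mask] = "UNKNOWN"
    return Hypnogram(labels, hypnogram.start, hypnogram.epoch_s)
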