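"""From epoch labels to sleep periods, daily metrics, cycles and clock stats.

Sleep periods are detected automatically (the study context labels main
onset/offset transitions manually; here the rules are explicit and
reproducible): runs of sleep merged across short wake gaps form periods,
intra-period wake is WASO, periods shorter than 2 h are naps, and isolated
N1 runs surrounded by wake are ignored entirely. Sleep cycles follow the
REM-anchored definition: a cycle spans from the start of one REM period to
the start of the next, with at most five cycles retained per night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Hypnogram, ParameterError, SLEEP_STAGES

PERIOD_COLUMNS = [
    "onset", "offset", "kind", "duration_h", "waso_min", "unknown_min",
    "n1_min", "n2_min", "n3_min", "rem_min",
]

NAP_MAX_H = 2.0  # sleep periods shorter than this are naps


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _drop_isolated_n1(labels: np.ndarray) -> np.ndarray:
    """Treat N1 runs bordered by non-sleep on both sides as not sleep."""
    sleep = np.isin(labels, SLEEP_STAGES)
    out = sleep.copy()
    for s, e in _runs(labels == "N1"):
        left_sleep = s > 0 and sleep[s - 1]
        right_sleep = e < labels.size and sleep[e]
        if not left_sleep and not right_sleep:
            out[s:e] = False
    return out


def detect_sleep_periods(
    hypnogram: Hypnogram,
    gap_merge_min: float = 30.0,
    min_seed_run_min: float = 10.0,
) -> pd.DataFrame:
    """Detect sleep periods (main sleep and naps) in a pruned hypnogram.

    Sleep runs separated by wake gaps shorter than ``gap_merge_min`` are
    merged into one period; the intra-period wake is WASO. A period must
    contain at least one sleep run of ``min_seed_run_min`` minutes.
    Periods shorter than 2 h (including WASO) are classed as naps.
    """
    labels = hypnogram.labels
    epm = 60.0 / hypnogram.epoch_s  # epochs per minute
    sleep = _drop_isolated_n1(labels)
    runs = _runs(sleep)
    if not runs:
        return pd.DataFrame(columns=PERIOD_COLUMNS)

    gap_max = gap_merge_min * epm
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for r in runs[1:]:
        if r[0] - groups[-1][-1][1] < gap_max:
            groups[-1].append(r)
        else:
            groups.append([r])

    seed_epochs = min_seed_run_min * epm
    rows = []
    for g in groups:
        if max(e - s for s, e in g) < seed_epochs:
            continue
        s0, e1 = g[0][0], g[-1][1]
        seg = labels[s0:e1]
        seg_sleep = sleep[s0:e1]
        dur_h = (e1 - s0) / epm / 60.0
        onset = hypnogram.start + pd.Timedelta(seconds=s0 * hypnogram.epoch_s)
        offset = hypnogram.start + pd.Timedelta(seconds=e1 * hypnogram.epoch_s)
        waso = float(np.sum((seg == "WAKE") | ((seg == "N1") & ~seg_sleep)) / epm)
        rows.append(
            {
                "onset": onset,
                "offset": offset,
                "kind": "nap" if dur_h < NAP_MAX_H else "main",
                "duration_h": dur_h,
                "waso_min": waso,
                "unknown_min": float(np.sum(seg == "UNKNOWN") / epm),
                "n1_min": float(np.sum((seg == "N1") & seg_sleep) / epm),
                "n2_min": float(np.sum(seg == "N2") / epm),
                "n3_min": float(np.sum(seg == "N3") / epm),
                "rem_min": float(np.sum(seg == "REM") / epm),
            }
        )
    return pd.DataFrame(rows, columns=PERIOD_COLUMNS)


def daily_metrics(
    periods: pd.DataFrame,
    hypnogram: Hypnogram,
    boundary_hour: int = 12,
) -> pd.DataFrame:
    """Per-24-h day records: total sleep, naps, composition, unknown share.

    Days run from ``boundary_hour`` to ``boundary_hour`` (noon to noon by
    default, so main sleep periods are not split) and each period belongs
    to the day containing its onset. Total sleep includes WASO and naps;
    composition proportions are over {WASO, N1, N2, N3, REM} and sum to 1.
    """
    if not periods.empty:
        p = periods.sort_values("onset")
        if (p["onset"].values[1:] < p["offset"].values[:-1]).any():
            raise ParameterError("sleep periods overlap")
    rows = []
    for d, (t0, sl) in enumerate(hypnogram.day_slices(boundary_hour)):
        t1 = t0 + pd.Timedelta(days=1)
        if periods.empty:
            sel = periods
        else:
            sel = periods[(periods["onset"] >= t0) & (periods["onset"] < t1)]
        total_h = float(sel["duration_h"].sum()) if not sel.empty else 0.0
        comp = {}
        mins = {
            "waso": float(sel["waso_min"].sum()) if not sel.empty else 0.0,
            "n1": float(sel["n1_min"].sum()) if not sel.empty else 0.0,
            "n2": float(sel["n2_min"].sum()) if not sel.empty else 0.0,
            "n3": float(sel["n3_min"].sum()) if not sel.empty else 0.0,
            "rem": float(sel["rem_min"].sum()) if not sel.empty else 0.0,
        }
        denom = sum(mins.values())
        for k, v in mins.items():
            comp[f"prop_{k}"] = v / denom if denom > 0 else np.nan
        labels = hypnogram.labels[sl]
        rows.append(
            {
                "day_start": t0,
                "day_index": d,
                "total_sleep_h": total_h,
                "nap_count": int((sel["kind"] == "nap").sum()) if not sel.empty else 0,
                **comp,
                "unknown_fraction": float(np.mean(labels == "UNKNOWN")),
                "no_sleep": denom == 0,
            }
        )
    return pd.DataFrame(rows)


def segment_cycles(
    hypnogram: Hypnogram,
    onset=None,
    offset=None,
    rem_gap_merge_min: float = 10.0,
    max_cycles: int = 5,
) -> pd.DataFrame:
    """Sleep cycles of one main sleep period, REM-start to REM-start.

    REM runs separated by less than ``rem_gap_merge_min`` belong to one
    REM period. Cycle ``i`` spans from the start of REM period ``i`` to
    the start of REM period ``i+1``; at most ``max_cycles`` are retained.
    Returns an empty table when fewer than two REM periods exist.
    """
    i0 = hypnogram.epoch_at(onset) if onset is not None else 0
    if offset is not None:
        i1 = int((pd.Timestamp(offset) - hypnogram.start).total_seconds()
                 // hypnogram.epoch_s)
        i1 = min(i1, len(hypnogram))
    else:
        i1 = len(hypnogram)
    labels = hypnogram.labels[i0:i1]
    epm = 60.0 / hypnogram.epoch_s
    rem_runs = _runs(labels == "REM")
    if not rem_runs:
        return pd.DataFrame(
            columns=["cycle", "start", "end", "duration_h",
                     "prop_waso", "prop_n1", "prop_n2", "prop_n3", "prop_rem"]
        )
    gap_max = rem_gap_merge_min * epm
    rem_periods = [list(rem_runs[0])]
    for s, e in rem_runs[1:]:
        if s - rem_periods[-1][1] < gap_max:
            rem_periods[-1][1] = e
        else:
            rem_periods.append([s, e])
    if len(rem_periods) < 2:
        return pd.DataFrame(
            columns=["cycle", "start", "end", "duration_h",
                     "prop_waso", "prop_n1", "prop_n2", "prop_n3", "prop_rem"]
        )
    starts = [s for s, _ in rem_periods]
    rows = []
    for i in range(min(len(starts) - 1, max_cycles)):
        c0, c1 = starts[i], starts[i + 1]
        seg = labels[c0:c1]
        n = seg.size
        rows.append(
            {
                "cycle": i + 1,
                "start": hypnogram.start
                + pd.Timedelta(seconds=(i0 + c0) * hypnogram.epoch_s),
                "end": hypnogram.start
                + pd.Timedelta(seconds=(i0 + c1) * hypnogram.epoch_s),
                "duration_h": n / epm / 60.0,
                "prop_waso": float(np.mean(seg == "WAKE")),
                "prop_n1": float(np.mean(seg == "N1")),
                "prop_n2": float(np.mean(seg == "N2")),
                "prop_n3": float(np.mean(seg == "N3")),
                "prop_rem": float(np.mean(seg == "REM")),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CircularStats:
    mean_hour: float
    resultant_length: float
    n: int


def circular_histogram(
    clock_times_h, n_bins: int = 24
) -> tuple[np.ndarray, CircularStats]:
    """Normalised polar histogram and circular mean of hours-of-day.

    Returns ``(bin_masses, stats)`` where bin masses sum to 1 over
    ``n_bins`` equal bins of the 24-h dial, and the circular mean and
    resultant length come from unit-vector averaging.
    """
    t = np.asarray(clock_times_h, dtype=float)
    if t.size == 0:
        raise ParameterError("no event times given")
    if np.any((t < 0) | (t >= 24)):
        raise ParameterError("clock times must lie in [0, 24)")
    hist, _ = np.histogram(t, bins=n_bins, range=(0.0, 24.0))
    masses = hist / t.size
    theta = t / 24.0 * 2 * np.pi
    z = np.exp(1j * theta).mean()
    mean_h = float((np.angle(z) % (2 * np.pi)) / (2 * np.pi) * 24.0)
    return masses, CircularStats(mean_h, float(np.abs(z)), int(t.size))


def sleep_clock_times(periods: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Hours-of-day of main-sleep onsets and offsets, for polar histograms."""
    main = periods[periods["kind"] == "main"]
    onset_h = np.array(
        [ts.hour + ts.minute / 60 + ts.second / 3600 for ts in main["onset"]]
    )
    offset_h = np.array(
        [ts.hour + ts.minute / 60 + ts.second / 3600 for ts in main["offset"]]
    )
    return onset_h, offset_h
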