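"""Day-level seizure generation and fast day-record simulation.

The generating model for seizure days is a random-intercept logistic
regression on the day's sleep category: ``logit(p) = b0_i +
log(or_decreased) I(dec) + log(or_increased) I(inc)`` with patient
intercepts ``b0_i ~ N(baseline_log_odds, sd^2)``. Seizure times within a
day are placed into sleep-wake states by configurable weights, or by a
two-component von Mises clock-time mixture when no hypnogram is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from ..core import Hypnogram, ParameterError
from .params import SeizureRiskParams

_CATEGORIES = ("decreased", "baseline", "increased")


def _category_effects(params: SeizureRiskParams) -> dict[str, float]:
    return {
        "decreased": float(np.log(params.or_decreased)),
        "baseline": 0.0,
        "increased": float(np.log(params.or_increased)),
    }


def simulate_risk_days(
    n_patients: int,
    n_days: int,
    params: SeizureRiskParams,
    seed: int,
    category_probs: tuple[float, float, float] = (0.25, 0.5, 0.25),
) -> pd.DataFrame:
    """Fast day-level simulation: categories and seizure-day indicators.

    Categories are drawn i.i.d. with the IQR-rule frequencies (25/50/25 by
    default); outcomes follow the generating logit. Returns a DataFrame
    with columns ``patient, day, category, outcome``.
    """
    rng = np.random.default_rng(seed)
    eff = _category_effects(params)
    b0 = rng.normal(params.baseline_log_odds, params.random_intercept_sd, n_patients)
    cats = rng.choice(_CATEGORIES, size=(n_patients, n_days), p=list(category_probs))
    eta = b0[:, None] + np.vectorize(eff.get)(cats)
    y = rng.random((n_patients, n_days)) < expit(eta)
    return pd.DataFrame(
        {
            "patient": np.repeat(np.arange(n_patients), n_days),
            "day": np.tile(np.arange(n_days), n_patients),
            "category": cats.ravel(),
            "outcome": y.ravel().astype(int),
        }
    )


def _place_in_state(
    state: str,
    day_slice: slice,
    hypnogram: Hypnogram,
    periods: pd.DataFrame | None,
    rng: np.random.Generator,
):
    """Pick an epoch of ``state`` within the day; returns its index or None.

    ``WASO`` means a WAKE epoch inside a sleep period, which requires the
    period table.
    """
    labels = hypnogram.labels[day_slice]
    base = day_slice.start
    if state == "WASO":
        if periods is None or periods.empty:
            return None
        in_period = np.zeros(labels.size, dtype=bool)
        times = hypnogram.times[day_slice]
        for _, p in periods.iterrows():
            in_period |= (times >= p["onset"]) & (times < p["offset"])
        idx = np.flatnonzero((labels == "WAKE") & in_period)
    else:
        idx = np.flatnonzero(labels == state)
        if state == "WAKE" and periods is not None and not periods.empty:
            times = hypnogram.times[day_slice]
            in_period = np.zeros(labels.size, dtype=bool)
            for _, p in periods.iterrows():
                in_period |= (times >= p["onset"]) & (times < p["offset"])
            idx = np.flatnonzero((labels == "WAKE") & ~in_period)
    if idx.size == 0:
        return None
    return base + int(rng.choice(idx))


def generate_seizures(
    day_truth: pd.DataFrame,
    params: SeizureRiskParams,
    seed: int,
    hypnogram: Hypnogram | None = None,
    periods: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Seizure events for one patient from categorized day ground truth.

    ``day_truth`` needs ``day_start`` (timestamp) and ``category`` columns.
    With a hypnogram, event times are drawn from epochs of the state chosen
    by ``state_placement_weights``; otherwise clock times come from a
    two-component von Mises mixture anchored at typical sleep onset (23:00)
    and offset (08:00) times.

    Returns a DataFrame with ``onset, duration_s, state_truth`` rows.
    """
    params.validate()
    if day_truth.empty or day_truth["category"].isna().all():
        raise ParameterError("no categorized days in ground truth")
    rng = np.random.default_rng(seed)
    eff = _category_effects(params)
    b0 = rng.normal(params.baseline_log_odds, params.random_intercept_sd)

    states = list(params.state_placement_weights)
    weights = np.array(
        [params.state_placement_weights[s] for s in states], dtype=float
    )
    weights = weights / weights.sum()

    rows = []
    for _, day in day_truth.iterrows():
        p = expit(b0 + eff[day["category"]])
        if rng.random() >= p:
            continue
        n_events = 1 + rng.poisson(0.5)
        day_start = pd.Timestamp(day["day_start"])
        for _ in range(n_events):
            state = str(rng.choice(states, p=weights))
            onset = None
            if hypnogram is not None:
                i0 = max(
                    0,
                    int(
                        (day_start - hypnogram.start).total_seconds()
                        // hypnogram.epoch_s
                    ),
                )
                i1 = min(len(hypnogram), i0 + 86400 // hypnogram.epoch_s)
                epoch = _place_in_state(
                    state, slice(i0, i1), hypnogram, periods, rng
                )
                if epoch is not None:
                    onset = hypnogram.start + pd.Timedelta(
                        seconds=epoch * hypnogram.epoch_s
                        + rng.uniform(0, hypnogram.epoch_s)
                    )
            if onset is None:
                # von Mises clock-time mixture at sleep onset/offset anchors
                anchor = 23.0 if rng.random() < 0.5 else 8.0
                clock = (
                    rng.vonmises(anchor / 24.0 * 2 * np.pi - np.pi, 4.0) + np.pi
                ) / (2 * np.pi) * 24.0
                onset = day_start.normalize() + pd.Timedelta(hours=float(clock))
                state = "unplaced"
            duration = float(
                np.exp(
                    rng.normal(
                        params.seizure_duration_log_mean,
                        params.seizure_duration_log_sd,
                    )
                )
            )
            rows.append(
                {"onset": onset, "duration_s": duration, "state_truth": state}
            )
    out = pd.DataFrame(rows, columns=["onset", "duration_s", "state_truth"])
    return out.sort_values("onset").reset_index(drop=True)


# Day-record summary simulation -------------------------------------------

_PROP_MEANS = {"waso": 0.10, "n1": 0.08, "n2": 0.45, "n3": 0.20, "rem": 0.17}
_PROP_CONC = 120.0  # Dirichlet concentration: day-to-day composition noise


def simulate_day_records(
    n_patients: int,
    n_days: int,
    params: SeizureRiskParams,
    seed: int,
    duration_mean: float = 9.5,
    duration_between_sd: float = 0.6,
    duration_within_sd: float = 0.9,
    start: str | pd.Timestamp = "2020-01-01 12:00:00",
) -> pd.DataFrame:
    """Day-level sleep metrics with seizures and post-seizure carry-over.

    Emulates the downstream day table without epoch-level detail: daily
    total sleep is Gaussian around a patient mean, composition is
    Dirichlet, seizure days follow the generating logit on the duration
    category, and the day after a seizure receives the configured additive
    shifts (longer sleep; more WASO and less REM after sleep seizures).
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    eff = _category_effects(params)
    w = params.state_placement_weights
    total_w = sum(w.values())
    p_sleep = sum(w.get(s, 0.0) for s in ("N1", "N2", "N3", "REM", "WASO")) / total_w

    alpha = np.array([_PROP_MEANS[k] for k in ("waso", "n1", "n2", "n3", "rem")])
    alpha = alpha * _PROP_CONC
    q3 = 0.6744897501960817  # z-score of the 75th percentile
    frames = []
    day_starts = start + pd.to_timedelta(np.arange(n_days), unit="D")
    for pt in range(n_patients):
        mu = rng.normal(duration_mean, duration_between_sd)
        b0 = rng.normal(params.baseline_log_odds, params.random_intercept_sd)
        dur = rng.normal(mu, duration_within_sd, n_days)
        props = rng.dirichlet(alpha, n_days)
        u_outcome = rng.random(n_days)
        n_events = 1 + rng.poisson(0.5, n_days)
        n_sleep_ev = rng.binomial(n_events, p_sleep)

        y = np.zeros(n_days, dtype=bool)
        sz_wake = np.zeros(n_days, dtype=bool)
        sz_sleep = np.zeros(n_days, dtype=bool)
        cat = np.empty(n_days, dtype=object)
        prev_effect = None  # post-seizure shift pending for the next day
        for d in range(n_days):
            if prev_effect is not None:
                e = params.postseizure_effects[prev_effect]
                dur[d] += e["duration_h"]
                p = props[d]
                p[0] = max(p[0] + e["waso_prop"], 0.005)
                p[4] = max(p[4] + e["rem_prop"], 0.005)
                p[2] = max(1.0 - p[0] - p[1] - p[3] - p[4], 0.005)
                props[d] = p / p.sum()
            z = (dur[d] - mu) / duration_within_sd
            cat[d] = (
                "decreased" if z < -q3 else "increased" if z > q3 else "baseline"
            )
            y[d] = u_outcome[d] < expit(b0 + eff[cat[d]])
            prev_effect = None
            if y[d]:
                sz_sleep[d] = n_sleep_ev[d] > 0
                sz_wake[d] = n_sleep_ev[d] < n_events[d]
                prev_effect = "sleep_sz" if sz_sleep[d] else "wake_sz"
        frames.append(
            pd.DataFrame(
                {
                    "patient": pt,
                    "day_index": np.arange(n_days),
                    "day_start": day_starts,
                    "total_sleep_h": dur,
                    "prop_waso": props[:, 0],
                    "prop_n1": props[:, 1],
                    "prop_n2": props[:, 2],
                    "prop_n3": props[:, 3],
                    "prop_rem": props[:, 4],
                    "category_truth": cat,
                    "seizure_any": y,
                    "seizure_wake": sz_wake,
                    "seizure_sleep": sz_sleep,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
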