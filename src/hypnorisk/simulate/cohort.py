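"""Cohort assembly: multi-patient bundles of hypnograms, seizures and truth.

Per-patient day counts default to the scale of the study cohort this
package targets (10 patients, 224-709 analysed days each, 4340 days in
total). Two fidelity levels are available: :func:`make_cohort` produces
epoch-level hypnograms with seizures placed into true sleep-wake states,
while :func:`simulate_feature_matrix` draws per-state Gaussian feature
vectors directly (the fast path for classifier tests).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import Hypnogram, ParameterError, seizures_to_csv
from .architecture import EPOCHS_PER_DAY, apply_dropout, generate_hypnogram
from .params import SeizureRiskParams, SleepArchitectureParams
from .risk import generate_seizures

#: Analysed-day and seizure counts at the cohort scale the simulator targets.
COHORT_DAY_COUNTS: tuple[int, ...] = (348, 607, 382, 355, 224, 318, 398, 709, 534, 465)
COHORT_SEIZURE_COUNTS: tuple[int, ...] = (151, 326, 71, 467, 204, 545, 467, 13, 500, 77)


@dataclass
class PatientBundle:
    """Everything generated for one synthetic patient."""

    patient_id: int
    hypnogram_true: Hypnogram
    hypnogram_observed: Hypnogram
    dropout_mask: np.ndarray
    artifact_mask: np.ndarray
    periods_truth: pd.DataFrame
    cycles_truth: pd.DataFrame
    day_truth: pd.DataFrame
    seizures: pd.DataFrame


def _day_truth_table(hyp: Hypnogram, periods: pd.DataFrame) -> pd.DataFrame:
    """True per-day total sleep and IQR category from the truth periods."""
    slices = hyp.day_slices(boundary_hour=12)
    rows = []
    for d, (t0, _) in enumerate(slices):
        t1 = t0 + pd.Timedelta(days=1)
        sel = periods[(periods["onset"] >= t0) & (periods["onset"] < t1)]
        total_h = (
            (sel["offset"] - sel["onset"]).dt.total_seconds().sum() / 3600.0
        )
        rows.append({"day_start": t0, "day_index": d, "total_sleep_h": total_h})
    df = pd.DataFrame(rows)
    p25, p75 = np.percentile(df["total_sleep_h"], [25, 75])
    cat = np.where(
        df["total_sleep_h"] < p25,
        "decreased",
        np.where(df["total_sleep_h"] > p75, "increased", "baseline"),
    )
    df["category"] = cat
    return df


def make_cohort(
    n_patients: int,
    seed: int,
    days_per_patient: int | list[int] | None = None,
    arch_params: SleepArchitectureParams | None = None,
    risk_params: SeizureRiskParams | None = None,
    out_dir: str | os.PathLike | None = None,
) -> list[PatientBundle]:
    """Generate a multi-patient cohort with known ground truth.

    When ``days_per_patient`` is None, per-patient day counts are taken
    from :data:`COHORT_DAY_COUNTS` (cycled if ``n_patients`` exceeds ten).
    If ``out_dir`` is given, each patient's observed hypnogram, seizure
    catalogue and true day table are written as CSV under ``p<ID>/``.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    arch = arch_params or SleepArchitectureParams()
    risk = risk_params or SeizureRiskParams()
    if days_per_patient is None:
        days = [COHORT_DAY_COUNTS[i % len(COHORT_DAY_COUNTS)] for i in range(n_patients)]
    elif np.isscalar(days_per_patient):
        days = [int(days_per_patient)] * n_patients
    else:
        days = list(days_per_patient)
        if len(days) != n_patients:
            raise ParameterError("days_per_patient list must match n_patients")

    root = np.random.default_rng(seed)
    bundles = []
    for pt in range(n_patients):
        s_hyp, s_sz = root.integers(0, 2**31 - 1, size=2)
        hyp, truth = generate_hypnogram(arch, days[pt], seed=int(s_hyp))
        observed = apply_dropout(hyp, truth["dropout_mask"])
        day_truth = _day_truth_table(hyp, truth["periods"])
        seizures = generate_seizures(
            day_truth,
            risk,
            seed=int(s_sz),
            hypnogram=hyp,
            periods=truth["periods"],
        )
        sz_days = {
            int((pd.Timestamp(t) - day_truth["day_start"].iloc[0]).days)
            for t in seizures["onset"]
        }
        day_truth["seizure_any"] = day_truth["day_index"].isin(sz_days)
        bundles.append(
            PatientBundle(
                patient_id=pt,
                hypnogram_true=hyp,
                hypnogram_observed=observed,
                dropout_mask=truth["dropout_mask"],
                artifact_mask=truth["artifact_mask"],
                periods_truth=truth["periods"],
                cycles_truth=truth["cycles"],
                day_truth=day_truth,
                seizures=seizures,
            )
        )

    if out_dir is not None:
        for b in bundles:
            pdir = os.path.join(out_dir, f"p{b.patient_id:02d}")
            os.makedirs(pdir, exist_ok=True)
            b.hypnogram_observed.to_csv(os.path.join(pdir, "hypnogram.csv"))
            b.hypnogram_true.to_csv(os.path.join(pdir, "hypnogram_true.csv"))
            seizures_to_csv(b.seizures, os.path.join(pdir, "seizures.csv"))
            b.day_truth.to_csv(os.path.join(pdir, "days_truth.csv"), index=False)
    return bundles


# Feature-level fast path ---------------------------------------------------

from ..features import FEATURE_NAMES  # noqa: E402  (avoid cycle at module top)

#: Which canonical features carry class signal in the fast path (the five
#: relative powers, broadband entropy, and the two frequency statistics).
_INFORMATIVE = (
    "rel_power_delta",
    "rel_power_theta",
    "rel_power_alpha",
    "rel_power_low_beta",
    "rel_power_high_beta",
    "spectral_entropy_broadband",
    "mean_dominant_freq",
    "spectral_median_freq",
)

_STATE_ORDER = ("WAKE", "N1", "N2", "N3", "REM")


def simulate_feature_matrix(
    labels: np.ndarray,
    separation: float = 2.0,
    seed: int = 0,
    informative: tuple[str, ...] = _INFORMATIVE,
) -> pd.DataFrame:
    """Draw 21-dim Gaussian feature vectors for each labelled epoch.

    Informative features get state-specific means scaled by ``separation``
    (class separability in SD units); the rest are standard-normal noise.
    UNKNOWN epochs give NaN rows. The state-mean pattern is a fixed
    constant so the same separation always means the same problem.
    """
    rng = np.random.default_rng(seed)
    pattern = np.random.default_rng(20200101).standard_normal(
        (len(_STATE_ORDER), len(informative))
    )
    labels = np.asarray(labels, dtype="U7")
    X = rng.standard_normal((labels.size, len(FEATURE_NAMES)))
    cols = list(FEATURE_NAMES)
    for si, state in enumerate(_STATE_ORDER):
        sel = labels == state
        if not sel.any():
            continue
        for fi, feat in enumerate(informative):
            X[sel, cols.index(feat)] += separation * pattern[si, fi]
    X[labels == "UNKNOWN"] = np.nan
    return pd.DataFrame(X, columns=cols)
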