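"""The inferential layer: IQR day categories, 48-h outcomes, risk models,
post-seizure comparisons and bootstrap contrasts.

Day-level sleep variables (total sleep duration and the per-state
proportions) are categorised per patient against the interquartile range
of that patient's seizure-free days: below the 25th percentile is
``decreased``, above the 75th is ``increased``, within (inclusive) is
``baseline``; days with a seizure are ``excluded`` from categorisation
but still provide outcomes for earlier days' windows. The outcome of a
categorized day is whether any seizure starts within the 48 h after the
day's 24-h measurement window, and the category effects are estimated by
the random-intercept logistic model in :mod:`hypnorisk.mixedlogit`, one
model per sleep variable with Bonferroni-corrected alpha 0.025 for the
two contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Hypnogram, ParameterError
from .mixedlogit import MixedLogit, MixedLogitResults

#: Day-table column for each modelled sleep variable.
RISK_VARIABLES = (
    "total_sleep_h", "prop_waso", "prop_n1", "prop_n2", "prop_n3", "prop_rem",
)


# -- seizure-state descriptives --------------------------------------------

def annotate_seizure_states(
    seizures: pd.DataFrame,
    hypnogram: Hypnogram,
    periods: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach the sleep-wake state at onset to each seizure.

    ``state`` is the label of the epoch containing the onset. ``in_sleep``
    is True for seizures in N1-REM *or* in wake epochs inside a sleep
    period (brief arousals count as sleep, recorded as state ``WASO``).
    Seizures in UNKNOWN epochs get ``in_sleep`` = NaN and are excluded
    from state statistics.
    """
    states, in_sleep = [], []
    for onset in pd.to_datetime(seizures["onset"]):
        idx = hypnogram.epoch_at(onset)  # raises outside the span
        st = hypnogram.labels[idx]
        sleeping: float | bool
        if st == "UNKNOWN":
            sleeping = np.nan
        elif st == "WAKE":
            sleeping = False
            if periods is not None and not periods.empty:
                inside = (
                    (periods["onset"] <= onset) & (onset < periods["offset"])
                ).any()
                if inside:
                    st, sleeping = "WASO", True
        else:
            sleeping = True
        states.append(st)
        in_sleep.append(sleeping)
    out = seizures.copy()
    out["state"] = states
    out["in_sleep"] = in_sleep
    return out


def seizure_rate_duration_by_state(
    annotated: pd.DataFrame,
    hypnogram: Hypnogram,
    periods: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-state time at risk, seizure rate (sz/h) and mean duration (min).

    WAKE means wake outside sleep periods; WASO is wake inside a period.
    States with zero recorded hours are omitted with a warning.
    """
    eph = 3600.0 / hypnogram.epoch_s
    labels = hypnogram.labels
    in_period = np.zeros(len(labels), dtype=bool)
    if periods is not None and not periods.empty:
        times = hypnogram.times
        for _, p in periods.iterrows():
            in_period |= (times >= p["onset"]) & (times < p["offset"])
    hours = {
        "WAKE": np.sum((labels == "WAKE") & ~in_period) / eph,
        "WASO": np.sum((labels == "WAKE") & in_period) / eph,
        "N1": np.sum(labels == "N1") / eph,
        "N2": np.sum(labels == "N2") / eph,
        "N3": np.sum(labels == "N3") / eph,
        "REM": np.sum(labels == "REM") / eph,
    }
    rows = []
    for state, h in hours.items():
        sel = annotated[annotated["state"] == state]
        if h <= 0:
            if len(sel):
                warnings.warn(f"state {state} has zero recorded hours; omitted")
            continue
        rows.append(
            {
                "state": state,
                "hours": float(h),
                "n_seizures": int(len(sel)),
                "rate_per_h": len(sel) / h,
                "mean_duration_min": float(sel["duration_s"].mean() / 60.0)
                if len(sel)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# -- IQR categorisation and outcomes ---------------------------------------

@dataclass
class CategoryThresholds:
    variable: str
    p25: float
    p75: float

    def __post_init__(self):
        if self.p25 > self.p75:
            raise ParameterError("p25 must not exceed p75")


def categorize_days(
    days: pd.DataFrame,
    variable: str,
    min_days: int = 8,
) -> tuple[pd.DataFrame, dict | CategoryThresholds]:
    """Label each day decreased / baseline / increased / excluded.

    Thresholds are the per-patient 25th and 75th percentiles of the
    variable over seizure-free days (linear interpolation between order
    statistics). Baseline is inclusive on both endpoints; seizure days are
    ``excluded`` and never shift the thresholds. Patients with fewer than
    ``min_days`` seizure-free days are skipped with a warning (category
    NaN).
    """
    if variable not in days.columns:
        raise ParameterError(f"unknown variable {variable!r}")
    out = days.copy()
    out["category"] = pd.Series(np.nan, index=out.index, dtype=object)

    def _one(group: pd.DataFrame):
        free = group[~group["seizure_any"].astype(bool)]
        vals = free[variable].dropna()
        if len(vals) < min_days:
            warnings.warn(
                f"patient skipped: only {len(vals)} seizure-free days"
            )
            return None
        p25, p75 = np.percentile(vals, [25, 75])
        cat = np.where(
            group["seizure_any"].astype(bool),
            "excluded",
            np.where(
                group[variable] < p25,
                "decreased",
                np.where(group[variable] > p75, "increased", "baseline"),
            ),
        )
        return cat, CategoryThresholds(variable, float(p25), float(p75))

    if "patient" in days.columns:
        thresholds: dict = {}
        for pt, group in out.groupby("patient"):
            res = _one(group)
            if res is None:
                continue
            cat, th = res
            out.loc[group.index, "category"] = cat
            thresholds[pt] = th
        return out, thresholds
    res = _one(out)
    if res is None:
        raise ParameterError(f"fewer than {min_days} seizure-free days")
    cat, th = res
    out["category"] = cat
    return out, th


def outcome_within_48h(
    days: pd.DataFrame,
    seizures: pd.DataFrame,
    window_h: float = 48.0,
) -> pd.Series:
    """Binary outcome: any seizure onset within 48 h after the day window.

    The window is ``(day_end, day_end + 48 h]`` where ``day_end`` is the
    end of the day's 24-h measurement window (half-open at the start,
    closed at +48 h).
    """
    def _one(day_rows: pd.DataFrame, sz: pd.DataFrame) -> np.ndarray:
        onsets = pd.to_datetime(sz["onset"]).to_numpy() if len(sz) else np.array(
            [], dtype="datetime64[ns]"
        )
        out = np.zeros(len(day_rows), dtype=int)
        for i, start in enumerate(pd.to_datetime(day_rows["day_start"])):
            w0 = start + pd.Timedelta(hours=24)
            w1 = w0 + pd.Timedelta(hours=window_h)
            out[i] = int(np.any((onsets > np.datetime64(w0)) &
                                (onsets <= np.datetime64(w1))))
        return out

    if "patient" in days.columns and "patient" in seizures.columns:
        res = pd.Series(0, index=days.index, dtype=int)
        for pt, group in days.groupby("patient"):
            sz = seizures[seizures["patient"] == pt]
            res.loc[group.index] = _one(group, sz)
        return res
    return pd.Series(_one(days, seizures), index=days.index, dtype=int)


# -- risk model bridge ------------------------------------------------------

def fit_seizure_risk(
    days: pd.DataFrame,
    covariates: list[str] | None = None,
    n_quad: int = 15,
    fix_sigma: float | None = None,
) -> MixedLogitResults:
    """Fit the per-variable risk model on a categorized day table.

    ``days`` needs columns ``patient``, ``category`` (decreased /
    baseline / increased; excluded and NaN rows are dropped) and
    ``outcome``. The fixed effects are an intercept plus indicator
    contrasts ``decreased`` and ``increased`` against baseline, with
    optional extra covariate columns; the random effect is the patient.
    """
    keep = days["category"].isin(["decreased", "baseline", "increased"])
    d = days.loc[keep]
    if d["patient"].nunique() < 2 and fix_sigma is None:
        raise ParameterError("need at least 2 patients for a random intercept")
    for cat in ("decreased", "increased"):
        if not (d["category"] == cat).any():
            raise ParameterError(f"no days in category {cat!r}")
    cols = [np.ones(len(d)),
            (d["category"] == "decreased").to_numpy(float),
            (d["category"] == "increased").to_numpy(float)]
    names = ["intercept", "decreased", "increased"]
    for cov in covariates or []:
        cols.append(d[cov].to_numpy(float))
        names.append(cov)
    X = np.column_stack(cols)
    model = MixedLogit(d["outcome"].to_numpy(), X, d["patient"].to_numpy(),
                       exog_names=names)
    return model.fit(n_quad=n_quad, fix_sigma=fix_sigma)


# -- post-seizure comparisons ----------------------------------------------

def classify_postseizure_days(days: pd.DataFrame) -> pd.Series:
    """Label days control / wake_sz / sleep_sz / excluded.

    Needs boolean columns ``seizure_wake`` and ``seizure_sleep`` (days
    with both kinds are excluded; days with seizures only in UNKNOWN
    epochs are excluded too if flagged via ``seizure_any``).
    """
    wake = days["seizure_wake"].astype(bool)
    sleep = days["seizure_sleep"].astype(bool)
    any_sz = days["seizure_any"].astype(bool) if "seizure_any" in days else (
        wake | sleep
    )
    lab = np.where(
        ~any_sz,
        "control",
        np.where(
            wake & sleep,
            "excluded",
            np.where(sleep, "sleep_sz", np.where(wake, "wake_sz", "excluded")),
        ),
    )
    return pd.Series(lab, index=days.index, dtype=object)


def add_seizure_day_flags(
    days: pd.DataFrame, annotated: pd.DataFrame
) -> pd.DataFrame:
    """Attach seizure_any / seizure_wake / seizure_sleep flags to day rows
    from an annotated seizure table (single patient)."""
    out = days.copy()
    onsets = pd.to_datetime(annotated["onset"])
    any_f, wake_f, sleep_f = [], [], []
    for start in pd.to_datetime(out["day_start"]):
        end = start + pd.Timedelta(hours=24)
        sel = annotated[(onsets >= start) & (onsets < end)]
        any_f.append(len(sel) > 0)
        wake_f.append(bool((sel["in_sleep"] == False).any()))  # noqa: E712
        sleep_f.append(bool((sel["in_sleep"] == True).any()))  # noqa: E712
    out["seizure_any"] = any_f
    out["seizure_wake"] = wake_f
    out["seizure_sleep"] = sleep_f
    return out


# -- repeated-measures ANOVA with GG correction and Dunnett contrasts -------

@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction."""

    F: float
    df1: float
    df2: float
    gg_epsilon: float
    pvalue: float
    n_subjects: int
    conditions: list[str]
    dunnett: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"RM-ANOVA over {self.conditions} (n={self.n_subjects})",
            f"  F({self.df1:.2f}, {self.df2:.2f}) = {self.F:.3f}, "
            f"GG epsilon = {self.gg_epsilon:.3f}, p = {self.pvalue:.4g}",
        ]
        if self.dunnett is not None:
            for _, r in self.dunnett.iterrows():
                lines.append(
                    f"  {r['comparison']}: diff = {r['mean_diff']:.4f}, "
                    f"t = {r['t']:.3f}, p = {r['pvalue']:.4g}"
                )
        return "\n".join(lines)


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    k = wide.shape[1]
    S = np.cov(wide, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2
    )
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _dunnett_pvalue(t_obs: float, m: int, df: int) -> float:
    """Two-sided many-to-one p-value under the equicorrelated (rho = 0.5)
    multivariate t; reduces to the paired t-test when m == 1."""
    t_obs = abs(float(t_obs))
    if m == 1:
        return float(2 * stats.t.sf(t_obs, df))
    R = np.full((m, m), 0.5)
    np.fill_diagonal(R, 1.0)
    mvt = stats.multivariate_t(loc=np.zeros(m), shape=R, df=df)
    rng = np.random.default_rng(20210605)
    inside = mvt.cdf(
        np.full(m, t_obs),
        lower_limit=np.full(m, -t_obs),
        random_state=rng,
        maxpts=100_000,
    )
    return float(np.clip(1.0 - inside, 0.0, 1.0))


def rm_anova(
    data: pd.DataFrame,
    bounded: bool = False,
    control: str | None = None,
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA across the columns of ``data``.

    Rows are subjects (patients), columns are conditions; rows with any
    missing condition are dropped listwise. ``bounded=True`` applies the
    arcsine-square-root transform appropriate for proportions before the
    ANOVA. When ``control`` names a column, two-sided Dunnett many-to-one
    comparisons of every other condition against it are included.
    """
    wide = data.dropna()
    if len(wide) < 3:
        raise ParameterError("need at least 3 subjects with all conditions")
    cols = list(wide.columns)
    X = wide.to_numpy(dtype=float)
    if bounded:
        if np.any((X < 0) | (X > 1)):
            raise ParameterError("bounded data must lie in [0, 1]")
        X = np.arcsin(np.sqrt(X))
    n, k = X.shape
    grand = X.mean()
    subj_means = X.mean(axis=1, keepdims=True)
    cond_means = X.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = X - subj_means - cond_means + grand
    ss_err = np.sum(resid**2)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_err <= 1e-300:
        F = 0.0 if ss_cond <= 1e-300 else np.inf
    else:
        F = (ss_cond / df1) / (ss_err / df2)
    eps = _gg_epsilon(X)
    p = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0

    dunnett_df = None
    if control is not None:
        if control not in cols:
            raise ParameterError(f"control condition {control!r} not present")
        others = [c for c in cols if c != control]
        m = len(others)
        rows = []
        ci = cols.index(control)
        for c in others:
            d = X[:, cols.index(c)] - X[:, ci]
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            rows.append(
                {
                    "comparison": f"{c} - {control}",
                    "mean_diff": float(d.mean()),
                    "t": float(t),
                    "pvalue": _dunnett_pvalue(t, m, n - 1),
                }
            )
        dunnett_df = pd.DataFrame(rows)
    return RMAnovaResult(
        F=float(F), df1=df1 * eps, df2=df2 * eps, gg_epsilon=eps,
        pvalue=p, n_subjects=n, conditions=cols, dunnett=dunnett_df,
    )


def label_days_after_seizure(days: pd.DataFrame) -> pd.Series:
    """Label each day by the *previous* day's seizure status.

    Useful for recovery analyses where the sleep of interest follows the
    seizure day: the first day of each patient gets NaN, and later days
    carry control / wake_sz / sleep_sz / excluded from the preceding day.
    """
    same_day = classify_postseizure_days(days)
    if "patient" in days.columns:
        return same_day.groupby(days["patient"]).shift(1)
    return same_day.shift(1)


def postseizure_condition_means(
    days: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Per-patient mean of ``variable`` in control / wake_sz / sleep_sz days.

    ``days`` needs ``patient`` and ``postseizure_label`` columns (see
    :func:`classify_postseizure_days`); excluded days are dropped. For
    recovery analyses that compare each day's sleep to the previous
    day's seizure status, pass a table whose label refers to the
    preceding 24 h (see :func:`label_days_after_seizure`).
    """
    keep = days[days["postseizure_label"].isin(["control", "wake_sz", "sleep_sz"])]
    wide = keep.pivot_table(
        index="patient", columns="postseizure_label", values=variable,
        aggfunc="mean",
    )
    return wide.reindex(columns=["control", "wake_sz", "sleep_sz"])


def rm_anova_postseizure(
    condition_means: pd.DataFrame, bounded: bool = False
) -> RMAnovaResult:
    """GG-corrected RM-ANOVA with Dunnett contrasts vs the control days."""
    return rm_anova(condition_means, bounded=bounded, control="control")


# -- bootstrap --------------------------------------------------------------

@dataclass
class BootstrapResult:
    mean_difference: float
    ci_lower: float
    ci_upper: float
    distribution: np.ndarray

    def summary(self) -> str:
        return (
            f"mean difference {self.mean_difference:.4f}, "
            f"95% CI [{self.ci_lower:.4f}, {self.ci_upper:.4f}] "
            f"({self.distribution.size} resamples)"
        )


def bootstrap_mean_difference(
    group_a,
    group_b,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap sampling distribution of mean(A) - mean(B).

    Resamples within each group with replacement; the 95% CI is the
    2.5/97.5 percentile interval of the resampled differences.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap resamples; CI is unstable")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    dist = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return BootstrapResult(float(a.mean() - b.mean()), float(lo), float(hi), dist)
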