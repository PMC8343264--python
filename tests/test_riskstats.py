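import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypnorisk.core import Hypnogram, ParameterError, labels_from_runs
from hypnorisk.riskstats import (
    annotate_seizure_states,
    bootstrap_mean_difference,
    categorize_days,
    classify_postseizure_days,
    label_days_after_seizure,
    outcome_within_48h,
    postseizure_condition_means,
    rm_anova,
    rm_anova_postseizure,
    seizure_rate_duration_by_state,
)
from hypnorisk.simulate import SeizureRiskParams, simulate_day_records


def _sz(*onsets, duration=60.0):
    return pd.DataFrame(
        {"onset": pd.to_datetime(list(onsets)), "duration_s": duration}
    )


# -- seizure-state annotation ----------------------------------------------

def _night_with_waso():
    runs = [("WAKE", 1320), ("N2", 240), ("WAKE", 20), ("REM", 240),
            ("WAKE", 1060)]
    hyp = Hypnogram(labels_from_runs(runs), "2020-01-01 12:00:00")
    from hypnorisk.analytics import detect_sleep_periods

    return hyp, detect_sleep_periods(hyp)


def test_onset_in_rem_epoch():
    hyp, periods = _night_with_waso()
    ann = annotate_seizure_states(_sz("2020-01-02 01:15:00"), hyp, periods)
    assert ann.iloc[0]["state"] == "REM"
    assert ann.iloc[0]["in_sleep"] == True  # noqa: E712


def test_onset_in_intra_period_wake_counts_as_sleep():
    hyp, periods = _night_with_waso()
    # the 10-min arousal runs 01:10-01:20... compute: onset 23:00 + 2 h = 01:00
    ann = annotate_seizure_states(_sz("2020-01-02 01:05:00"), hyp, periods)
    assert ann.iloc[0]["state"] == "WASO"
    assert ann.iloc[0]["in_sleep"] == True  # noqa: E712


def test_onset_outside_hypnogram_errors():
    hyp, periods = _night_with_waso()
    with pytest.raises(ParameterError):
        annotate_seizure_states(_sz("2020-01-05 00:00:00"), hyp, periods)


def test_unknown_state_excluded_from_stats():
    runs = [("UNKNOWN", 120), ("WAKE", 2760)]
    hyp = Hypnogram(labels_from_runs(runs), "2020-01-01 12:00:00")
    ann = annotate_seizure_states(_sz("2020-01-01 12:30:00"), hyp)
    assert ann.iloc[0]["state"] == "UNKNOWN"
    assert np.isnan(ann.iloc[0]["in_sleep"])


def test_rate_arithmetic():
    """2 seizures in 100 h of N2 give 0.02 sz/h."""
    hyp = Hypnogram(["N2"] * 12000, "2020-01-01 00:00:00")
    ann = annotate_seizure_states(
        _sz("2020-01-01 05:00:00", "2020-01-03 07:00:00"), hyp
    )
    table = seizure_rate_duration_by_state(ann, hyp)
    n2 = table.set_index("state").loc["N2"]
    assert n2["hours"] == pytest.approx(100.0)
    assert n2["rate_per_h"] == pytest.approx(0.02)
    assert n2["mean_duration_min"] == pytest.approx(1.0)


def test_zero_hours_state_omitted():
    hyp = Hypnogram(["N2"] * 200, "2020-01-01 00:00:00")
    ann = annotate_seizure_states(_sz("2020-01-01 00:10:00"), hyp)
    table = seizure_rate_duration_by_state(ann, hyp)
    assert "REM" not in set(table["state"])


# -- categorisation ---------------------------------------------------------

def _days(values, seizure_flags=None, start="2020-01-01 12:00:00"):
    n = len(values)
    return pd.DataFrame(
        {
            "day_start": pd.date_range(start, periods=n, freq="D"),
            "total_sleep_h": values,
            "seizure_any": seizure_flags if seizure_flags is not None
            else [False] * n,
        }
    )


def test_percentile_boundaries_are_baseline():
    days = _days(list(range(1, 10)))  # p25 = 3, p75 = 7 exactly
    out, th = categorize_days(days, "total_sleep_h")
    assert th.p25 == pytest.approx(3.0) and th.p75 == pytest.approx(7.0)
    cats = out.set_index("total_sleep_h")["category"]
    assert cats[3] == "baseline" and cats[7] == "baseline"
    assert cats[2] == "decreased" and cats[8] == "increased"


def test_identical_values_all_baseline():
    out, _ = categorize_days(_days([5.0] * 10), "total_sleep_h")
    assert (out["category"] == "baseline").all()


def test_seizure_day_excluded_and_does_not_shift_thresholds():
    base = list(range(1, 10))
    days = _days(base + [100.0], seizure_flags=[False] * 9 + [True])
    out, th = categorize_days(days, "total_sleep_h")
    assert out.iloc[-1]["category"] == "excluded"
    assert th.p75 == pytest.approx(7.0)  # the extreme seizure day is ignored


def test_too_few_seizure_free_days():
    days = _days([1, 2, 3], seizure_flags=[False, False, True])
    with pytest.raises(ParameterError):
        categorize_days(days, "total_sleep_h")
    multi = pd.concat(
        [
            _days(list(range(10))).assign(patient=0),
            _days([1.0, 2.0]).assign(patient=1),
        ],
        ignore_index=True,
    )
    with pytest.warns(UserWarning, match="skipped"):
        out, th = categorize_days(multi, "total_sleep_h")
    assert out[out["patient"] == 1]["category"].isna().all()
    assert 0 in th and 1 not in th


def test_category_mass_near_quarter_half_quarter():
    rng = np.random.default_rng(0)
    days = _days(rng.normal(9.5, 1.0, 400))
    out, _ = categorize_days(days, "total_sleep_h")
    freq = out["category"].value_counts(normalize=True)
    assert freq["decreased"] == pytest.approx(0.25, abs=0.05)
    assert freq["baseline"] == pytest.approx(0.50, abs=0.05)
    assert freq["increased"] == pytest.approx(0.25, abs=0.05)


# -- 48-h outcomes ----------------------------------------------------------

def test_outcome_window_boundaries():
    days = _days([8.0])  # window end: 2020-01-02 12:00
    assert outcome_within_48h(days, _sz("2020-01-02 22:00:00")).iloc[0] == 1
    assert outcome_within_48h(days, _sz("2020-01-04 13:00:00")).iloc[0] == 0
    # exactly +48 h: closed right endpoint
    assert outcome_within_48h(days, _sz("2020-01-04 12:00:00")).iloc[0] == 1
    # seizure inside the measured day itself does not count as outcome
    assert outcome_within_48h(days, _sz("2020-01-02 00:00:00")).iloc[0] == 0


# -- post-seizure labels ----------------------------------------------------

def test_postseizure_day_partition():
    days = pd.DataFrame(
        {
            "seizure_any": [False, True, True, True, True],
            "seizure_wake": [False, True, False, True, False],
            "seizure_sleep": [False, False, True, True, False],
        }
    )
    labels = classify_postseizure_days(days)
    assert list(labels) == ["control", "wake_sz", "sleep_sz", "excluded",
                            "excluded"]


def test_label_days_after_seizure_shifts_by_one():
    days = pd.DataFrame(
        {
            "patient": [0, 0, 0, 1, 1],
            "seizure_any": [True, False, False, False, True],
            "seizure_wake": [True, False, False, False, False],
            "seizure_sleep": [False, False, False, False, True],
        }
    )
    lab = label_days_after_seizure(days)
    assert pd.isna(lab.iloc[0]) and pd.isna(lab.iloc[3])
    assert lab.iloc[1] == "wake_sz" and lab.iloc[2] == "control"
    assert pd.isna(lab.iloc[3])


# -- RM-ANOVA ---------------------------------------------------------------

def test_identical_condition_means_give_f_zero():
    w = pd.DataFrame(
        {"control": [1.0, 2.0, 3.0], "wake_sz": [1.0, 2.0, 3.0],
         "sleep_sz": [1.0, 2.0, 3.0]}
    )
    r = rm_anova(w)
    assert r.F == 0.0 and r.pvalue == 1.0


def test_gg_epsilon_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    w = pd.DataFrame(
        rng.normal(size=(12, 3)) + [0.0, 0.5, 1.0],
        columns=["control", "wake_sz", "sleep_sz"],
    )
    r = rm_anova(w)
    long = w.reset_index().melt(id_vars="index", var_name="cond", value_name="v")
    ref = pg.rm_anova(data=long, dv="v", within="cond", subject="index",
                      correction=True)
    assert r.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
    assert r.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-9)
    assert r.pvalue == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)


def test_gg_epsilon_bounds():
    rng = np.random.default_rng(2)
    w = pd.DataFrame(rng.normal(size=(8, 4)))
    r = rm_anova(w)
    assert 1 / 3 <= r.gg_epsilon <= 1.0


def test_dunnett_two_conditions_reduces_to_paired_t():
    rng = np.random.default_rng(3)
    w = pd.DataFrame({"control": rng.normal(size=10),
                      "wake_sz": rng.normal(0.5, 1, 10)})
    r = rm_anova(w, control="control")
    d = w["wake_sz"] - w["control"]
    t_ref, p_ref = stats.ttest_rel(w["wake_sz"], w["control"])
    assert r.dunnett.iloc[0]["t"] == pytest.approx(t_ref, abs=1e-12)
    assert r.dunnett.iloc[0]["pvalue"] == pytest.approx(p_ref, abs=1e-6)


def test_dunnett_adjusted_p_exceeds_unadjusted():
    rng = np.random.default_rng(4)
    w = pd.DataFrame(
        rng.normal(size=(10, 3)) + [0.0, 0.6, 0.3],
        columns=["control", "a", "b"],
    )
    r = rm_anova(w, control="control")
    for _, row in r.dunnett.iterrows():
        _, p_unadj = stats.ttest_rel(
            w[row["comparison"].split(" - ")[0]], w["control"]
        )
        assert row["pvalue"] >= p_unadj - 1e-12


def test_bounded_data_arcsine_transformed():
    w = pd.DataFrame(
        {"control": [0.1, 0.2, 0.15, 0.12], "sleep_sz": [0.3, 0.42, 0.35, 0.4]}
    )
    r = rm_anova(w, bounded=True, control="control")
    d = np.arcsin(np.sqrt(w["sleep_sz"])) - np.arcsin(np.sqrt(w["control"]))
    t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert r.dunnett.iloc[0]["t"] == pytest.approx(t_ref, abs=1e-12)
    with pytest.raises(ParameterError):
        rm_anova(w * 10, bounded=True)


def test_too_few_complete_subjects():
    w = pd.DataFrame({"control": [1.0, 2.0, np.nan], "a": [1.0, 2.0, 3.0]})
    with pytest.raises(ParameterError):
        rm_anova(w)


def test_rm_anova_null_p_values_uniform():
    """Pure-null condition means give uniform p-values (calibration)."""
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(200):
        w = pd.DataFrame(rng.normal(size=(10, 3)),
                         columns=["a", "b", "c"])
        pvals.append(rm_anova(w).pvalue)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_postseizure_recovery_power():
    """The generator's post-seizure sleep elongation is detected by the
    duration RM-ANOVA in at least 80% of replicates at cohort scale."""
    params = SeizureRiskParams()
    detections = 0
    n_reps = 50
    for rep in range(n_reps):
        days = simulate_day_records(10, 430, params, seed=3000 + rep)
        days["postseizure_label"] = label_days_after_seizure(days)
        wide = postseizure_condition_means(days, "total_sleep_h")
        r = rm_anova_postseizure(wide)
        detections += r.pvalue < 0.05
    assert detections / n_reps >= 0.8


# -- bootstrap --------------------------------------------------------------

def test_bootstrap_identical_groups_ci_contains_zero():
    x = np.arange(30.0)
    r = bootstrap_mean_difference(x, x, seed=1)
    assert r.ci_lower <= 0.0 <= r.ci_upper


def test_bootstrap_separated_groups():
    rng = np.random.default_rng(2)
    a = rng.normal(1.0, 0.1, 100)
    b = rng.normal(0.0, 0.1, 100)
    r = bootstrap_mean_difference(a, b, seed=3)
    assert 0.9 < r.ci_lower < 1.0 < r.ci_upper < 1.1
    assert r.ci_lower > 0.0


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=50), rng.normal(size=50)
    r1 = bootstrap_mean_difference(a, b, seed=9)
    r2 = bootstrap_mean_difference(a, b, seed=9)
    np.testing.assert_array_equal(r1.distribution, r2.distribution)


def test_bootstrap_warns_on_few_resamples():
    with pytest.warns(UserWarning):
        bootstrap_mean_difference([1.0, 2.0], [0.0], n_boot=50, seed=0)
    with pytest.raises(ParameterError):
        bootstrap_mean_difference([], [1.0])
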