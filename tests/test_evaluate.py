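import numpy as np
import pandas as pd
import pytest

from lira.evaluate import (combined_marker_model, compare_auc, dcb_label,
                           decision_curve, hazard_ratio_report, percent,
                           response_rates, time_dependent_auc)
from lira.survstats import fit_cox


def _mann_whitney_auc(benefit_score, case):
    """Independent closed-form oracle: Mann-Whitney AUC of risk = -score."""
    risk = -np.asarray(benefit_score, dtype=float)
    case = np.asarray(case, dtype=bool)
    rc = risk[case][:, None]
    rn = risk[~case][None, :]
    return float(((rc > rn) + 0.5 * (rc == rn)).mean())


@pytest.mark.parametrize("seed", range(6))
def test_auc_reduces_to_mann_whitney_when_uncensored(seed):
    rng = np.random.default_rng(seed)
    n = 120
    s = rng.normal(size=n)
    t = rng.exponential(6, n)
    e = np.ones(n, int)
    h = float(np.median(t))
    res = time_dependent_auc(s, t, e, h)
    assert res.auc == pytest.approx(_mann_whitney_auc(s, t <= h), abs=1e-12)


def test_auc_perfect_ranking():
    """A benefit score equal to the event time itself ranks perfectly."""
    rng = np.random.default_rng(1)
    t = rng.uniform(1, 10, 50)
    res = time_dependent_auc(t, t, np.ones(50, int), 5.0)
    assert res.auc == 1.0
    # and the anti-score ranks perfectly wrongly
    assert time_dependent_auc(-t, t, np.ones(50, int), 5.0).auc == 0.0


def test_auc_null_score_near_half():
    rng = np.random.default_rng(2)
    n = 2000
    t = rng.exponential(6, n)
    e = (rng.uniform(size=n) < 0.7).astype(int)
    s = rng.normal(size=n)
    res = time_dependent_auc(s, t, e, float(np.quantile(t, 0.5)))
    assert 0.46 <= res.auc <= 0.54


def test_auc_requires_cases_and_controls():
    with pytest.raises(ValueError):
        time_dependent_auc([1, 2, 3], [5, 6, 7], [1, 1, 1], 1.0)   # no cases
    with pytest.raises(ValueError):
        time_dependent_auc([1, 2, 3], [1, 2, 3], [1, 1, 1], 3.0)   # no controls


def test_compare_auc_identical_scores():
    rng = np.random.default_rng(3)
    n = 150
    s = rng.normal(size=n)
    t = rng.exponential(5, n)
    e = (rng.uniform(size=n) < 0.8).astype(int)
    d, p = compare_auc(s, s, t, e, float(np.median(t)), B=150, seed=0)
    assert d == 0.0 and p >= 0.95
    with pytest.raises(ValueError):
        compare_auc(s, s, t, e, 1.0, B=50)


def test_compare_auc_detects_informative_score():
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 400
        risk = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.9 * risk)))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        info = -risk                    # benefit-scale informative score
        noise = rng.normal(size=n)
        _, p = compare_auc(info, noise, t, e, float(np.median(t)), B=300, seed=seed)
        hits += int(p < 0.05)
    assert hits >= 4


def test_combined_marker_model_delegates_to_cox(small_cohort, small_model):
    from lira.model import predict_score

    cohort, _ = small_cohort
    scores = predict_score(small_model.model, cohort.expr).set_index(
        "sample_id")["lira_score"]
    mm = combined_marker_model(cohort, ("lira", "tmb"), scores=scores)
    df = cohort.clinical.df.set_index("sample_id")
    X = np.column_stack([scores.loc[df.index], df["tmb"]])
    ref = fit_cox(df["pfs_months"], df["pfs_event"], X)
    assert np.allclose(mm.fit.coef, ref.coef)
    lp = X @ mm.fit.coef
    assert np.allclose(mm.linear_predictor.to_numpy(), lp)


def test_combined_model_auc_not_worse_than_best_single(small_cohort, small_model):
    from lira.model import predict_score

    cohort, _ = small_cohort
    scores = predict_score(small_model.model, cohort.expr).set_index(
        "sample_id")["lira_score"]
    df = cohort.clinical.df
    t = df["pfs_months"].to_numpy()
    e = df["pfs_event"].to_numpy()
    h = float(np.quantile(t, 0.5))
    mm = combined_marker_model(cohort, ("lira", "tmb"), scores=scores)
    auc_comb = time_dependent_auc(-mm.linear_predictor.to_numpy(), t, e, h).auc
    auc_lira = time_dependent_auc(scores.to_numpy(), t, e, h).auc
    auc_tmb = time_dependent_auc(-df["tmb"].to_numpy(), t, e, h).auc
    assert auc_comb >= max(auc_lira, auc_tmb) - 0.01


def test_combined_marker_model_missing_marker_errors(small_cohort):
    cohort, _ = small_cohort
    clin = cohort.clinical.df.copy()
    clin["tmb"] = np.nan
    from lira.cohort_io import ClinicalTable, CohortDataset
    broken = CohortDataset(cohort.expr, ClinicalTable(clin))
    with pytest.raises(ValueError, match="tmb"):
        combined_marker_model(broken, ("tmb",))


def test_hazard_ratio_report_symmetry(small_cohort):
    cohort, _ = small_cohort
    rng = np.random.default_rng(0)
    labels = np.where(rng.uniform(size=cohort.n) < 0.5, "high", "low")
    fit, curves, lr = hazard_ratio_report(cohort, labels)
    swapped = np.where(labels == "high", "low", "high")
    fit2, _, lr2 = hazard_ratio_report(cohort, swapped)
    assert fit2.hr[0] == pytest.approx(1.0 / fit.hr[0], abs=1e-9)
    assert lr2.statistic == pytest.approx(lr.statistic)
    assert set(curves) == {"high", "low"}


def test_decision_curve_hand_computed_uncensored():
    # 10 subjects, horizon 5: events by 5 for the first 4; predicted risks
    # make subjects 0-5 positive at pt=0.2 -> TP=4, FP=2
    t = np.array([1, 2, 3, 4, 9, 9, 9, 9, 9, 9], dtype=float)
    e = np.ones(10, int)
    risk = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.1, 0.1, 0.1, 0.1])
    out = decision_curve(risk, t, e, 5.0, [0.2])
    nb = out["net_benefit"].iloc[0]
    assert nb == pytest.approx(4 / 10 - (2 / 10) * (0.2 / 0.8), abs=1e-12)
    # treat-all at small pt tends to prevalence
    out2 = decision_curve(np.ones(10), t, e, 5.0, [0.01])
    assert out2["treat_all"].iloc[0] == pytest.approx(0.4 - 0.6 * (0.01 / 0.99))
    assert out2["treat_none"].iloc[0] == 0.0


def test_decision_curve_validation():
    t = np.array([1.0, 2.0]); e = np.array([1, 1])
    with pytest.raises(ValueError):
        decision_curve([0.5, 0.5], t, e, 5.0, [0.2])     # horizon too late
    with pytest.raises(ValueError):
        decision_curve([0.5, 0.5], t, e, 1.5, [0.0, 0.2])


def test_response_rates_table_arithmetic():
    """Percentages recompute from counts at 3 significant figures."""
    groups = {
        "io": ["CR"] * 1 + ["PR"] * 12 + ["SD"] * 40 + ["PD"] * 34 + ["NE"] * 8,
        "combo": ["CR"] * 3 + ["PR"] * 73 + ["SD"] * 24 + ["PD"] * 13,
    }
    out = response_rates(groups)
    assert out.counts.loc["io"].sum() == 95
    assert out.percentages.loc["io", "CR"] == 1.05
    assert out.percentages.loc["io", "PR"] == 12.6
    assert out.percentages.loc["io", "NE"] == 8.42
    assert out.percentages.loc["combo", "PR"] == 64.6
    assert out.percentages.loc["combo", "NE"] == 0.0
    assert out.orr["io"] == percent(13, 95)
    # percentages always recompute from stored counts
    for g in out.counts.index:
        n = out.counts.loc[g].sum()
        for c in out.counts.columns:
            assert out.percentages.loc[g, c] == percent(out.counts.loc[g, c], n)


def test_response_rates_unknown_code():
    with pytest.raises(ValueError, match="unknown BOR"):
        response_rates({"g": ["CR", "XX"]})


@pytest.mark.parametrize("bor,pfs,expected", [
    ("CR", 1.0, "DCB"),
    ("PR", 7.0, "DCB"),
    ("PR", 2.0, "DCB"),          # response is durable regardless of duration
    ("SD", 6.5, "DCB"),
    ("SD", 6.0, "NDB"),          # boundary: strictly > 6 months required
    ("SD", 5.0, "NDB"),
    ("PD", 20.0, "NDB"),
    ("NE", 3.0, "NE"),
])
def test_dcb_label_definition(bor, pfs, expected):
    assert dcb_label(bor, pfs) == expected


def test_dcb_label_rejects_unknown():
    with pytest.raises(ValueError):
        dcb_label("XYZ", 1.0)
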