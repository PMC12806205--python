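import logging

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lira.cohort_io import ClinicalTable, CohortDataset, ExpressionMatrix
from lira.forest import ForestParams, fit_survival_forest
from lira.model import (LiraConfig, build_lira, interaction_screen,
                        predict_score, train_forest, univariate_screen)
from lira.simdata import SimConfig, simulate_cohort


def _one_gene_cohort(x, times, events, arms):
    n = len(times)
    expr = ExpressionMatrix(("G1",), tuple(f"S{i}" for i in range(n)),
                            np.asarray(x, dtype=float)[None, :], "log_tpm")
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)], "arm": arms,
        "pfs_months": times, "pfs_event": events,
        "os_months": np.asarray(times) * 1.5, "os_event": events}))
    return CohortDataset(expr, clin)


def test_univariate_screen_null_pass_fraction(small_cohort):
    """Null genes pass at about the nominal alpha = 0.01 rate."""
    cohort, _ = simulate_cohort(SimConfig(n_samples=600, n_genes=2000,
                                          n_predictive=0, n_prognostic=0, seed=21))
    tab = univariate_screen(cohort)
    frac = tab["pass_univariate"].mean()
    # binomial 99% bounds around 0.01 with 2000 genes
    bound = 2.576 * np.sqrt(0.01 * 0.99 / 2000)
    assert abs(frac - 0.01) <= bound


def test_univariate_screen_flags_latent_risk_gene(small_cohort):
    """A gene equal to the latent risk score is overwhelmingly significant
    with 'advanced' direction (higher expression = worse outcome)."""
    cohort, truth = small_cohort
    n = cohort.n
    genes = ("RISK",) + cohort.expr.gene_ids[:10]
    vals = np.vstack([truth.latent_risk[None, :], cohort.expr.values[:10]])
    vals = vals - vals.min() + 0.1
    expr = ExpressionMatrix(genes, cohort.expr.sample_ids, vals, "log_tpm")
    tab = univariate_screen(CohortDataset(expr, cohort.clinical)).set_index("gene_id")
    assert tab.loc["RISK", "uni_p"] < 1e-6
    assert tab.loc["RISK", "direction"] == "advanced"
    assert tab.loc["RISK", "uni_hr"] > 1


def test_univariate_screen_constant_gene_unevaluable(small_cohort):
    cohort, _ = small_cohort
    genes = ("FLAT",) + cohort.expr.gene_ids[:5]
    vals = np.vstack([np.full((1, cohort.n), 3.0), cohort.expr.values[:5]])
    expr = ExpressionMatrix(genes, cohort.expr.sample_ids, vals, "log_tpm")
    tab = univariate_screen(CohortDataset(expr, cohort.clinical)).set_index("gene_id")
    assert not tab.loc["FLAT", "evaluable"]
    assert not tab.loc["FLAT", "pass_univariate"]


def test_univariate_screen_empty_gene_list(small_cohort):
    cohort, _ = small_cohort
    expr = ExpressionMatrix((), cohort.expr.sample_ids,
                            np.zeros((0, cohort.n)), "log_tpm")
    tab = univariate_screen(CohortDataset(expr, cohort.clinical))
    assert len(tab) == 0


def test_interaction_screen_power_and_specificity():
    """Predictive genes reject, prognostic-only genes mostly do not."""
    hits_pred, hits_prog = 0, 0
    n_seeds = 8
    for seed in range(n_seeds):
        cohort, truth = simulate_cohort(SimConfig(
            n_samples=600, n_genes=1, n_predictive=1, n_prognostic=0,
            beta_interaction=-0.8, seed=seed))
        tab = univariate_screen(cohort)
        tab["pass_univariate"] = True     # isolate the interaction criterion
        tab = interaction_screen(cohort, tab).set_index("gene_id")
        hits_pred += int(tab["interaction_p"].iloc[0] < 0.05)

        cohort2, _ = simulate_cohort(SimConfig(
            n_samples=600, n_genes=1, n_predictive=0, n_prognostic=1,
            beta_interaction=0.0, beta_prognostic=-0.8, seed=seed))
        tab2 = univariate_screen(cohort2)
        tab2["pass_univariate"] = True
        tab2 = interaction_screen(cohort2, tab2).set_index("gene_id")
        hits_prog += int(tab2["interaction_p"].iloc[0] < 0.05)
    assert hits_pred >= int(0.8 * n_seeds)
    assert hits_prog <= max(2, int(0.2 * n_seeds))


def test_interaction_screen_reports_subgroup_hrs():
    cohort, _ = simulate_cohort(SimConfig(n_samples=400, n_genes=1, n_predictive=1,
                                          n_prognostic=0, beta_interaction=-1.0,
                                          seed=3))
    tab = univariate_screen(cohort)
    tab["pass_univariate"] = True
    tab = interaction_screen(cohort, tab).set_index("gene_id")
    row = tab.iloc[0]
    # benefit concentrates in high expressers: arm HR lower there
    assert row["arm_hr_high_expr"] < row["arm_hr_low_expr"]


def test_interaction_screen_degenerate_gene_unevaluable():
    rng = np.random.default_rng(0)
    n = 60
    cohort = _one_gene_cohort(np.full(n, 2.0), rng.exponential(5, n),
                              np.ones(n, int), ["IO", "Chemo"] * 30)
    tab = univariate_screen(cohort)
    tab.loc[:, "pass_univariate"] = True
    tab.loc[:, "evaluable"] = True
    out = interaction_screen(cohort, tab).set_index("gene_id")
    assert not out.loc["G1", "evaluable"]


def test_interaction_screen_df_mode_2_larger_df():
    cohort, _ = simulate_cohort(SimConfig(n_samples=300, n_genes=1, n_predictive=1,
                                          n_prognostic=0, seed=4))
    tab = univariate_screen(cohort)
    tab["pass_univariate"] = True
    p1 = interaction_screen(cohort, tab.copy(), df_mode=1)["interaction_p"].iloc[0]
    p2 = interaction_screen(cohort, tab.copy(), df_mode=2)["interaction_p"].iloc[0]
    assert 0 <= p1 <= 1 and 0 <= p2 <= 1
    assert p1 != p2


def test_train_forest_requires_ici_arm(small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(ValueError, match="ICI"):
        train_forest(cohort, list(cohort.expr.gene_ids[:3]))
    with pytest.raises(ValueError, match="absent"):
        train_forest(cohort.ici_subset(), ["NOT_A_GENE"])


def test_build_lira_contract_and_recovery(small_model, small_cohort):
    cohort, truth = small_cohort
    res = small_model
    passers = set(res.candidate_genes)
    assert len(res.model.genes) == min(50, len(passers))
    assert set(res.model.genes) <= passers
    # vimp ranks are a permutation of 1..n
    assert sorted(res.vimp_table["rank"]) == list(range(1, len(res.vimp_table) + 1))
    # most predictive genes survive the pipeline even at this small size
    assert len(passers & truth.predictive_genes) >= len(truth.predictive_genes) // 2


def test_build_lira_warns_when_few_passers(caplog):
    cohort, _ = simulate_cohort(SimConfig(n_samples=300, n_genes=60, n_predictive=3,
                                          n_prognostic=3, seed=13))
    with caplog.at_level(logging.WARNING, logger="lira.model"):
        res = build_lira(cohort, LiraConfig(forest=ForestParams(n_trees=20), seed=13))
    assert "retaining all" in caplog.text
    assert len(res.model.genes) < 50


def test_predict_score_properties(small_model, small_cohort):
    cohort, truth = small_cohort
    scores = predict_score(small_model.model, cohort.expr)
    s = scores["lira_score"].to_numpy()
    assert np.all((s >= 0) & (s <= small_model.model.tau))
    # higher score = lower risk under ICI
    assert spearmanr(s, truth.ici_latent_risk).statistic < 0


def test_predict_score_missing_gene_warns_small_shift(small_cohort, caplog):
    """Dropping 1 of 50 model genes degrades scores gracefully (<5% median)."""
    cohort, _ = small_cohort
    ici = cohort.ici_subset()
    genes = list(cohort.expr.gene_ids[:50])
    model = train_forest(ici, genes, ForestParams(n_trees=40), seed=2)
    full = predict_score(model, cohort.expr)["lira_score"].to_numpy()
    drop = model.genes[0]
    kept = [g for g in cohort.expr.gene_ids if g != drop]
    with caplog.at_level(logging.WARNING, logger="lira.model"):
        partial = predict_score(model, cohort.expr.subset_genes(kept))
    assert drop in caplog.text
    assert (partial["n_model_genes_used"] == len(model.genes) - 1).all()
    rel = np.abs(partial["lira_score"].to_numpy() - full) / np.maximum(full, 1e-9)
    assert np.median(rel) < 0.05


def test_predict_score_too_many_missing_errors(small_model, small_cohort):
    cohort, _ = small_cohort
    model = small_model.model
    n_drop = len(model.genes) // 2 + 1
    kept = [g for g in cohort.expr.gene_ids if g not in set(model.genes[:n_drop])]
    with pytest.raises(ValueError, match="unreliable"):
        predict_score(model, cohort.expr.subset_genes(kept))


def test_predict_score_rejects_non_log_scale(small_model, small_cohort):
    cohort, _ = small_cohort
    expr = ExpressionMatrix(cohort.expr.gene_ids, cohort.expr.sample_ids,
                            np.exp(cohort.expr.values), "tpm")
    with pytest.raises(ValueError, match="log_tpm"):
        predict_score(small_model.model, expr)


def test_monotone_response_single_gene_model():
    """Raising a favorable gene's expression never lowers the score."""
    rng = np.random.default_rng(10)
    n = 300
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (0.25 * np.exp(-1.5 * x)))   # high x = favorable
    e = np.ones(n, int)
    # depth-1 trees with generous leaves: each tree is one strong split, so
    # its survival step is ordered along the gene axis and the ensemble is
    # monotone in the gene value
    model = fit_survival_forest(x[:, None], t, e, ["g"],
                                ForestParams(n_trees=25, min_leaf_events=40,
                                             max_depth=1),
                                seed=0)
    base = model.predict_rmst(x[:, None])
    bumped = model.predict_rmst((x + 1.0)[:, None])
    assert np.all(bumped - base >= -1e-9)


def test_end_to_end_seed_determinism(small_cohort):
    cohort, _ = small_cohort
    cfg = LiraConfig(forest=ForestParams(n_trees=15), seed=5)
    r1 = build_lira(cohort, cfg)
    r2 = build_lira(cohort, cfg)
    assert r1.model.archive_hash() == r2.model.archive_hash()
    pd.testing.assert_frame_equal(r1.screen_table, r2.screen_table)
    s1 = predict_score(r1.model, cohort.expr)
    s2 = predict_score(r2.model, cohort.expr)
    pd.testing.assert_frame_equal(s1, s2)
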