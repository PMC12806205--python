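"""Reproducible benchmark harness: the package's standard study conditions.

Each function simulates data under the standard conditions, runs the
relevant part of the pipeline, and measures operating characteristics:
gene-recovery rates of the three-criterion screen, type-I error and power
of the treatment-interaction test, the end-to-end stratification pattern
on held-out data, and reference-database round-trip fidelity.  The
benchmark forest uses 200 trees (the production default is 1000) so the
full recovery benchmark runs on a laptop in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .cohort_io import ExpressionMatrix, split_cohort
from .forest import ForestParams
from .model import (LiraConfig, build_lira, interaction_screen, predict_score,
                    univariate_screen)
from .refdb import batch_adjust, build_reference, score_samples
from .simdata import SimConfig, simulate_cohort
from .stratify import mean_split
from .survstats import fit_cox

log = logging.getLogger(__name__)

BENCH_FOREST = ForestParams(n_trees=200)


def recovery_benchmark(seeds=range(10), sim: SimConfig | None = None):
    """Three-criterion gene recovery on the standard benchmark.

    For each seed: simulate the default two-arm cohort (600 patients, 2000
    genes, 30 predictive / 50 prognostic-only), run the full pipeline, and
    report the fraction of predictive genes inside the final model gene
    set and the fraction of the final set that is prognostic-only.
    """
    recov, contam = [], []
    for seed in seeds:
        cfg = sim if sim is not None else SimConfig(seed=seed)
        cfg = replace(cfg, seed=seed)
        cohort, truth = simulate_cohort(cfg)
        res = build_lira(cohort, LiraConfig(forest=BENCH_FOREST, seed=seed))
        final = set(res.model.genes)
        recov.append(len(final & truth.predictive_genes)
                     / max(len(truth.predictive_genes), 1))
        contam.append(len(final & truth.prognostic_genes) / max(len(final), 1))
    return {"recovery": recov, "contamination": contam}


def _one_gene_interaction_p(cfg: SimConfig) -> float | None:
    cohort, _ = simulate_cohort(cfg)
    tab = univariate_screen(cohort)
    tab["pass_univariate"] = True         # isolate the interaction criterion
    tab = interaction_screen(cohort, tab, genes=list(cohort.expr.gene_ids))
    p = tab["interaction_p"].iloc[0]
    return None if np.isnan(p) else float(p)


def interaction_type1(n_reps: int = 500, n: int = 400, alpha: float = 0.05,
                      seed: int = 0):
    """Rejection rate of the interaction test on null genes."""
    rng = np.random.default_rng(seed)
    hits, total = 0, 0
    for _ in range(n_reps):
        s = int(rng.integers(0, 2**31 - 1))
        p = _one_gene_interaction_p(SimConfig(
            n_samples=n, n_genes=1, n_predictive=0, n_prognostic=0, seed=s))
        if p is None:
            continue
        total += 1
        hits += int(p < alpha)
    return hits / total, total


def interaction_power(n_seeds: int = 20, n: int = 600,
                      beta_interaction: float = -0.8, alpha: float = 0.05,
                      seed: int = 0):
    """Power of the interaction test for a predictive gene."""
    rng = np.random.default_rng(seed)
    hits, total = 0, 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        p = _one_gene_interaction_p(SimConfig(
            n_samples=n, n_genes=1, n_predictive=1, n_prognostic=0,
            beta_interaction=beta_interaction, seed=s))
        if p is None:
            continue
        total += 1
        hits += int(p < alpha)
    return hits / total, total


def stratification_pattern(seed: int = 0, n_samples: int = 900):
    """Train on 70% of a simulated trial, stratify the held-out 30%.

    Returns the high-vs-low hazard ratios and log-rank p separately for
    the ICI and chemotherapy arms of the held-out cohort — the predictive
    (not merely prognostic) signature shows strong ICI-arm separation and
    weaker chemo-arm separation.
    """
    cohort, _ = simulate_cohort(SimConfig(n_samples=n_samples, seed=seed))
    train, test = split_cohort(cohort, 0.7, seed=seed)
    res = build_lira(train, LiraConfig(forest=BENCH_FOREST, seed=seed))
    out = {}
    for arm_name, sub in (("ici", test.ici_subset()), ("chemo", test.chemo_subset())):
        scores = predict_score(res.model, sub.expr)["lira_score"].to_numpy()
        labels = mean_split(scores)
        df = sub.clinical.df
        ind = (labels == "high").astype(float)
        fit = fit_cox(df["pfs_months"], df["pfs_event"], ind)
        from .survstats import logrank_test

        lr = logrank_test(df["pfs_months"], df["pfs_event"], labels)
        out[arm_name] = {"hr": float(fit.hr[0]),
                         "log_hr": float(fit.coef[0]),
                         "logrank_p": float(lr.p)}
    return out


def refdb_fidelity(seed: int = 0):
    """Reference-database single-sample fidelity under the study conditions.

    Builds a reference from the ICI arm of a simulated cohort, then:
    (a) rescoring each reference sample alone -> max score deviation and
    class-flip count; (b) cohort-wide Spearman between batch scores and
    the one-at-a-time path; (c) residual per-gene mean difference after
    adjusting a copy of the reference shifted by a constant.
    """
    cohort, _ = simulate_cohort(SimConfig(n_samples=500, n_genes=300,
                                          n_predictive=15, n_prognostic=20,
                                          seed=seed))
    res = build_lira(cohort, LiraConfig(forest=ForestParams(n_trees=150),
                                        seed=seed))
    ref = cohort.ici_subset()
    refdb = build_reference(ref, res.model)
    stored = refdb.ref_scores.set_index("sample_id")["lira_score"]

    devs, flips, singles = [], 0, []
    for sid in ref.expr.sample_ids:
        single = ref.expr.subset_samples([sid])
        single = ExpressionMatrix(single.gene_ids, ("NEW",), single.values,
                                  "log_tpm")
        out = score_samples(refdb, single)
        s_new = float(out["lira_score"].iloc[0])
        singles.append(s_new)
        devs.append(abs(s_new - stored.loc[sid]))
        old = "benefit" if stored.loc[sid] > refdb.cutoff.cutoff else "no_benefit"
        flips += int(out["predicted_class"].iloc[0] != old)
    rho = float(spearmanr(singles, stored.loc[list(ref.expr.sample_ids)]).statistic)

    shifted = ExpressionMatrix(ref.expr.gene_ids,
                               tuple("N" + s for s in ref.expr.sample_ids),
                               ref.expr.values + 2.0, "log_tpm")
    adj = batch_adjust(refdb, shifted)
    resid = float(np.abs(adj.values.mean(axis=1)
                         - ref.expr.values.mean(axis=1)).max())
    return {"max_dev_months": float(max(devs)), "class_flips": int(flips),
            "rank_spearman": rho, "shift_residual": resid,
            "n_reference": ref.n}
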