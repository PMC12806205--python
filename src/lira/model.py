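"""The three-criterion gene-selection pipeline and score prediction.

Model construction follows three gene-selection criteria: (1) association
with survival in univariate Cox regression on standardized log-expression
(p < 0.01); (2) a significant treatment x gene interaction, tested by a
likelihood-ratio test between nested Cox models after dichotomizing each
gene at the cohort median (p < 0.05); (3) the top 50 genes by out-of-bag
permutation variable importance in a random survival forest grown on the
ICI-treated arm.  The final forest, retrained on the selected genes,
assigns each sample a score: the ensemble restricted mean event-free time
up to the training horizon tau (months; higher = lower predicted risk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortDataset, ExpressionMatrix
from .forest import ForestParams, SurvivalForestModel, fit_survival_forest, permutation_vimp
from .survstats import DegenerateCovariateError, SurvData, fit_cox, lrt

log = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "gene_id", "uni_hr", "uni_ci_low", "uni_ci_high", "uni_p", "uni_p_os",
    "direction", "pass_univariate", "interaction_p",
    "arm_hr_low_expr", "arm_hr_high_expr", "pass_interaction", "evaluable",
]


@dataclass(frozen=True)
class LiraConfig:
    """Knobs of the model-construction pipeline (defaults = published procedure)."""

    endpoint: str = "pfs"
    alpha_univariate: float = 0.01
    alpha_interaction: float = 0.05
    require_hr_lt_1: bool = False
    df_mode: int = 1                 # 1: arm:grp term only; 2: vs Cox(arm)
    continuous_interaction: bool = False
    top_k: int = 50
    forest: ForestParams = field(default_factory=ForestParams)
    seed: int = 0


@dataclass(frozen=True)
class LiraResult:
    model: SurvivalForestModel
    screen_table: pd.DataFrame
    vimp_table: pd.DataFrame
    candidate_genes: tuple[str, ...]


def _endpoint_arrays(cohort: CohortDataset, endpoint: str):
    df = cohort.clinical.df
    if endpoint == "pfs":
        return df["pfs_months"].to_numpy(), df["pfs_event"].to_numpy()
    if endpoint == "os":
        return df["os_months"].to_numpy(), df["os_event"].to_numpy()
    raise ValueError(f"unknown endpoint {endpoint!r}")


def univariate_screen(cohort: CohortDataset, endpoint: str = "pfs",
                      alpha: float = 0.01,
                      require_hr_lt_1: bool = False) -> pd.DataFrame:
    """Criterion 1: per-gene univariate Cox on standardized log-expression.

    Returns one row per gene with PFS HR/CI/p (endpoint-configurable), the
    OS p-value for reference, the prognostic direction (favorable when
    HR < 1, advanced otherwise) and the pass flag.  Constant genes are
    flagged unevaluable and never pass.
    """
    times, events = _endpoint_arrays(cohort, endpoint)
    other = "os" if endpoint == "pfs" else "pfs"
    times2, events2 = _endpoint_arrays(cohort, other)
    if events.sum() < 10:
        raise ValueError("need at least 10 events for the univariate screen")
    sd_main = SurvData(times, events)
    sd_other = SurvData(times2, events2)

    rows = []
    vals = cohort.expr.values
    for i, gene in enumerate(cohort.expr.gene_ids):
        x = vals[i]
        std = x.std()
        if std == 0:
            rows.append(dict(gene_id=gene, uni_hr=np.nan, uni_ci_low=np.nan,
                             uni_ci_high=np.nan, uni_p=np.nan, uni_p_os=np.nan,
                             direction="na", pass_univariate=False,
                             evaluable=False))
            continue
        z = (x - x.mean()) / std
        fit = fit_cox(times, events, z, names=(gene,), surv=sd_main)
        fit2 = fit_cox(times2, events2, z, names=(gene,), surv=sd_other)
        hr = float(fit.hr[0])
        p = float(fit.p[0])
        ok = p < alpha and (hr < 1 or not require_hr_lt_1)
        rows.append(dict(
            gene_id=gene, uni_hr=hr, uni_ci_low=float(fit.ci_low[0]),
            uni_ci_high=float(fit.ci_high[0]), uni_p=p,
            uni_p_os=float(fit2.p[0]),
            direction="favorable" if hr < 1 else "advanced",
            pass_univariate=bool(ok), evaluable=True,
        ))
    if not rows:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    df = pd.DataFrame(rows)
    for c in ("interaction_p", "arm_hr_low_expr", "arm_hr_high_expr"):
        df[c] = np.nan
    df["pass_interaction"] = False
    return df[SCREEN_COLUMNS]


def interaction_screen(cohort: CohortDataset, screen: pd.DataFrame,
                       genes=None, endpoint: str = "pfs", alpha: float = 0.05,
                       df_mode: int = 1,
                       continuous: bool = False) -> pd.DataFrame:
    """Criterion 2: treatment x gene interaction by likelihood-ratio test.

    Each gene is dichotomized at the cohort median (or used continuously);
    the LRT compares Cox(arm + grp + arm:grp) against Cox(arm + grp)
    (``df_mode=1``) or against Cox(arm) alone (``df_mode=2``).  Treatment
    HRs within the low- and high-expression subgroups are reported.  Genes
    with an empty arm x subgroup event cell are flagged unevaluable.
    """
    if df_mode not in (1, 2):
        raise ValueError("df_mode must be 1 or 2")
    times, events = _endpoint_arrays(cohort, endpoint)
    arm = cohort.clinical.is_ici().astype(float)
    if arm.min() == arm.max():
        raise ValueError("interaction screen needs both treatment arms")
    screen = screen.copy().set_index("gene_id", drop=False)
    if genes is None:
        genes = screen.loc[screen["pass_univariate"], "gene_id"].tolist()
    gene_idx = {g: i for i, g in enumerate(cohort.expr.gene_ids)}
    sd = SurvData(times, events)

    for gene in genes:
        x = cohort.expr.values[gene_idx[gene]]
        if continuous:
            std = x.std()
            if std == 0:
                screen.loc[gene, "evaluable"] = False
                continue
            grp = (x - x.mean()) / std
            cells_ok = True
        else:
            med = np.median(x)
            grp = (x > med).astype(float)
            cells_ok = all(
                events[(arm == a) & (grp == g)].sum() > 0
                for a in (0.0, 1.0) for g in (0.0, 1.0)
            ) and 0 < grp.sum() < grp.size
        if not cells_ok:
            screen.loc[gene, "evaluable"] = False
            screen.loc[gene, "pass_interaction"] = False
            continue
        X_full = np.column_stack([arm, grp, arm * grp])
        names_full = ("arm", "grp", "arm:grp")
        try:
            full = fit_cox(times, events, X_full, names=names_full, surv=sd)
            if df_mode == 1:
                nested = fit_cox(times, events, X_full[:, :2],
                                 names=("arm", "grp"), surv=sd)
            else:
                nested = fit_cox(times, events, arm, names=("arm",), surv=sd)
            _, _, p_int = lrt(nested, full)
        except (DegenerateCovariateError, np.linalg.LinAlgError):
            screen.loc[gene, "evaluable"] = False
            continue
        screen.loc[gene, "interaction_p"] = p_int
        screen.loc[gene, "pass_interaction"] = bool(
            p_int < alpha and bool(screen.loc[gene, "pass_univariate"]))
        if not continuous:
            for label, mask_val in (("arm_hr_low_expr", 0.0), ("arm_hr_high_expr", 1.0)):
                m = grp == mask_val
                try:
                    sub = fit_cox(times[m], events[m], arm[m], names=("arm",))
                    screen.loc[gene, label] = float(sub.hr[0])
                except (DegenerateCovariateError, ValueError):
                    screen.loc[gene, label] = np.nan
    return screen.reset_index(drop=True)


def train_forest(cohort_ici: CohortDataset, candidate_genes,
                 params: ForestParams | None = None, endpoint: str = "pfs",
                 seed: int = 0) -> SurvivalForestModel:
    """Criterion-3 forest: grown on the ICI-treated arm only."""
    params = params or ForestParams()
    if not all(cohort_ici.clinical.is_ici()):
        raise ValueError("forest must be trained on the ICI-treated arm only")
    missing = [g for g in candidate_genes if g not in set(cohort_ici.expr.gene_ids)]
    if missing:
        raise ValueError(f"candidate genes absent from expression: {missing}")
    times, events = _endpoint_arrays(cohort_ici, endpoint)
    if cohort_ici.n < 20 or events.sum() < 1:
        raise ValueError("need at least 20 ICI-arm samples with events")
    expr = cohort_ici.expr.subset_genes(list(candidate_genes))
    X = expr.values.T
    return fit_survival_forest(X, times, events, list(candidate_genes),
                               params, seed=seed)


def variable_importance(model: SurvivalForestModel, cohort_ici: CohortDataset,
                        endpoint: str = "pfs") -> pd.DataFrame:
    """OOB permutation VIMP for every model gene, with ranks (1 = top)."""
    times, events = _endpoint_arrays(cohort_ici, endpoint)
    expr = cohort_ici.expr.subset_genes(list(model.genes))
    vimp = permutation_vimp(model, expr.values.T, times, events)
    order = np.lexsort((np.array(model.genes), -vimp))
    rank = np.empty(len(model.genes), dtype=int)
    rank[order] = np.arange(1, len(model.genes) + 1)
    return pd.DataFrame({"gene_id": list(model.genes), "vimp": vimp,
                         "rank": rank}).sort_values("rank").reset_index(drop=True)


def build_lira(training_cohort: CohortDataset,
               config: LiraConfig | None = None) -> LiraResult:
    """Run the full three-criterion pipeline and return the trained model.

    univariate screen -> interaction screen on the passers -> forest on the
    double-passers (ICI arm) -> permutation VIMP -> retain the top-k genes
    -> retrain the final forest on those genes.  When fewer than k genes
    double-pass, all of them are retained with a warning.
    """
    cfg = config or LiraConfig()
    screen = univariate_screen(training_cohort, cfg.endpoint,
                               cfg.alpha_univariate, cfg.require_hr_lt_1)
    screen = interaction_screen(training_cohort, screen, endpoint=cfg.endpoint,
                                alpha=cfg.alpha_interaction, df_mode=cfg.df_mode,
                                continuous=cfg.continuous_interaction)
    passers = screen.loc[screen["pass_interaction"], "gene_id"].tolist()
    if not passers:
        raise ValueError("no gene passed both screening criteria; cannot train")
    if len(passers) < cfg.top_k:
        log.warning("only %d genes passed both criteria (< top_k=%d); retaining all",
                    len(passers), cfg.top_k)
    ici = training_cohort.ici_subset()
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(cfg.seed).spawn(2)]
    candidate_model = train_forest(ici, passers, cfg.forest, cfg.endpoint,
                                   seed=seeds[0])
    vimp = variable_importance(candidate_model, ici, cfg.endpoint)
    k = min(cfg.top_k, len(passers))
    final_genes = vimp.head(k)["gene_id"].tolist()
    final_model = train_forest(ici, final_genes, cfg.forest, cfg.endpoint,
                               seed=seeds[1])
    return LiraResult(model=final_model, screen_table=screen, vimp_table=vimp,
                      candidate_genes=tuple(passers))


def predict_score(model: SurvivalForestModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Score samples: restricted mean event-free months per sample.

    Model genes missing from the input are omitted: trees route through
    splits on missing genes by sending the sample to both children with
    halved weight (logged).  More than 50% missing model genes is an error.
    """
    if expr.scale != "log_tpm":
        raise ValueError("expression must be on the log_tpm scale")
    if expr.n_samples == 0:
        raise ValueError("empty expression matrix")
    present = set(expr.gene_ids)
    missing = [g for g in model.genes if g not in present]
    if len(missing) * 2 > len(model.genes):
        raise ValueError(
            f"{len(missing)}/{len(model.genes)} model genes missing; "
            "score deemed unreliable")
    if missing:
        log.warning("omitting %d missing model gene(s): %s", len(missing), missing)
    gene_idx = {g: i for i, g in enumerate(expr.gene_ids)}
    n = expr.n_samples
    X = np.zeros((n, len(model.genes)))
    miss_mask = np.zeros(len(model.genes), dtype=bool)
    for j, g in enumerate(model.genes):
        if g in gene_idx:
            X[:, j] = expr.values[gene_idx[g]]
        else:
            miss_mask[j] = True
    scores = model.predict_rmst(X, miss_mask if miss_mask.any() else None)
    return pd.DataFrame({
        "sample_id": list(expr.sample_ids),
        "lira_score": scores,
        "n_model_genes_used": len(model.genes) - len(missing),
    })
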