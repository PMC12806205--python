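"""Synthetic two-arm immunotherapy-trial generator.

Emulates the structure of a randomized ICI-vs-chemotherapy NSCLC cohort:
log-TPM expression with per-gene location/scale, a minority of genes whose
effect on progression hazard exists only under ICI treatment (predictive,
arm x gene interaction), a set of prognostic-only genes acting in both
arms, and the remainder null.  Event times are Weibull (exponential by
default) with independent uniform censoring calibrated to a target
censoring fraction; OS is PFS plus an independent exponential
post-progression tail, which makes the PFS signal stronger than the OS
signal by construction.

Effect genes are co-expressed: the predictive genes share a latent
"ICI-benefit program" and the prognostic genes a "prognosis program"
(within-block correlation ``rho``), and the hazard acts on the
standardized program scores, so ``beta_interaction``/``beta_prognostic``
are log-hazard-ratios per SD of the underlying signature.  The implied
marginal per-gene log-HR, ``beta * sqrt(rho + (1 - rho)/k)`` for a block
of k genes, is recorded in the ground truth.  With a single effect gene
the gene is the signature and beta is its per-SD log-HR exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import ClinicalTable, CohortDataset, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BatchSpec:
    """Location/scale shift per batch applied to log-scale expression."""

    loc_shifts: tuple[float, ...] = (0.0,)
    scale_shifts: tuple[float, ...] = (1.0,)

    @property
    def n_batches(self) -> int:
        return len(self.loc_shifts)

    def __post_init__(self):
        if len(self.loc_shifts) != len(self.scale_shifts):
            raise ValueError("loc_shifts and scale_shifts must have equal length")
        if any(s == 0 for s in self.scale_shifts):
            raise ValueError("scale shift of 0 is degenerate")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-arm cohort.

    Defaults mirror a second-line NSCLC trial: ~600 patients randomized
    1:1, baseline PFS hazard 0.2/month (median ~3.5 months on chemo),
    ~30% censoring, 30 predictive genes (arm x gene log-HR -0.8 per SD)
    and 50 prognostic-only genes (log-HR -0.8 per SD) among 2000.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_predictive: int = 30
    n_prognostic: int = 50
    beta_interaction: float = -0.8
    beta_prognostic: float = -0.8
    rho_predictive: float = 0.8
    rho_prognostic: float = 0.8
    arm_loghr: float = 0.0
    baseline_hazard: float = 0.2
    censor_rate: float = 0.3
    arm_ratio: float = 0.5
    os_tail_hazard: float = 0.08
    weibull_shape: float = 1.0
    batch_spec: BatchSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples, self.n_genes, self.n_predictive, self.n_prognostic) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_predictive + self.n_prognostic > self.n_genes:
            raise ValueError("n_predictive + n_prognostic exceeds n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0 < self.arm_ratio < 1:
            raise ValueError("arm_ratio must be in (0, 1)")
        if not (0 <= self.rho_predictive <= 1 and 0 <= self.rho_prognostic <= 1):
            raise ValueError("block correlations must be in [0, 1]")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("hazard parameters must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted with each simulated cohort (the recovery oracle)."""

    predictive_genes: frozenset
    prognostic_genes: frozenset
    main_loghr: dict
    interaction_loghr: dict
    latent_risk: np.ndarray        # realized linear predictor (arm-dependent)
    ici_latent_risk: np.ndarray    # linear predictor as if everyone got ICI
    batch_labels: np.ndarray | None = None

    def __post_init__(self):
        if self.predictive_genes & self.prognostic_genes:
            raise ValueError("predictive and prognostic gene sets must be disjoint")


def _calibrate_censor_horizon(event_times: np.ndarray, target: float,
                              max_iter: int = 200) -> float:
    """Find c so that C ~ U(0, c) censors the realized times at `target` rate.

    E[censored | T] = mean(min(T / c, 1)) is monotone decreasing in c;
    solved by bisection on a bounded bracket.
    """
    lo, hi = 1e-9, float(event_times.max()) * 1e6 + 1.0

    def frac(c):
        return float(np.mean(np.minimum(event_times / c, 1.0)))

    if frac(hi) > target or frac(lo) < target:
        raise RuntimeError("censoring calibration infeasible for this target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig) -> tuple[CohortDataset, SimulationTruth]:
    """Generate one cohort plus its ground truth. Bitwise-reproducible by seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_genes

    gene_ids = tuple(f"G{i + 1:05d}" for i in range(p))
    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n))

    roles = rng.permutation(p)
    pred_idx = np.sort(roles[: cfg.n_predictive])
    prog_idx = np.sort(roles[cfg.n_predictive: cfg.n_predictive + cfg.n_prognostic])

    mu = rng.uniform(1.0, 5.0, size=p)
    sigma = rng.uniform(0.4, 1.2, size=p)
    z = rng.standard_normal((p, n))

    # co-expression: effect blocks load on shared latent program scores
    f_benefit = rng.standard_normal(n)
    f_prognosis = rng.standard_normal(n)

    def _block_score(idx, factor, rho):
        k = idx.size
        if k == 0:
            return np.zeros(n)
        z[idx] = np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * z[idx]
        zbar = z[idx].mean(axis=0)
        return zbar / np.sqrt(rho + (1.0 - rho) / k)    # theoretical SD

    benefit_score = _block_score(pred_idx, f_benefit, cfg.rho_predictive)
    prognosis_score = _block_score(prog_idx, f_prognosis, cfg.rho_prognostic)
    expr_vals = mu[:, None] + sigma[:, None] * z    # log-TPM scale

    # balanced randomization to the ICI arm
    n_io = int(round(cfg.arm_ratio * n))
    arm_io = np.zeros(n, dtype=bool)
    arm_io[rng.permutation(n)[:n_io]] = True

    lp_main = cfg.beta_prognostic * prognosis_score
    lp_inter = cfg.beta_interaction * benefit_score
    lp = lp_main + arm_io * (lp_inter + cfg.arm_loghr)
    lp_ici = lp_main + lp_inter + cfg.arm_loghr

    # implied marginal per-gene log-HR per SD of a single block gene
    def _marginal(beta, rho, k):
        return float(beta * np.sqrt(rho + (1.0 - rho) / k)) if k else 0.0

    main_marg = _marginal(cfg.beta_prognostic, cfg.rho_prognostic, prog_idx.size)
    inter_marg = _marginal(cfg.beta_interaction, cfg.rho_predictive, pred_idx.size)

    # Weibull event times: h(t) = h0 * k * t^(k-1) * exp(lp)
    u = rng.uniform(size=n)
    k = cfg.weibull_shape
    t_pfs = (-np.log(u) / (cfg.baseline_hazard * np.exp(lp))) ** (1.0 / k)

    if cfg.censor_rate == 0:
        pfs_obs, pfs_event = t_pfs, np.ones(n, dtype=int)
        cens = np.full(n, np.inf)
    else:
        horizon = _calibrate_censor_horizon(t_pfs, cfg.censor_rate)
        cens = rng.uniform(0.0, horizon, size=n)
        pfs_event = (t_pfs <= cens).astype(int)
        pfs_obs = np.minimum(t_pfs, cens)

    t_os = t_pfs + rng.exponential(1.0 / cfg.os_tail_hazard, size=n)
    os_event = (t_os <= cens).astype(int)
    os_obs = np.minimum(t_os, cens)

    # best overall response: responder probability increases with benefit
    s = -lp
    if np.std(lp) > 0:
        s = (s - s.mean()) / s.std()
    p_resp = expit(-0.8 + 1.2 * s)
    responder = rng.uniform(size=n) < p_resp
    cr = responder & (rng.uniform(size=n) < 0.07)
    sd = ~responder & (rng.uniform(size=n) < expit(0.3 + 0.5 * s))
    bor = np.where(cr, "CR", np.where(responder, "PR", np.where(sd, "SD", "PD")))
    bor = np.where(rng.uniform(size=n) < 0.05, "NE", bor)

    tps = np.round(np.clip(rng.normal(35 + 8 * s, 30), 0, 100), 1)
    tmb = np.round(np.exp(rng.normal(2.0 + 0.25 * s, 0.6)), 2)

    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "arm": np.where(arm_io, "IO", "Chemo"),
        "pfs_months": np.round(pfs_obs, 6),
        "pfs_event": pfs_event,
        "os_months": np.round(os_obs, 6),
        "os_event": os_event,
        "tps_pct": tps,
        "tmb": tmb,
        "bor": bor,
    }))

    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                            values=expr_vals, scale="log_tpm")

    batch_labels = None
    if cfg.batch_spec is not None and cfg.batch_spec.n_batches > 1:
        batch_labels = rng.integers(0, cfg.batch_spec.n_batches, size=n)
        expr = inject_batch_effect(expr, batch_labels, cfg.batch_spec)

    truth = SimulationTruth(
        predictive_genes=frozenset(gene_ids[i] for i in pred_idx),
        prognostic_genes=frozenset(gene_ids[i] for i in prog_idx),
        main_loghr={gene_ids[i]: main_marg for i in prog_idx},
        interaction_loghr={gene_ids[i]: inter_marg for i in pred_idx},
        latent_risk=lp,
        ici_latent_risk=lp_ici,
        batch_labels=batch_labels,
    )
    return CohortDataset(expr, clinical), truth


def inject_batch_effect(expr: ExpressionMatrix, batch_labels,
                        shifts: BatchSpec) -> ExpressionMatrix:
    """Apply per-batch location/scale shifts to log-scale expression:
    x' = loc[b] + scale[b] * x."""
    if expr.scale != "log_tpm":
        raise ValueError("batch effects are injected on log-scale expression")
    labels = np.asarray(batch_labels)
    if labels.shape != (expr.n_samples,):
        raise ValueError("batch label length does not match sample count")
    if labels.min() < 0 or labels.max() >= shifts.n_batches:
        raise ValueError("batch label outside the declared number of batches")
    loc = np.asarray(shifts.loc_shifts, dtype=float)[labels]
    scale = np.asarray(shifts.scale_shifts, dtype=float)[labels]
    vals = loc[None, :] + scale[None, :] * expr.values
    return ExpressionMatrix(gene_ids=expr.gene_ids, sample_ids=expr.sample_ids,
                            values=vals, scale=expr.scale)
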