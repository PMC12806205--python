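"""Reference database for single-sample prediction.

A frozen bundle of: an ICI-treated reference cohort (log-TPM expression +
PFS), the trained forest, the PFS-optimal score cutoff computed on the
reference, the reference score table, and per-gene reference moments.
Incoming samples are batch-adjusted onto the reference (the reference
itself is never modified), scored, and classified against the frozen
cutoff: score > cutoff -> predicted benefit.

Batch adjustment is an empirical-Bayes location/scale correction on the
log scale with the reference as the frozen target.  Per-gene batch
location effects get a normal prior whose hyperparameters are
moment-matched across genes with the sampling-noise contribution removed;
a batch whose shift is exactly constant across genes therefore yields a
degenerate prior and is removed exactly, while a single sample collapses
to a global (scalar) shift, preserving its gene-level biology.  Scale
effects are shrunk on the log-variance-ratio scale and skipped for
single-sample batches.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (ClinicalTable, CohortDataset, ExpressionMatrix,
                        read_clinical, read_expression, write_clinical,
                        write_expression)
from .forest import SurvivalForestModel
from .model import predict_score
from .stratify import CutoffResult, best_cutoff

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceDatabase:
    expr: ExpressionMatrix            # log-TPM, reference cohort
    clinical: ClinicalTable           # ICI-treated, PFS available
    model: SurvivalForestModel
    cutoff: CutoffResult
    ref_scores: pd.DataFrame          # sample_id, lira_score
    gene_mean: pd.Series              # frozen per-gene moments
    gene_var: pd.Series

    def version_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.expr.values.tobytes())
        h.update(",".join(self.expr.gene_ids).encode())
        h.update(self.clinical.df.to_csv(index=False).encode())
        h.update(self.model.archive_hash().encode())
        h.update(json.dumps({"cutoff": self.cutoff.cutoff,
                             "stat": self.cutoff.statistic}).encode())
        return h.hexdigest()


def build_reference(ici_cohort: CohortDataset,
                    model: SurvivalForestModel) -> ReferenceDatabase:
    """Score the reference cohort, freeze its moments, and fix the cutoff."""
    if not all(ici_cohort.clinical.is_ici()):
        raise ValueError("reference cohort must be ICI-treated")
    if ici_cohort.expr.scale != "log_tpm":
        raise ValueError("reference expression must be log_tpm")
    missing = [g for g in model.genes if g not in set(ici_cohort.expr.gene_ids)]
    if missing:
        raise ValueError(f"model genes absent from reference: {missing}")
    scores = predict_score(model, ici_cohort.expr)
    df = ici_cohort.clinical.df
    cut = best_cutoff(scores["lira_score"].to_numpy(),
                      df["pfs_months"].to_numpy(), df["pfs_event"].to_numpy())
    vals = ici_cohort.expr.values
    gene_mean = pd.Series(vals.mean(axis=1), index=list(ici_cohort.expr.gene_ids))
    gene_var = pd.Series(vals.var(axis=1, ddof=1), index=list(ici_cohort.expr.gene_ids))
    return ReferenceDatabase(expr=ici_cohort.expr, clinical=ici_cohort.clinical,
                             model=model, cutoff=cut, ref_scores=scores,
                             gene_mean=gene_mean, gene_var=gene_var)


def _shrunk_global_shift(refdb: ReferenceDatabase, shared_genes,
                         gamma_bar_raw: float, m: int) -> float:
    """EB-shrunk global location shift of a new batch.

    The null SD of the observed batch-mean deviation for an
    in-distribution batch of size m is sqrt(v0/m), where v0 is the
    between-sample variance of the per-sample mean deviation within the
    reference itself.  A shift within 3 null-SDs is indistinguishable from
    biology and left alone; one beyond 6 null-SDs is an unambiguous batch
    effect and removed in full; in between the correction ramps linearly.
    """
    gidx = {g: i for i, g in enumerate(refdb.expr.gene_ids)}
    rows = np.array([gidx[g] for g in shared_genes])
    ref_mu = refdb.gene_mean.loc[list(shared_genes)].to_numpy()
    dev = refdb.expr.values[rows, :] - ref_mu[:, None]
    v0 = float(dev.mean(axis=0).var(ddof=1))
    sd_null = np.sqrt(v0 / m) if v0 > 0 else 0.0
    if sd_null == 0.0:
        return gamma_bar_raw
    a = abs(gamma_bar_raw) / sd_null
    f = float(np.clip((a - 3.0) / 3.0, 0.0, 1.0))
    return f * gamma_bar_raw


def batch_adjust(refdb: ReferenceDatabase, new_expr: ExpressionMatrix,
                 mode: str = "reference_anchored") -> ExpressionMatrix:
    """Map a new batch onto the frozen reference moments (EB location/scale).

    Only ``mode='reference_anchored'`` is supported: the reference is the
    target and is never modified.  Requires the new batch to share at least
    50% of the model genes with the reference.
    """
    if mode != "reference_anchored":
        raise ValueError("only reference_anchored adjustment is supported; "
                         "modes that modify the reference are forbidden")
    if new_expr.scale != "log_tpm":
        raise ValueError("new expression must be log_tpm")
    shared_model = [g for g in refdb.model.genes if g in set(new_expr.gene_ids)]
    if len(shared_model) * 2 < len(refdb.model.genes):
        raise ValueError("new batch shares fewer than 50% of model genes "
                         "with the reference")
    shared = [g for g in new_expr.gene_ids if g in refdb.gene_mean.index]
    gidx = {g: i for i, g in enumerate(new_expr.gene_ids)}
    rows = np.array([gidx[g] for g in shared])
    X = new_expr.values[rows, :]           # shared genes x m new samples
    m = X.shape[1]
    ref_mu = refdb.gene_mean.loc[shared].to_numpy()
    ref_var = refdb.gene_var.loc[shared].to_numpy()

    batch_mu = X.mean(axis=1)
    gamma_hat = batch_mu - ref_mu          # raw-scale location batch effect
    if m >= 2:
        s2 = X.var(axis=1, ddof=1)
    else:
        s2 = ref_var.copy()
    # Two-level EB on the location effect.
    #
    # Global level: the batch-wide shift gamma_bar is itself an estimate
    # whose null variance (no batch effect, samples drawn from the
    # reference population) is v0/m, with v0 the reference's own
    # between-sample variance of the mean deviation.  Shrink gamma_bar by
    # f = 1 - (v0/m)/gamma_bar^2 (clipped to [0, 1]); an in-distribution
    # batch therefore receives ~no global correction, while a shift that
    # stands far outside the null is treated as fully identified (f
    # saturates to 1) and removed exactly.
    #
    # Per-gene level: normal prior moment-matched across genes with the
    # sampling-noise contribution removed; a batch whose shift is constant
    # across genes has tau2 = 0 (degenerate prior), and a single sample
    # never gets per-gene corrections (batch and biology confounded).
    gamma_bar_raw = float(gamma_hat.mean())
    gamma_bar = _shrunk_global_shift(refdb, shared, gamma_bar_raw, m)
    if m == 1:
        tau2 = 0.0
    else:
        tau2 = max(float(gamma_hat.var()) - float(s2.mean()) / m, 0.0)
    noise = s2 / m
    if tau2 == 0.0:
        gamma_star = np.full_like(gamma_hat, gamma_bar)
    else:
        w = tau2 / (tau2 + noise)
        gamma_star = gamma_bar + w * (gamma_hat - gamma_bar_raw)

    # EB scale: shrink log variance ratios; skipped for single samples
    if m >= 3:
        zero_var = s2 <= 0
        if zero_var.any():
            log.warning("scale step skipped for %d zero-variance gene(s)",
                        int(zero_var.sum()))
        ratio = np.where(zero_var | (ref_var <= 0), 1.0,
                         s2 / np.where(ref_var > 0, ref_var, 1.0))
        lam = np.log(ratio)
        lam_noise = 2.0 / (m - 1)
        lam_tau2 = max(float(lam.var()) - lam_noise, 0.0)
        lam_bar = float(lam.mean())
        if lam_tau2 == 0.0:
            lam_star = np.full_like(lam, lam_bar)
        else:
            wl = lam_tau2 / (lam_tau2 + lam_noise)
            lam_star = lam_bar + wl * (lam - lam_bar)
        scale = np.exp(0.5 * lam_star)
        scale = np.where(zero_var, 1.0, scale)
    else:
        if m == 1:
            log.warning("single-sample batch: scale adjustment skipped")
        scale = np.ones_like(gamma_hat)

    X_adj = (X - batch_mu[:, None]) / scale[:, None] + (batch_mu - gamma_star)[:, None]
    out = new_expr.values.copy()
    out[rows, :] = X_adj
    return replace(new_expr, values=out)


def score_samples(refdb: ReferenceDatabase, new_expr: ExpressionMatrix) -> pd.DataFrame:
    """Batch-adjust, score, and classify new samples against the frozen cutoff.

    Returns sample_id, lira_score, predicted_class (benefit iff score >
    cutoff), and the list of omitted model genes.
    """
    if new_expr.n_samples == 0:
        raise ValueError("empty expression matrix")
    adjusted = batch_adjust(refdb, new_expr)
    scores = predict_score(refdb.model, adjusted)
    present = set(new_expr.gene_ids)
    omitted = [g for g in refdb.model.genes if g not in present]
    scores["predicted_class"] = np.where(
        scores["lira_score"] > refdb.cutoff.cutoff, "benefit", "no_benefit")
    scores["omitted_genes"] = [";".join(omitted)] * len(scores)
    return scores


# ---- directory bundle ------------------------------------------------

def save_reference(refdb: ReferenceDatabase, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_expression(refdb.expr, d / "reference_expression.tsv")
    write_clinical(refdb.clinical, d / "reference_clinical.csv")
    refdb.model.save(d / "model.json")
    with open(d / "cutoff.json", "w") as fh:
        json.dump({"cutoff": refdb.cutoff.cutoff,
                   "statistic": refdb.cutoff.statistic,
                   "p_naive": refdb.cutoff.p_naive,
                   "minprop": refdb.cutoff.minprop,
                   "n_low": refdb.cutoff.n_low,
                   "n_high": refdb.cutoff.n_high,
                   "selection_biased_p": True}, fh, indent=1)
    refdb.ref_scores.to_csv(d / "reference_scores.csv", index=False)
    with open(d / "manifest.json", "w") as fh:
        json.dump({"version_hash": refdb.version_hash()}, fh)


def load_reference(directory) -> ReferenceDatabase:
    d = Path(directory)
    expr = read_expression(d / "reference_expression.tsv", scale_hint="log_tpm")
    clinical = read_clinical(d / "reference_clinical.csv")
    model = SurvivalForestModel.load(d / "model.json")
    cohort = CohortDataset(expr, clinical)
    refdb = build_reference(cohort, model)
    manifest = json.loads((d / "manifest.json").read_text())
    if refdb.version_hash() != manifest["version_hash"]:
        raise ValueError("reference bundle hash mismatch; bundle corrupted")
    return refdb
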