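"""Evaluation suite: time-dependent AUC, marker models, HR/KM reports,
decision curves, response-rate tables, and durable-clinical-benefit labels.

The time-dependent AUC is the cumulative-case / dynamic-control estimator
with inverse-probability-of-censoring weights (IPCW) from the Kaplan-Meier
estimate of the censoring distribution; without censoring it reduces
exactly to the Mann-Whitney AUC.  Scores follow the package convention:
higher score = lower predicted risk, so risk = -score internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_io import BOR_CODES, CohortDataset
from .survstats import CoxFit, KMCurve, fit_cox, km_estimate, logrank_test

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AucResult:
    horizon: float
    auc: float
    method: str
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class MarkerModel:
    markers: tuple[str, ...]
    fit: CoxFit
    linear_predictor: pd.Series     # risk scale: higher = worse


@dataclass(frozen=True)
class ResponseSummary:
    counts: pd.DataFrame            # groups x BOR categories
    percentages: pd.DataFrame
    orr: pd.Series
    include_ne_in_denominator: bool


def _censoring_km(times, events):
    """KM of the censoring distribution G(t) (events flipped)."""
    return km_estimate(times, 1 - np.asarray(events))


def _km_eval(curve: KMCurve, t, left: bool = False):
    """Step-function evaluation of a KM curve at times t (left limit opt.)."""
    side = "left" if left else "right"
    idx = np.searchsorted(curve.times, np.asarray(t, dtype=float), side=side) - 1
    idx = np.clip(idx, 0, curve.survival.size - 1)
    return curve.survival[idx]


def time_dependent_auc(scores, times, events, horizon) -> AucResult:
    """IPCW cumulative/dynamic AUC at `horizon` months.

    Cases: events by the horizon; controls: still at risk past it.  Case
    weights 1/G(T-), control weights 1/G(horizon).  Higher score = lower
    risk; tied risks get half credit.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if not 0 < horizon <= t.max():
        raise ValueError("horizon must be positive and within observed follow-up")
    risk = -s
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("no cases or no controls at this horizon")
    G = _censoring_km(t, e)
    w_case = 1.0 / np.clip(_km_eval(G, t[cases], left=True), 1e-12, None)
    g_h = float(np.clip(_km_eval(G, horizon), 1e-12, None))
    w_ctrl = np.full(int(controls.sum()), 1.0 / g_h)

    rc = risk[cases][:, None]
    rn = risk[controls][None, :]
    W = w_case[:, None] * w_ctrl[None, :]
    conc = (rc > rn) * 1.0 + (rc == rn) * 0.5
    auc = float((W * conc).sum() / W.sum())
    return AucResult(horizon=float(horizon), auc=auc, method="ipcw-km",
                     n_cases=int(cases.sum()), n_controls=int(controls.sum()))


def compare_auc(score_a, score_b, times, events, horizon,
                B: int = 1000, seed: int = 0):
    """Paired bootstrap comparison of two time-dependent AUCs.

    Returns (delta_auc, p) with delta = AUC_a - AUC_b on the full sample
    and a two-sided normal p from delta / SE_bootstrap.  Identical scores
    give delta 0 and p = 1.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if a.shape != b.shape or a.shape != t.shape:
        raise ValueError("scores must be paired on the same samples")
    delta = (time_dependent_auc(a, t, e, horizon).auc
             - time_dependent_auc(b, t, e, horizon).auc)
    rng = np.random.default_rng(seed)
    n = t.size
    deltas = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            d = (time_dependent_auc(a[idx], t[idx], e[idx], horizon).auc
                 - time_dependent_auc(b[idx], t[idx], e[idx], horizon).auc)
        except ValueError:
            continue
        deltas.append(d)
    se = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
    if se == 0.0:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        p = float(2.0 * sps.norm.sf(abs(delta) / se))
    return float(delta), p


def combined_marker_model(cohort: CohortDataset, markers,
                          scores: pd.Series | None = None,
                          endpoint: str = "pfs") -> MarkerModel:
    """Cox model combining markers from {lira, tps, tmb} (complete-case).

    ``scores`` supplies the per-sample model score when 'lira' is among the
    markers (indexed by sample_id).  The combined score is the fitted
    linear predictor (risk scale).
    """
    markers = tuple(markers)
    df = cohort.clinical.df.set_index("sample_id")
    cols = {}
    for mk in markers:
        if mk == "lira":
            if scores is None:
                raise ValueError("marker 'lira' requires a scores series")
            cols[mk] = scores.reindex(df.index)
        elif mk == "tps":
            cols[mk] = df["tps_pct"]
        elif mk == "tmb":
            cols[mk] = df["tmb"]
        else:
            raise ValueError(f"unknown marker {mk!r}")
    M = pd.DataFrame(cols)
    for mk in markers:
        if M[mk].isna().all():
            raise ValueError(f"marker {mk!r} is missing for all samples")
    keep = M.notna().all(axis=1)
    M = M.loc[keep]
    endpoint_cols = ("pfs_months", "pfs_event") if endpoint == "pfs" else \
        ("os_months", "os_event")
    times = df.loc[keep, endpoint_cols[0]].to_numpy()
    events = df.loc[keep, endpoint_cols[1]].to_numpy()
    fit = fit_cox(times, events, M.to_numpy(), names=markers)
    lp = pd.Series(M.to_numpy() @ fit.coef, index=M.index, name="combined_score")
    return MarkerModel(markers=markers, fit=fit, linear_predictor=lp)


def hazard_ratio_report(cohort: CohortDataset, group_labels,
                        endpoint: str = "pfs"):
    """HR of high vs low (low = reference), per-group KM curves, log-rank p."""
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    df = cohort.clinical.df
    tcol, ecol = ("pfs_months", "pfs_event") if endpoint == "pfs" else \
        ("os_months", "os_event")
    times = df[tcol].to_numpy()
    events = df[ecol].to_numpy()
    ref, other = ("low", "high") if set(uniq) == {"low", "high"} else uniq
    ind = (labels == other).astype(float)
    fit = fit_cox(times, events, ind, names=(f"{other}_vs_{ref}",))
    curves = {g: km_estimate(times[labels == g], events[labels == g]) for g in uniq}
    lr = logrank_test(times, events, labels)
    return fit, curves, lr


def decision_curve(scores_or_classes, times, events, horizon,
                   thresholds) -> pd.DataFrame:
    """Net benefit per threshold probability pt.

    NB(pt) = TP/n - (FP/n) * pt/(1-pt), with event status at the horizon
    handled by IPCW (exact 2x2 counts when uncensored).  Input is either a
    predicted event-probability per sample (positive when >= pt) or a
    binary class (positive when 1, threshold-independent).  Also emits the
    treat-all and treat-none reference policies.
    """
    x = np.asarray(scores_or_classes, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    if horizon > t.max():
        raise ValueError("horizon beyond observed follow-up")
    is_class = set(np.unique(x)) <= {0.0, 1.0}

    G = _censoring_km(t, e)
    event_by_h = (t <= horizon) & (e == 1)
    at_risk_after = t > horizon
    w = np.zeros(t.size)
    w[event_by_h] = 1.0 / np.clip(_km_eval(G, t[event_by_h], left=True), 1e-12, None)
    w[at_risk_after] = 1.0 / np.clip(_km_eval(G, horizon), 1e-12, None)
    n = t.size

    rows = []
    for pt in thresholds:
        pos = x == 1 if is_class else x >= pt
        tp = float(w[pos & event_by_h].sum()) / n
        fp = float(w[pos & at_risk_after].sum()) / n
        odds = pt / (1 - pt)
        prev = float(w[event_by_h].sum()) / n
        fp_all = float(w[at_risk_after].sum()) / n
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * odds,
            "treat_all": prev - fp_all * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def response_rates(clinical_by_group, include_ne: bool = True,
                   sig_figs: int = 3) -> ResponseSummary:
    """Per-group BOR counts and percentages (of group n), plus ORR = CR+PR.

    ``clinical_by_group`` maps group name -> iterable of BOR codes.
    Percentages are rounded to ``sig_figs`` significant figures and always
    recompute from the stored counts.
    """
    counts = {}
    for group, bors in clinical_by_group.items():
        bors = list(bors)
        bad = sorted({b for b in bors if b not in BOR_CODES})
        if bad:
            raise ValueError(f"unknown BOR codes in group {group!r}: {bad}")
        counts[group] = {c: bors.count(c) for c in BOR_CODES}
    cdf = pd.DataFrame(counts).T[list(BOR_CODES)]
    totals = cdf.sum(axis=1)
    pdf = cdf.apply(lambda col: [
        percent(c, n, sig_figs) for c, n in zip(col, totals)])
    denom = totals if include_ne else totals - cdf["NE"]
    orr = pd.Series({g: percent(cdf.loc[g, "CR"] + cdf.loc[g, "PR"], denom[g], sig_figs)
                     for g in cdf.index})
    return ResponseSummary(counts=cdf, percentages=pdf, orr=orr,
                           include_ne_in_denominator=include_ne)


def percent(count, n, sig_figs: int = 3) -> float:
    """Percentage rounded to `sig_figs` significant figures (0 -> 0.0)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * count / n
    if pct == 0:
        return 0.0
    digits = sig_figs - 1 - int(math.floor(math.log10(abs(pct))))
    return round(pct, digits)


def dcb_label(bor: str, pfs_months: float) -> str:
    """Durable clinical benefit: CR/PR, or SD lasting strictly > 6 months.

    PD, or SD lasting <= 6 months, is no durable benefit; NE stays NE.
    """
    if bor not in BOR_CODES:
        raise ValueError(f"unknown BOR code {bor!r}")
    if bor in ("CR", "PR"):
        return "DCB"
    if bor == "SD":
        return "DCB" if pfs_months > 6 else "NDB"
    if bor == "PD":
        return "NDB"
    return "NE"
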