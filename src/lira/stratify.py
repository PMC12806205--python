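"""Score-based patient stratification.

Two rules: the cohort-mean threshold (the headline grouping rule) and a
maximally selected log-rank cutpoint on PFS (used to freeze the reference
cutoff for single-sample prediction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .survstats import logrank_test

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutoffResult:
    """Maximally selected log-rank cutpoint.

    ``p_naive`` is the log-rank p at the selected cutpoint WITHOUT any
    correction for having searched over candidates (selection-biased); it
    is reported for transparency, not inference.
    """

    cutoff: float
    statistic: float          # |standardized log-rank| at the cutoff
    p_naive: float
    minprop: float
    n_low: int
    n_high: int
    candidates: np.ndarray


def mean_split(scores) -> np.ndarray:
    """Label samples 'high' when score > mean(scores), else 'low'.

    Ties at exactly the mean go to 'low'.  All-identical scores yield all
    'low' with a warning.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(s) == 0:
        log.warning("all scores identical; every sample labelled 'low'")
        return np.full(s.size, "low", dtype=object)
    return np.where(s > s.mean(), "high", "low").astype(object)


def best_cutoff(scores, pfs_times, pfs_events, minprop: float = 0.1) -> CutoffResult:
    """Cutpoint maximizing |standardized two-sample log-rank statistic|.

    Candidates are the unique score values v splitting into low (score <= v)
    and high (score > v) groups of at least ceil(minprop * n) samples each.
    Ties in the statistic break toward the smaller cutoff.  The returned
    cutoff is the midpoint between the selected value and the next unique
    score, so no sample sits exactly on the threshold.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(pfs_times, dtype=float)
    e = np.asarray(pfs_events).astype(int)
    n = s.size
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    min_n = int(np.ceil(minprop * n))
    uniq = np.unique(s)
    best = None
    candidates = []
    for v in uniq[:-1]:
        low = s <= v
        if low.sum() < min_n or (~low).sum() < min_n:
            continue
        candidates.append(v)
        if e[low].sum() == 0 and e[~low].sum() == 0:
            continue
        try:
            res = logrank_test(t, e, np.where(low, "low", "high"))
        except (ValueError, np.linalg.LinAlgError):
            continue
        stat = float(np.sqrt(max(res.statistic, 0.0)))
        if best is None or stat > best[0]:
            best = (stat, float(v), res.p)
    if best is None:
        raise ValueError("no candidate cutoff satisfies the minprop constraint "
                         "with events on both sides")
    stat, cut, p = best
    low = s <= cut
    next_up = uniq[np.searchsorted(uniq, cut, side="right")]
    cut = 0.5 * (cut + next_up)
    return CutoffResult(cutoff=cut, statistic=stat, p_naive=p, minprop=minprop,
                        n_low=int(low.sum()), n_high=int((~low).sum()),
                        candidates=np.asarray(candidates))
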