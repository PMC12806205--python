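import logging

import numpy as np
import pytest

from lira.forest import ForestParams
from lira.model import LiraConfig, build_lira
from lira.simdata import SimConfig, simulate_cohort

logging.getLogger("lira").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but signal-bearing two-arm cohort shared across tests."""
    cohort, truth = simulate_cohort(SimConfig(
        n_samples=240, n_genes=80, n_predictive=8, n_prognostic=10, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A trained model on the small cohort (cheap forest)."""
    cohort, truth = small_cohort
    cfg = LiraConfig(forest=ForestParams(n_trees=60), seed=11)
    return build_lira(cohort, cfg)


def naive_efron_loglik(beta, times, events, x):
    """Independent straight-loop Efron partial log-likelihood (1 covariate).

    Written directly from the defining formula with O(n^2) loops; used as
    the brute-force oracle for the Newton-Raphson fitter.
    """
    beta = float(beta)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.flatnonzero((times == t) & (events == 1))
        R = np.flatnonzero(times >= t)
        d = len(D)
        sum_d_eta = float(np.sum(beta * x[D]))
        S_R = float(np.sum(np.exp(beta * x[R])))
        S_D = float(np.sum(np.exp(beta * x[D])))
        ll += sum_d_eta
        for l in range(d):
            ll -= np.log(S_R - (l / d) * S_D)
    return ll


def grid_maximize(fun, lo=-5.0, hi=5.0):
    """Three-stage grid refinement down to step 1e-7."""
    for step in (1e-2, 1e-4, 1e-7):
        grid = np.arange(lo, hi + step / 2, step)
        vals = [fun(b) for b in grid]
        best = grid[int(np.argmax(vals))]
        lo, hi = best - 2 * step, best + 2 * step
    return float(best)
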