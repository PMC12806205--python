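"""Random survival forest with log-rank splitting.

Each tree is grown on a bootstrap sample; at each node the split maximizing
the absolute standardized two-sample log-rank statistic is chosen among
``mtry`` randomly drawn candidate genes, subject to a minimum number of
events per child.  Leaves store the Nelson-Aalen cumulative hazard of their
in-bag members evaluated on the shared grid of training event times; the
ensemble survival curve is the across-tree mean of exp(-CHF), and the
model's score is its restricted mean event-free time up to tau, the maximum
training follow-up (months; higher = lower predicted risk).

Samples whose expression lacks the gene used at a split are routed to both
children with halved weight, so scores degrade gracefully when model genes
are missing from an input matrix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from .survstats import concordance_index

log = logging.getLogger(__name__)

ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 1000
    mtry: int | None = None          # default ceil(sqrt(p))
    min_leaf_events: int = 3
    max_depth: int | None = None
    bootstrap: bool = True

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else int(np.ceil(np.sqrt(p)))
        return max(1, min(m, p))


@dataclass
class _Tree:
    feature: np.ndarray       # int, -1 at leaves
    threshold: np.ndarray     # split value; go left when x <= threshold
    left: np.ndarray
    right: np.ndarray
    leaf_id: np.ndarray       # row into leaf_chf, -1 at internal nodes
    leaf_chf: np.ndarray      # (n_leaves, n_grid) cumulative hazard
    oob: np.ndarray           # indices of out-of-bag training samples


def _best_split(x, times, events, min_leaf_events):
    """Best split of one feature by |standardized log-rank statistic|.

    Returns (|stat|, threshold) or None when no admissible split exists.
    Candidate thresholds are the unique feature values; left = x <= v.
    Ties in the statistic resolve to the smaller threshold.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    t = times[order]
    e = events[order]
    et = np.unique(t[e == 1])
    if et.size == 0:
        return None
    pos = np.flatnonzero(xs[:-1] < xs[1:])
    if pos.size == 0:
        return None

    risk = t[:, None] >= et[None, :]
    died = (e[:, None] == 1) & (t[:, None] == et[None, :])
    cum_risk = np.cumsum(risk, axis=0)
    cum_died = np.cumsum(died, axis=0)
    nk = cum_risk[-1].astype(float)
    dk = cum_died[-1].astype(float)

    n1 = cum_risk[pos].astype(float)
    d1 = cum_died[pos].astype(float)
    O1 = d1.sum(axis=1)
    frac = n1 / nk[None, :]
    E1 = (dk[None, :] * frac).sum(axis=1)
    denom = np.maximum(nk - 1.0, 1.0)
    V = (dk[None, :] * frac * (1.0 - frac) * ((nk - dk) / denom)[None, :]).sum(axis=1)

    ev_left = np.cumsum(e)[pos]
    ev_right = e.sum() - ev_left
    valid = (ev_left >= min_leaf_events) & (ev_right >= min_leaf_events) & (V > 0)
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(O1 - E1) / np.sqrt(V)
    stat[~valid] = -np.inf
    best = int(np.argmax(stat))     # first max -> smallest threshold
    return float(stat[best]), float(xs[pos[best]])


def _nelson_aalen_on_grid(times, events, grid):
    """Nelson-Aalen CHF of one leaf's members, evaluated on `grid`."""
    et = np.unique(times[events == 1])
    if et.size == 0:
        return np.zeros(grid.size)
    d = np.array([(times[events == 1] == s).sum() for s in et], dtype=float)
    n_at = np.array([(times >= s).sum() for s in et], dtype=float)
    chf = np.cumsum(d / n_at)
    idx = np.searchsorted(et, grid, side="right")
    return np.concatenate(([0.0], chf))[idx]


def _grow_tree(X, times, events, params: ForestParams, rng, grid):
    n, p = X.shape
    mtry = params.resolved_mtry(p)
    if params.bootstrap:
        inbag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), inbag)
    else:
        inbag = np.arange(n)
        oob = np.array([], dtype=int)

    feature, threshold, left, right, leaf_id = [], [], [], [], []
    leaf_chf = []

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf_id.append(-1)
        return len(feature) - 1

    def make_leaf(node, idx):
        leaf_id[node] = len(leaf_chf)
        leaf_chf.append(_nelson_aalen_on_grid(times[idx], events[idx], grid))

    stack = [(new_node(), inbag, 0)]
    while stack:
        node, idx, depth = stack.pop()
        t_n, e_n = times[idx], events[idx]
        n_ev = int(e_n.sum())
        if (n_ev < 2 * params.min_leaf_events
                or (params.max_depth is not None and depth >= params.max_depth)):
            make_leaf(node, idx)
            continue
        cand = rng.permutation(p)[:mtry]
        best = None
        for f in np.sort(cand):
            res = _best_split(X[idx, f], t_n, e_n, params.min_leaf_events)
            if res is not None and (best is None or res[0] > best[0]):
                best = (res[0], f, res[1])
        if best is None:
            make_leaf(node, idx)
            continue
        _, f, thr = best
        go_left = X[idx, f] <= thr
        feature[node] = int(f)
        threshold[node] = thr
        l_node, r_node = new_node(), new_node()
        left[node], right[node] = l_node, r_node
        stack.append((r_node, idx[~go_left], depth + 1))
        stack.append((l_node, idx[go_left], depth + 1))

    return _Tree(
        feature=np.array(feature, dtype=np.int32),
        threshold=np.array(threshold, dtype=float),
        left=np.array(left, dtype=np.int32),
        right=np.array(right, dtype=np.int32),
        leaf_id=np.array(leaf_id, dtype=np.int32),
        leaf_chf=np.array(leaf_chf, dtype=float)
        if leaf_chf else np.zeros((0, grid.size)),
        oob=oob,
    )


def _route(tree: _Tree, X: np.ndarray) -> np.ndarray:
    """Leaf index for each row of X (no missing features). Vectorized."""
    node = np.zeros(X.shape[0], dtype=np.int32)
    while True:
        f = tree.feature[node]
        active = f >= 0
        if not active.any():
            break
        rows = np.flatnonzero(active)
        fa = f[rows]
        go_left = X[rows, fa] <= tree.threshold[node[rows]]
        node[rows] = np.where(go_left, tree.left[node[rows]], tree.right[node[rows]])
    return tree.leaf_id[node]


def _route_with_missing(tree: _Tree, X: np.ndarray, missing_mask: np.ndarray):
    """Leaf-weight matrix (n, n_leaves) when some features are missing.

    A sample reaching a split on a missing feature is sent to both children
    with halved weight.
    """
    n = X.shape[0]
    weights = np.zeros((n, tree.leaf_chf.shape[0]))
    frontier = [(0, np.ones(n))]
    while frontier:
        node, w = frontier.pop()
        f = tree.feature[node]
        if f < 0:
            weights[:, tree.leaf_id[node]] += w
            continue
        if missing_mask[f]:
            frontier.append((tree.left[node], w * 0.5))
            frontier.append((tree.right[node], w * 0.5))
        else:
            go_left = X[:, f] <= tree.threshold[node]
            frontier.append((tree.left[node], w * go_left))
            frontier.append((tree.right[node], w * (~go_left)))
    return weights


@dataclass
class SurvivalForestModel:
    """Trained survival forest plus everything needed to score new samples."""

    genes: tuple[str, ...]
    params: ForestParams
    grid: np.ndarray          # training event-time grid (months)
    tau: float                # max training follow-up
    trees: list[_Tree]
    seed: int
    train_rmst: float = float("nan")

    # ---- prediction -------------------------------------------------

    def ensemble_survival(self, X: np.ndarray,
                          missing_mask: np.ndarray | None = None) -> np.ndarray:
        """Mean over trees of exp(-leaf CHF); shape (n_samples, n_grid)."""
        n = X.shape[0]
        S = np.zeros((n, self.grid.size))
        for tree in self.trees:
            surv = np.exp(-tree.leaf_chf)
            if missing_mask is not None and missing_mask.any():
                w = _route_with_missing(tree, X, missing_mask)
                S += w @ surv
            else:
                S += surv[_route(tree, X)]
        return S / len(self.trees)

    def predict_rmst(self, X: np.ndarray,
                     missing_mask: np.ndarray | None = None) -> np.ndarray:
        """Restricted mean event-free time up to tau (months) per sample."""
        S = self.ensemble_survival(X, missing_mask)
        return _rmst_from_survival(S, self.grid, self.tau)

    def predict_mortality(self, X: np.ndarray) -> np.ndarray:
        """Ensemble mortality (summed CHF over the grid); higher = riskier."""
        m = np.zeros(X.shape[0])
        for tree in self.trees:
            m += tree.leaf_chf[_route(tree, X)].sum(axis=1)
        return m / len(self.trees)

    # ---- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "format_version": ARCHIVE_VERSION,
            "genes": list(self.genes),
            "params": {
                "n_trees": self.params.n_trees,
                "mtry": self.params.mtry,
                "min_leaf_events": self.params.min_leaf_events,
                "max_depth": self.params.max_depth,
                "bootstrap": self.params.bootstrap,
            },
            "grid": self.grid.tolist(),
            "tau": self.tau,
            "seed": self.seed,
            "train_rmst": self.train_rmst,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "leaf_id": t.leaf_id.tolist(),
                    "leaf_chf": t.leaf_chf.tolist(),
                    "oob": t.oob.tolist(),
                }
                for t in self.trees
            ],
        }
        d["config_hash"] = hashlib.sha256(
            json.dumps({k: d[k] for k in ("genes", "params", "seed")},
                       sort_keys=True).encode()
        ).hexdigest()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalForestModel":
        if d.get("format_version") != ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {d.get('format_version')!r}")
        grid = np.asarray(d["grid"], dtype=float)
        trees = [
            _Tree(
                feature=np.asarray(t["feature"], dtype=np.int32),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=np.int32),
                right=np.asarray(t["right"], dtype=np.int32),
                leaf_id=np.asarray(t["leaf_id"], dtype=np.int32),
                leaf_chf=np.asarray(t["leaf_chf"], dtype=float).reshape(-1, grid.size),
                oob=np.asarray(t["oob"], dtype=int),
            )
            for t in d["trees"]
        ]
        params = ForestParams(**d["params"])
        return cls(genes=tuple(d["genes"]), params=params, grid=grid,
                   tau=float(d["tau"]), trees=trees, seed=int(d["seed"]),
                   train_rmst=float(d.get("train_rmst", float("nan"))))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SurvivalForestModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def archive_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _rmst_from_survival(S: np.ndarray, grid: np.ndarray, tau: float) -> np.ndarray:
    """Trapezoid integral of the survival curve from 0 to tau.

    The curve is anchored at (0, 1) and extended flat from the last event
    time to tau.
    """
    pts = np.concatenate(([0.0], grid))
    vals = np.concatenate((np.ones((S.shape[0], 1)), S), axis=1)
    if pts[-1] < tau:
        pts = np.concatenate((pts, [tau]))
        vals = np.concatenate((vals, vals[:, -1:]), axis=1)
    keep = pts <= tau
    return np.trapezoid(vals[:, keep], pts[keep], axis=1)


def fit_survival_forest(X, times, events, genes, params: ForestParams,
                        seed: int = 0) -> SurvivalForestModel:
    """Grow a survival forest on (X, times, events). Deterministic per seed."""
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n, p = X.shape
    if len(genes) != p:
        raise ValueError("gene list length does not match feature count")
    grid = np.unique(times[events == 1])
    if grid.size == 0:
        raise ValueError("no events in training data")
    tau = float(times.max())
    child_seeds = np.random.SeedSequence(seed).spawn(params.n_trees)
    trees = [
        _grow_tree(X, times, events, params, np.random.default_rng(cs), grid)
        for cs in child_seeds
    ]
    model = SurvivalForestModel(genes=tuple(genes), params=params, grid=grid,
                                tau=tau, trees=trees, seed=seed)
    model.train_rmst = float(np.mean(model.predict_rmst(X)))
    return model


def permutation_vimp(model: SurvivalForestModel, X, times, events,
                     seed: int | None = None) -> np.ndarray:
    """Out-of-bag permutation variable importance.

    Per gene: mean over trees of [OOB error with the gene's values permuted
    minus original OOB error], where error = 1 - Harrell's C of the tree's
    mortality prediction.  Requires bootstrap (non-empty OOB sets).
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if not model.params.bootstrap:
        raise ValueError("VIMP needs out-of-bag samples; forest was grown without bootstrap")
    p = X.shape[1]
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    vimp_sum = np.zeros(p)
    n_used = 0
    for tree in model.trees:
        oob = tree.oob
        if oob.size < 2 or events[oob].sum() == 0:
            continue
        n_used += 1
        Xo = X[oob]
        base_m = tree.leaf_chf[_route(tree, Xo)].sum(axis=1)
        base_err = 1.0 - concordance_index(times[oob], events[oob], base_m)
        used = np.unique(tree.feature[tree.feature >= 0])
        perm = rng.permutation(oob.size)
        for g in used:
            Xp = Xo.copy()
            Xp[:, g] = Xo[perm, g]
            m = tree.leaf_chf[_route(tree, Xp)].sum(axis=1)
            err = 1.0 - concordance_index(times[oob], events[oob], m)
            vimp_sum[g] += err - base_err
    if n_used == 0:
        raise ValueError("no tree had usable out-of-bag samples")
    return vimp_sum / n_used
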