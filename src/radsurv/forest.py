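"""Random survival forest: bootstrap survival trees with logrank splitting,
per-terminal-node Nelson-Aalen cumulative hazards, ensemble CHF prediction,
out-of-bag error and variable importance by random daughter assignment.

The reference configuration uses 10,000 trees, depth 10 and minimum node
size 10; tests and examples run a few hundred trees, which is enough for
the ensemble CHF and importance rankings to stabilize on cohorts of this
size. VIMP for a variable is the increase in out-of-bag error when every
out-of-bag traversal of a split on that variable takes a uniformly random
daughter; zero or negative importance means no prognostic value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .survival import HazardCurve, concordance_index, nelson_aalen

__all__ = [
    "ForestSpec",
    "SurvivalTree",
    "RandomSurvivalForest",
    "grow_tree",
    "fit_forest",
    "predict_chf",
    "risk_score",
    "oob_error",
    "vimp",
]


@dataclass(frozen=True)
class ForestSpec:
    n_trees: int = 10_000
    max_depth: int = 10
    min_node_size: int = 10
    variables_per_split: int | None = None  # default ceil(sqrt(p))
    bootstrap: bool = True
    seed: int = 0

    def validate(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_node_size < 2:
            raise ValueError("min_node_size must be >= 2")


@dataclass
class _Node:
    variable: int = -1          # -1 marks a terminal node
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    chf: HazardCurve | None = None
    n_members: int = 0


@dataclass
class SurvivalTree:
    nodes: list[_Node]
    in_bag: np.ndarray      # row indices drawn for this tree (with repeats)
    oob: np.ndarray         # row indices never drawn

    def terminal_chf(self, x, rng=None, noise_variable=None):
        """Drop one covariate vector down the tree.

        When ``noise_variable`` is given, any split on that variable sends
        the case to a uniformly random daughter (the VIMP perturbation).
        """
        k = 0
        while True:
            node = self.nodes[k]
            if node.variable < 0:
                return node.chf
            if node.variable == noise_variable:
                k = node.left if rng.random() < 0.5 else node.right
            elif x[node.variable] <= node.threshold:
                k = node.left
            else:
                k = node.right


# ---------------------------------------------------------------------------
# logrank split search (vectorized over candidate thresholds)
# ---------------------------------------------------------------------------

def _best_split_for_variable(values, time, event, min_node_size):
    """Best (threshold, logrank statistic) for one variable within a node.

    Candidate thresholds are midpoints of consecutive sorted unique values
    whose daughters both hold at least ``min_node_size`` members. Returns
    ``None`` when no admissible threshold exists. The statistic is the 1-df
    logrank chi-square with the hypergeometric tie-corrected variance.
    """
    uniq = np.unique(values)
    if len(uniq) < 2:
        return None
    thresholds = 0.5 * (uniq[:-1] + uniq[1:])
    low = values[:, None] <= thresholds[None, :]       # (n, K)
    n_low = low.sum(axis=0)
    n = len(values)
    ok = (n_low >= min_node_size) & ((n - n_low) >= min_node_size)
    if not ok.any():
        return None
    low = low[:, ok].astype(float)
    thresholds = thresholds[ok]

    etimes = np.unique(time[event == 1])
    if len(etimes) == 0:
        return None
    at_risk = time[None, :] >= etimes[:, None]          # (E, n)
    dying = (time[None, :] == etimes[:, None]) & (event[None, :] == 1)
    n_t = at_risk.sum(axis=1).astype(float)             # (E,)
    d_t = dying.sum(axis=1).astype(float)
    n1 = at_risk.astype(float) @ low                    # (E, K)
    d1 = dying.astype(float) @ low
    frac = n1 / n_t[:, None]
    observed = d1.sum(axis=0)
    expected = (d_t[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = np.where(n_t[:, None] > 1,
                         d_t[:, None] * frac * (1 - frac)
                         * (n_t[:, None] - d_t[:, None]) / (n_t[:, None] - 1),
                         0.0)
    variance = vterm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(variance > 0, (observed - expected) ** 2 / variance, 0.0)
    best = int(np.argmax(stat))
    if stat[best] <= 0:
        return None
    return float(thresholds[best]), float(stat[best])


def grow_tree(X, time, event, spec: ForestSpec, rng: np.random.Generator):
    """Grow one survival tree on a bootstrap sample.

    Splitting stops on depth, on node size (both daughters must keep at
    least ``min_node_size`` members) or when no candidate variable admits a
    positive logrank statistic. Terminal nodes hold the Nelson-Aalen CHF of
    their in-bag members (bootstrap repeats counted).
    """
    spec.validate()
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if n < spec.min_node_size:
        raise ValueError("fewer rows than min_node_size")
    mtry = spec.variables_per_split or int(np.ceil(np.sqrt(p)))
    mtry = min(mtry, p)

    if spec.bootstrap:
        in_bag = np.sort(rng.integers(0, n, size=n))
    else:
        in_bag = np.arange(n)
    oob = np.setdiff1d(np.arange(n), in_bag)

    Xb, tb, eb = X[in_bag], time[in_bag], event[in_bag]
    nodes: list[_Node] = []

    if eb.sum() < 2:
        warnings.warn("fewer than 2 events in the bootstrap sample; "
                      "returning a root-only tree", stacklevel=2)
        nodes.append(_Node(chf=nelson_aalen(tb, eb) if eb.sum() else
                           _zero_chf(), n_members=len(in_bag)))
        return SurvivalTree(nodes=nodes, in_bag=in_bag, oob=oob)

    # iterative construction: stack of (member row indices into Xb, depth)
    stack = [(np.arange(len(in_bag)), 0, -1, "root")]
    while stack:
        members, depth, parent, side = stack.pop()
        node_id = len(nodes)
        if parent >= 0:
            if side == "left":
                nodes[parent].left = node_id
            else:
                nodes[parent].right = node_id
        node = _Node(n_members=len(members))
        nodes.append(node)

        split = None
        if depth < spec.max_depth and len(members) >= 2 * spec.min_node_size:
            cand = np.sort(rng.choice(p, size=mtry, replace=False))
            best_stat = -np.inf
            for v in cand:
                res = _best_split_for_variable(Xb[members, v], tb[members],
                                               eb[members], spec.min_node_size)
                if res is not None and res[1] > best_stat:
                    best_stat = res[1]
                    split = (int(v), res[0])
        if split is None:
            node.chf = nelson_aalen(tb[members], eb[members]) \
                if eb[members].sum() else _zero_chf()
            continue
        v, thr = split
        node.variable, node.threshold = v, thr
        go_left = Xb[members, v] <= thr
        # push right first so the left child is built next (stable layout)
        stack.append((members[~go_left], depth + 1, node_id, "right"))
        stack.append((members[go_left], depth + 1, node_id, "left"))
    return SurvivalTree(nodes=nodes, in_bag=in_bag, oob=oob)


def _zero_chf():
    z = np.empty(0)
    return HazardCurve(times=z, chf=z, at_risk=np.empty(0, int),
                       deaths=np.empty(0, int))


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass
class RandomSurvivalForest:
    spec: ForestSpec
    trees: list[SurvivalTree]
    grid: np.ndarray            # distinct training event times
    n_variables: int
    variable_names: list[str]
    time: np.ndarray
    event: np.ndarray


def fit_forest(X, time, event, spec: ForestSpec = ForestSpec(),
               names=None) -> RandomSurvivalForest:
    if hasattr(X, "columns"):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trees = [grow_tree(X, time, event, spec, rng) for _ in range(spec.n_trees)]
    grid = np.unique(time[event == 1])
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    return RandomSurvivalForest(spec=spec, trees=trees, grid=grid,
                                n_variables=X.shape[1],
                                variable_names=list(names),
                                time=time, event=event)


def predict_chf(forest: RandomSurvivalForest, x) -> HazardCurve:
    """Ensemble CHF for one covariate vector: per-tree terminal CHFs
    evaluated on the training event-time grid and averaged over trees."""
    x = np.asarray(x, dtype=float)
    if x.shape != (forest.n_variables,):
        raise ValueError("covariate vector does not match the fitted forest")
    acc = np.zeros(len(forest.grid))
    for tree in forest.trees:
        acc += tree.terminal_chf(x).evaluate(forest.grid)
    chf = acc / len(forest.trees)
    return HazardCurve(times=forest.grid.copy(), chf=chf,
                       at_risk=np.zeros(len(forest.grid), int),
                       deaths=np.zeros(len(forest.grid), int))


def risk_score(forest: RandomSurvivalForest, x, horizon: float) -> float:
    """Ensemble-mortality risk: the ensemble CHF summed over all event-time
    grid points up to ``horizon``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    curve = predict_chf(forest, x)
    sel = curve.times <= horizon
    return float(curve.chf[sel].sum())


def _oob_risks(forest, X, horizon, noise_variable=None, rng=None):
    """Per-case OOB ensemble risk scores; NaN for cases never out of bag."""
    n = X.shape[0]
    acc = np.zeros((n, len(forest.grid)))
    counts = np.zeros(n, dtype=int)
    for tree in forest.trees:
        for i in tree.oob:
            curve = tree.terminal_chf(X[i], rng=rng,
                                      noise_variable=noise_variable)
            acc[i] += curve.evaluate(forest.grid)
        counts[tree.oob] += 1
    sel = forest.grid <= horizon
    risks = np.full(n, np.nan)
    seen = counts > 0
    risks[seen] = (acc[np.ix_(seen, sel)]
                   / counts[seen, None]).sum(axis=1)
    return risks, seen


def oob_error(forest: RandomSurvivalForest, X, time=None, event=None):
    """1 minus the c-index of OOB ensemble risk scores at the horizon of the
    last training event time. Cases never out of bag are excluded."""
    X = _as_matrix(X, forest)
    time = forest.time if time is None else np.asarray(time, float)
    event = forest.event if event is None else np.asarray(event, int)
    horizon = float(forest.grid.max()) if len(forest.grid) else np.inf
    risks, seen = _oob_risks(forest, X, horizon)
    if not seen.all():
        warnings.warn(f"{int((~seen).sum())} case(s) never out of bag; "
                      "excluded from the OOB error", stacklevel=2)
    c = concordance_index(risks[seen], time[seen], event[seen], kind="risk")
    return 1.0 - c


def vimp(forest: RandomSurvivalForest, X, time=None, event=None, seed=None,
         method="daughter"):
    """Variable importance as the increase in out-of-bag error.

    ``method='daughter'`` (default) sends every OOB traversal of a split on
    the variable to a uniformly random daughter; ``method='permutation'``
    instead permutes the variable's column among the cases before the OOB
    pass. Variables never used in a split have daughter-importance
    exactly 0.
    """
    if method not in ("daughter", "permutation"):
        raise ValueError("method must be 'daughter' or 'permutation'")
    X = _as_matrix(X, forest)
    time = forest.time if time is None else np.asarray(time, float)
    event = forest.event if event is None else np.asarray(event, int)
    base = oob_error(forest, X, time, event)
    used = set()
    for tree in forest.trees:
        for node in tree.nodes:
            if node.variable >= 0:
                used.add(node.variable)
    horizon = float(forest.grid.max()) if len(forest.grid) else np.inf
    out = {}
    master = np.random.default_rng(forest.spec.seed if seed is None else seed)
    for v in range(forest.n_variables):
        name = forest.variable_names[v]
        if v not in used:
            out[name] = 0.0
            continue
        rng = np.random.default_rng(master.integers(2**31))
        if method == "daughter":
            risks, seen = _oob_risks(forest, X, horizon, noise_variable=v,
                                     rng=rng)
        else:
            Xp = X.copy()
            Xp[:, v] = Xp[rng.permutation(len(Xp)), v]
            risks, seen = _oob_risks(forest, Xp, horizon)
        c = concordance_index(risks[seen], time[seen], event[seen], kind="risk")
        out[name] = (1.0 - c) - base
    return out


def _as_matrix(X, forest):
    if hasattr(X, "columns"):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != forest.n_variables:
        raise ValueError("covariate table does not match the fitted forest")
    return X
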