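"""Boosted regression trees for binary presence/pseudo-absence labels.

A from-scratch gradient-boosting engine on the Bernoulli deviance with the
feature set the habitat models need: shallow trees grown best-first to a
fixed interaction depth (tree complexity), bagging with out-of-bag (OOB)
bookkeeping, per-predictor monotone constraints, exhaustive small-cardinality
categorical splits, relative influence, partial dependence, two-way
interaction strength, stratified five-fold cross-validation, fold-wise
predictor pruning (lowest 10% in every fold) and OOB-based tree-count
selection. Everything is deterministic given the config seed.

Fitting is classical stagewise boosting: start from the logit of the label
mean; per iteration draw a bag (without replacement), fit a regression tree
to the gradient residuals ``y - p`` by best-first squared-error splits, set
terminal values by a Newton step ``sum(r) / sum(p(1-p))`` shrunk by the
learning rate. Monotone constraints act twice: candidate splits whose child
mean residuals violate the sign are rejected during the split scan, and the
fitted leaf values are clipped within bound intervals propagated through
constrained splits, so monotonicity of the ensemble is guaranteed, not just
encouraged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation
from .env_annotate import AnnotatedTable

__all__ = ["BrtConfig", "BrtModel", "CvResult", "fit", "predict",
           "relative_influence", "partial_dependence", "interaction_strength",
           "rank_interactions", "cross_validate", "prune_predictors",
           "select_n_trees_oob", "fit_pipeline", "suggest_monotone"]

_EPS = 1e-12
MAX_EXHAUSTIVE_CATEGORIES = 8


@dataclass(frozen=True)
class BrtConfig:
    """Boosting hyper-parameters.

    tree_complexity: number of best-first splits per tree (interaction depth).
    learning_rate: shrinkage applied to every terminal-node update.
    max_trees: maximum boosting iterations.
    bag_fraction: fraction of rows drawn (without replacement) per iteration.
    n_folds: cross-validation folds.
    monotone: predictor name -> -1 (decreasing), 0 (free) or +1 (increasing).
    """

    tree_complexity: int = 5
    learning_rate: float = 0.005
    max_trees: int = 10_000
    bag_fraction: float = 0.75
    n_folds: int = 5
    monotone: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")


@dataclass
class BrtModel:
    """Fitted boosted-tree ensemble.

    ``trees`` is a list of root nodes; each node is a plain dict with keys
    feature (index), threshold (continuous) or cats_left (category codes
    routed left), left/right children, n_left/n_right bagged-row counts (for
    routing unseen codes to the majority branch), gain (squared-error
    improvement of the split), and for leaves, value (logit-scale increment,
    learning rate already applied).
    """

    trees: list
    intercept: float
    feature_names: list
    categorical: frozenset
    config: BrtConfig
    oob_improvement: np.ndarray  # per-iteration OOB deviance improvement
    train_deviance: np.ndarray  # full-data Bernoulli deviance per iteration
    bag_improvement: np.ndarray  # per-iteration deviance improvement on the bag
    y_mean: float

    @property
    def n_trees_used(self) -> int:
        return len(self.trees)

    def to_json(self) -> str:
        def enc(node):
            if "value" in node:
                return {"value": node["value"]}
            return {
                "feature": node["feature"], "threshold": node.get("threshold"),
                "cats_left": sorted(node["cats_left"]) if node.get("cats_left") is not None else None,
                "n_left": node["n_left"], "n_right": node["n_right"],
                "gain": node["gain"],
                "left": enc(node["left"]), "right": enc(node["right"]),
            }
        return json.dumps({
            "intercept": self.intercept,
            "feature_names": self.feature_names,
            "categorical": sorted(self.categorical),
            "y_mean": self.y_mean,
            "trees": [enc(t) for t in self.trees],
        })


# ---------------------------------------------------------------------------
# tree growing
# ---------------------------------------------------------------------------


def _scan_continuous(v_sorted, r_sorted, sign):
    """Best squared-error split of pre-sorted values; returns
    (gain, threshold) or None. ``sign`` applies a monotone constraint on the
    child mean residuals."""
    n = len(v_sorted)
    if n < 2:
        return None
    S = r_sorted.sum()
    cum = np.cumsum(r_sorted)
    nl = np.arange(1, n)
    boundary = v_sorted[:-1] < v_sorted[1:]
    if not boundary.any():
        return None
    SL = cum[:-1]
    nr = n - nl
    gain = SL**2 / nl + (S - SL) ** 2 / nr - S**2 / n
    ok = boundary
    if sign:
        mean_l = SL / nl
        mean_r = (S - SL) / nr
        ok = ok & (sign * (mean_r - mean_l) >= 0)
    if not ok.any():
        return None
    gain = np.where(ok, gain, -np.inf)
    i = int(np.argmax(gain))
    thr = 0.5 * (v_sorted[i] + v_sorted[i + 1])
    return float(gain[i]), thr


def _scan_categorical(codes, r):
    """Best subset split on an integer-coded categorical feature: exhaustive
    when cardinality <= MAX_EXHAUSTIVE_CATEGORIES, else an ordinal scan over
    codes ordered by within-node mean residual. Returns (gain, cats_left)."""
    uniq, inv = np.unique(codes, return_inverse=True)
    k = len(uniq)
    if k < 2:
        return None
    sums = np.bincount(inv, weights=r, minlength=k)
    cnts = np.bincount(inv, minlength=k).astype(float)
    S = sums.sum()
    n = cnts.sum()
    base = S**2 / n
    if k <= MAX_EXHAUSTIVE_CATEGORIES:
        best = None
        for m in range(1, 1 << (k - 1)):  # proper subsets, fixing category 0's side
            sel = np.array([(m >> j) & 1 for j in range(k)], dtype=bool)
            nl = cnts[sel].sum()
            if nl == 0 or nl == n:
                continue
            SL = sums[sel].sum()
            gain = SL**2 / nl + (S - SL) ** 2 / (n - nl) - base
            if best is None or gain > best[0]:
                best = (float(gain), frozenset(uniq[sel].tolist()))
        return best
    order = np.argsort(sums / cnts, kind="stable")
    so = sums[order]
    co = cnts[order]
    cumS = np.cumsum(so)[:-1]
    cumN = np.cumsum(co)[:-1]
    gain = cumS**2 / cumN + (S - cumS) ** 2 / (n - cumN) - base
    i = int(np.argmax(gain))
    cats_left = frozenset(uniq[order[: i + 1]].tolist())
    return float(gain[i]), cats_left


class _TreeGrower:
    """Best-first regression-tree growth on gradient residuals."""

    def __init__(self, X, sort_idx, is_cat, monotone_signs, complexity):
        self.X = X
        self.sort_idx = sort_idx  # per-feature argsort of the full column
        self.is_cat = is_cat
        self.signs = monotone_signs
        self.complexity = complexity

    def _best_split(self, mask, r):
        best = None
        n_feat = self.X.shape[1]
        for f in range(n_feat):
            if self.is_cat[f]:
                codes = self.X[mask, f]
                res = _scan_categorical(codes, r[mask])
                if res is not None:
                    gain, cats = res
                    if best is None or gain > best["gain"]:
                        best = {"feature": f, "gain": gain, "cats_left": cats,
                                "threshold": None}
            else:
                order = self.sort_idx[f]
                idx = order[mask[order]]
                res = _scan_continuous(self.X[idx, f], r[idx], self.signs[f])
                if res is not None:
                    gain, thr = res
                    if best is None or gain > best["gain"]:
                        best = {"feature": f, "gain": gain, "threshold": thr,
                                "cats_left": None}
        return best

    def grow(self, bag_mask, r):
        n = self.X.shape[0]
        root = {"mask": bag_mask}
        leaves = [root]
        cand = {id(root): self._best_split(bag_mask, r)}
        for _ in range(self.complexity):
            splittable = [(cand[id(lf)]["gain"], i) for i, lf in enumerate(leaves)
                          if cand[id(lf)] is not None and cand[id(lf)]["gain"] > _EPS]
            if not splittable:
                break
            _, pos = max(splittable)
            leaf = leaves.pop(pos)
            sp = cand.pop(id(leaf))
            f = sp["feature"]
            col = self.X[:, f]
            if sp["cats_left"] is not None:
                go_left = np.isin(col, list(sp["cats_left"]))
            else:
                go_left = col <= sp["threshold"]
            lmask = leaf["mask"] & go_left
            rmask = leaf["mask"] & ~go_left
            left = {"mask": lmask}
            right = {"mask": rmask}
            cats_right = None
            if sp["cats_left"] is not None:
                cats_right = frozenset(np.unique(col[leaf["mask"]]).tolist()) - sp["cats_left"]
            leaf.clear()
            leaf.update({"feature": f, "threshold": sp["threshold"],
                         "cats_left": sp["cats_left"], "cats_right": cats_right,
                         "gain": sp["gain"],
                         "n_left": int(lmask.sum()), "n_right": int(rmask.sum()),
                         "left": left, "right": right})
            leaves.extend([left, right])
            cand[id(left)] = self._best_split(lmask, r)
            cand[id(right)] = self._best_split(rmask, r)
        return root, leaves


def _assign_leaf_values(leaves, r, h, learning_rate):
    for leaf in leaves:
        mask = leaf.pop("mask")
        num = r[mask].sum()
        den = h[mask].sum()
        leaf["value"] = learning_rate * (num / (den + _EPS))
        leaf["n"] = int(mask.sum())


def _subtree_mean(node):
    """n-weighted mean leaf value of a subtree."""
    if "value" in node:
        return node["value"], node["n"]
    ml, nl = _subtree_mean(node["left"])
    mr, nr = _subtree_mean(node["right"])
    n = nl + nr
    if n == 0:
        return 0.0, 0
    return (ml * nl + mr * nr) / n, n


def _enforce_monotone(node, signs, lo=-np.inf, hi=np.inf):
    """Clip leaf values within bound intervals propagated through constrained
    splits so that the whole tree's response is monotone where required."""
    if "value" in node:
        node["value"] = min(max(node["value"], lo), hi)
        return
    f = node["feature"]
    s = signs[f] if node["cats_left"] is None else 0
    if s:
        ml, _ = _subtree_mean(node["left"])
        mr, _ = _subtree_mean(node["right"])
        mid = 0.5 * (ml + mr)
        mid = min(max(mid, lo), hi)
        if s > 0:  # left (lower x) must not exceed right
            _enforce_monotone(node["left"], signs, lo, mid)
            _enforce_monotone(node["right"], signs, mid, hi)
        else:
            _enforce_monotone(node["left"], signs, mid, hi)
            _enforce_monotone(node["right"], signs, lo, mid)
    else:
        _enforce_monotone(node["left"], signs, lo, hi)
        _enforce_monotone(node["right"], signs, lo, hi)


def _strip_masks(node):
    node.pop("mask", None)
    if "left" in node:
        _strip_masks(node["left"])
        _strip_masks(node["right"])


def _tree_predict(node, X, out=None, idx=None):
    """Add the tree's logit contribution for every row of X into out."""
    if out is None:
        out = np.zeros(len(X))
    if idx is None:
        idx = np.arange(len(X))
    if "value" in node:
        out[idx] += node["value"]
        return out
    col = X[idx, node["feature"]]
    if node["cats_left"] is not None:
        go_left = np.isin(col, list(node["cats_left"]))
        unseen = ~(go_left | np.isin(col, list(node["cats_right"])))
        if unseen.any():
            # unseen category codes take the majority branch
            if node["n_left"] > node["n_right"]:
                go_left = go_left | unseen
    else:
        go_left = col <= node["threshold"]
    _tree_predict(node["left"], X, out, idx[go_left])
    _tree_predict(node["right"], X, out, idx[~go_left])
    return out


def _bernoulli_deviance(y, eta):
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def _tree_uses(node, f) -> bool:
    if "value" in node:
        return False
    return node["feature"] == f or _tree_uses(node["left"], f) or _tree_uses(node["right"], f)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _design(table: AnnotatedTable):
    X = table.data[table.predictors].to_numpy(dtype=float)
    y = table.data["label"].to_numpy(dtype=float)
    is_cat = np.array([p in table.categorical for p in table.predictors])
    return X, y, is_cat


def fit(table: AnnotatedTable, cfg: BrtConfig) -> BrtModel:
    """Fit the boosted ensemble; deterministic given ``cfg.seed``.

    Requires both classes present and no missing values in the retained
    predictor columns. Constant predictors are skipped by the split scan
    automatically (no boundary to split on).
    """
    X, y, is_cat = _design(table)
    if np.isnan(X).any():
        raise ValueError("missing predictor values; drop or screen rows first")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit")
    n, p = X.shape
    signs = np.array([cfg.monotone.get(name, 0) for name in table.predictors])
    sort_idx = [np.argsort(X[:, f], kind="stable") if not is_cat[f] else None
                for f in range(p)]
    grower = _TreeGrower(X, sort_idx, is_cat, signs, cfg.tree_complexity)

    y_mean = float(y.mean())
    intercept = math.log(y_mean / (1.0 - y_mean))
    eta = np.full(n, intercept)
    rng = np.random.default_rng(cfg.seed)
    n_bag = max(1, int(round(cfg.bag_fraction * n)))

    trees = []
    oob_improve = []
    bag_improve = []
    train_dev = []
    for _ in range(cfg.max_trees):
        bag_rows = rng.choice(n, size=n_bag, replace=False)
        bag = np.zeros(n, dtype=bool)
        bag[bag_rows] = True
        pvec = 1.0 / (1.0 + np.exp(-eta))
        r = y - pvec
        h = pvec * (1.0 - pvec)
        root, leaves = grower.grow(bag, r)
        _assign_leaf_values(leaves, r, h, cfg.learning_rate)  # leaf masks are subsets of the bag
        if any(signs):
            _enforce_monotone(root, signs)
        _strip_masks(root)

        contrib = _tree_predict(root, X)
        oob = ~bag
        if oob.any():
            before = _bernoulli_deviance(y[oob], eta[oob])
            after = _bernoulli_deviance(y[oob], eta[oob] + contrib[oob])
            oob_improve.append(before - after)
        else:
            oob_improve.append(0.0)
        bag_improve.append(_bernoulli_deviance(y[bag], eta[bag])
                           - _bernoulli_deviance(y[bag], eta[bag] + contrib[bag]))
        eta = eta + contrib
        train_dev.append(_bernoulli_deviance(y, eta))
        trees.append(root)

    return BrtModel(trees=trees, intercept=intercept,
                    feature_names=list(table.predictors),
                    categorical=table.categorical, config=cfg,
                    oob_improvement=np.array(oob_improve),
                    train_deviance=np.array(train_dev),
                    bag_improvement=np.array(bag_improve), y_mean=y_mean)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _as_matrix(model: BrtModel, rows) -> np.ndarray:
    if isinstance(rows, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in rows.columns]
        if missing:
            raise ValueError(f"rows lack model predictors: {missing}")
        return rows[model.feature_names].to_numpy(dtype=float)
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def decision_function(model: BrtModel, rows, n_trees: int | None = None) -> np.ndarray:
    """Logit-scale prediction: intercept + sum of the first n_trees trees."""
    X = _as_matrix(model, rows)
    eta = np.full(len(X), model.intercept)
    use = model.trees if n_trees is None else model.trees[:n_trees]
    for t in use:
        _tree_predict(t, X, eta)
    return eta


def predict(model: BrtModel, rows, n_trees: int | None = None) -> np.ndarray:
    """Probability of presence for each row; strictly inside (0, 1)."""
    eta = decision_function(model, rows, n_trees)
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------


def relative_influence(model: BrtModel, n_trees: int | None = None) -> pd.Series:
    """Percent of total split-gain (loss reduction) per predictor; sums to 100."""
    gains = np.zeros(len(model.feature_names))

    def walk(node):
        if "value" in node:
            return
        gains[node["feature"]] += node["gain"]
        walk(node["left"])
        walk(node["right"])

    use = model.trees if n_trees is None else model.trees[:n_trees]
    for t in use:
        walk(t)
    total = gains.sum()
    if total <= 0:
        vals = np.full(len(gains), 100.0 / len(gains))
    else:
        vals = 100.0 * gains / total
    return pd.Series(vals, index=model.feature_names).sort_values(ascending=False)


def influential_predictors(model: BrtModel) -> list[str]:
    """Predictors whose relative influence exceeds the null share 100/p."""
    infl = relative_influence(model)
    return list(infl[infl > 100.0 / len(model.feature_names)].index)


def partial_dependence(model: BrtModel, predictor: str, grid,
                       reference: pd.DataFrame | np.ndarray,
                       n_trees: int | None = None) -> np.ndarray:
    """Partial dependence on the logit scale.

    For every grid value, the mean prediction over the reference rows with
    ``predictor`` overridden to that value. Trees that never split on the
    predictor contribute a constant and are evaluated once — an exact
    shortcut, not an approximation.
    """
    f = model.feature_names.index(predictor)
    X = _as_matrix(model, reference)
    grid = np.asarray(grid, dtype=float)
    use = model.trees if n_trees is None else model.trees[:n_trees]
    using = [t for t in use if _tree_uses(t, f)]
    constant = np.full(len(X), model.intercept)
    for t in use:
        if not _tree_uses(t, f):
            _tree_predict(t, X, constant)
    base = constant.mean()
    out = np.empty(len(grid))
    Xg = X.copy()
    for i, g in enumerate(grid):
        Xg[:, f] = g
        eta = np.zeros(len(Xg))
        for t in using:
            _tree_predict(t, Xg, eta)
        out[i] = base + eta.mean()
    return out


def partial_dependence_2d(model: BrtModel, pred_a: str, pred_b: str,
                          grid_a, grid_b, reference) -> np.ndarray:
    """Two-way partial-dependence surface (logit scale), shape (len_a, len_b)."""
    fa = model.feature_names.index(pred_a)
    fb = model.feature_names.index(pred_b)
    X = _as_matrix(model, reference)
    ga = np.asarray(grid_a, dtype=float)
    gb = np.asarray(grid_b, dtype=float)
    surf = np.empty((len(ga), len(gb)))
    Xg = X.copy()
    for i, a in enumerate(ga):
        Xg[:, fa] = a
        for j, b in enumerate(gb):
            Xg[:, fb] = b
            surf[i, j] = decision_function(model, Xg).mean()
    return surf


def _quantile_knots(x, k):
    qs = np.quantile(x, np.linspace(0.05, 0.95, k))
    return np.unique(qs)


def interaction_strength(model: BrtModel, pair: tuple[str, str],
                         reference, grid_size: int = 20,
                         max_reference_rows: int = 200) -> float:
    """Departure of the two-way PD surface from additivity.

    The surface is built on quantile knots; the additive part (row + column
    means) is removed and the residual variance is scaled by the surface
    variance. 0 = perfectly additive; symmetric in the pair.
    """
    a, b = pair
    X = _as_matrix(model, reference)
    if len(X) > max_reference_rows:
        step = len(X) / max_reference_rows
        X = X[(np.arange(max_reference_rows) * step).astype(int)]
    fa = model.feature_names.index(a)
    fb = model.feature_names.index(b)
    ga = _quantile_knots(X[:, fa], grid_size)
    gb = _quantile_knots(X[:, fb], grid_size)
    if len(ga) < 2 or len(gb) < 2:
        return 0.0
    surf = partial_dependence_2d(model, a, b, ga, gb, X)
    total_var = surf.var()
    if total_var <= _EPS:
        return 0.0
    resid = surf - surf.mean(axis=1, keepdims=True) - surf.mean(axis=0, keepdims=True) + surf.mean()
    return float(resid.var() / total_var)


def rank_interactions(model: BrtModel, reference, top: int = 5,
                      grid_size: int = 20) -> pd.DataFrame:
    """Interaction strength for every predictor pair, strongest first."""
    names = model.feature_names
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            s = interaction_strength(model, (names[i], names[j]), reference,
                                     grid_size=grid_size)
            rows.append((names[i], names[j], s))
    out = pd.DataFrame(rows, columns=["predictor_a", "predictor_b", "strength"])
    return out.sort_values("strength", ascending=False).head(top).reset_index(drop=True)


def suggest_monotone(table: AnnotatedTable, n_bins: int = 10) -> dict:
    """Suggest monotone signs from empirical-logit trends, the automated
    analogue of choosing signs by eye from input-data plots. A predictor gets
    +1/-1 when its binned empirical logit is strongly rank-correlated
    (|Spearman| > 0.7) with the bin centres, else 0."""
    from scipy import stats as _stats

    y = table.data["label"].to_numpy(dtype=float)
    out = {}
    for p in table.continuous:
        x = table.data[p].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 10 or np.nanstd(x[ok]) == 0:
            out[p] = 0
            continue
        edges = np.quantile(x[ok], np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < 3:
            out[p] = 0
            continue
        which = np.clip(np.searchsorted(edges, x[ok], side="right") - 1, 0, len(edges) - 2)
        rates = np.array([y[ok][which == b].mean() if (which == b).any() else np.nan
                          for b in range(len(edges) - 1)])
        centers = 0.5 * (edges[:-1] + edges[1:])
        good = np.isfinite(rates)
        if good.sum() < 3:
            out[p] = 0
            continue
        rho = _stats.spearmanr(centers[good], rates[good]).statistic
        out[p] = int(np.sign(rho)) if abs(rho) > 0.7 else 0
    return out


# ---------------------------------------------------------------------------
# cross-validation, pruning, OOB tree selection
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    """Per-fold models and held-out metrics."""

    fold_models: list
    fold_metrics: list  # evaluation.MetricReport per fold
    fold_influence: pd.DataFrame  # folds x predictors
    fold_assignment: np.ndarray
    config: BrtConfig
    predictors: list

    @property
    def mean_metrics(self) -> dict:
        keys = ("auc", "tss", "tpr", "deviance_explained")
        return {k: float(np.mean([getattr(m, k) for m in self.fold_metrics]))
                for k in keys}


def _stratified_folds(y, n_folds, rng):
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def cross_validate(table: AnnotatedTable, cfg: BrtConfig) -> CvResult:
    """Stratified seeded k-fold cross-validation; each fold held out once.

    Held-out AUC / TSS / TPR / percent deviance explained are reported per
    fold; the fold means are the model's headline metrics. Folds leaving a
    single class in any part are redrawn (up to 10 attempts).
    """
    if cfg.n_folds < 2:
        raise ValueError("need at least 2 folds")
    X, y, _ = _design(table)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(10):
        fold = _stratified_folds(y, cfg.n_folds, rng)
        ok = all(len(np.unique(y[fold == k])) == 2 and len(np.unique(y[fold != k])) == 2
                 for k in range(cfg.n_folds))
        if ok:
            break
    else:
        raise RuntimeError("could not build folds with both classes present")

    models, metrics, infl = [], [], []
    for k in range(cfg.n_folds):
        tr = table.data[fold != k].reset_index(drop=True)
        te = table.data[fold == k].reset_index(drop=True)
        sub = AnnotatedTable(tr, list(table.predictors), table.categorical)
        m = fit(sub, replace(cfg, seed=cfg.seed + 1000 * (k + 1)))
        scores = predict(m, te)
        rep = evaluation.metric_report(te["label"].to_numpy(dtype=float), scores)
        models.append(m)
        metrics.append(rep)
        infl.append(relative_influence(m).reindex(table.predictors))
    return CvResult(fold_models=models, fold_metrics=metrics,
                    fold_influence=pd.DataFrame(infl).reset_index(drop=True),
                    fold_assignment=fold, config=cfg,
                    predictors=list(table.predictors))


def prune_predictors(cv: CvResult, percentile: float = 10.0) -> list[str]:
    """Predictors to keep after fold-wise pruning: a predictor is dropped iff
    its influence is at or below the fold's 10th-percentile cutoff in EVERY
    fold. Pruning that would empty the list is a no-op (warned)."""
    import warnings as _warnings

    infl = cv.fold_influence
    cut = infl.quantile(percentile / 100.0, axis=1)
    low_everywhere = (infl.le(cut, axis=0)).all(axis=0)
    keep = [p for p in cv.predictors if not low_everywhere[p]]
    if not keep:
        _warnings.warn("pruning would remove every predictor; keeping all")
        return list(cv.predictors)
    return keep


def select_n_trees_oob(cv: CvResult, window: int = 50) -> int:
    """Tree count encompassing the best iteration of all folds.

    Per fold, the OOB deviance improvements are smoothed by a ``window``-wide
    moving average; the best iteration is the argmax of their cumulative sum.
    The maximum over folds is returned so the final model covers every fold's
    optimum.
    """
    best = []
    for m in cv.fold_models:
        imp = m.oob_improvement
        if len(imp) == 0:
            continue
        w = min(window, len(imp))
        sm = np.convolve(imp, np.ones(w) / w, mode="same")
        best.append(int(np.argmax(np.cumsum(sm))) + 1)
    return max(best) if best else 0


@dataclass
class PipelineResult:
    model: BrtModel
    cv_initial: CvResult
    cv_final: CvResult
    kept_predictors: list
    n_trees: int

    @property
    def mean_metrics(self) -> dict:
        return self.cv_final.mean_metrics


def fit_pipeline(table: AnnotatedTable, cfg: BrtConfig) -> PipelineResult:
    """Full modelling workflow: cross-validate with all predictors, prune the
    fold-wise unimportant ones (single pass), re-cross-validate, choose the
    tree count by the OOB method, then train the final model on 100% of the
    rows with that tree count."""
    cv1 = cross_validate(table, cfg)
    keep = prune_predictors(cv1)
    reduced = table.with_predictors(keep)
    cv2 = cross_validate(reduced, cfg) if keep != cv1.predictors else cv1
    n_trees = select_n_trees_oob(cv2)
    n_trees = max(n_trees, 1)
    final_cfg = replace(cfg, max_trees=n_trees,
                        monotone={k: v for k, v in cfg.monotone.items() if k in keep})
    model = fit(reduced, final_cfg)
    return PipelineResult(model=model, cv_initial=cv1, cv_final=cv2,
                          kept_predictors=keep, n_trees=n_trees)
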