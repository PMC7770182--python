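"""Weighted regression-tree ensembles: random forest, paired-candidate random
forest, Extra-Trees and VR-Trees.

The split criterion is the decrease in the weighted sum of squared deviations
of the node outputs,

    I(nu) = Sq_w(nu) - Sq_w(nu_L) - Sq_w(nu_R),

with Sq_w(nu) = sum_k w_k (y_k - ybar_w(nu))^2 over the training rows
allocated to the node, ybar_w the weighted mean and N_w the weighted count.
Summing I(nu) over the nodes that split on input m gives the raw importance
of m, which the inference layer normalizes into a regulation confidence.
A ``literal`` variant multiplies each Sq_w by its N_w inside the gain; it is
kept as a configuration switch (``importance="literal"``) because it breaks
the telescoping identity that keeps normalized confidences in [0, 1].

Variants differ only in how a node picks its split:

* ``rf`` scans every midpoint cut of ``n_test`` sampled candidate inputs;
* ``rf_paired`` samples ``n_test/2`` original inputs and always adds each
  one's permuted shadow as a candidate, giving original and shadow columns
  even chances of being chosen (used by the feature-selection stage);
* ``extra`` draws one uniformly random cut per candidate and keeps the best;
* ``vr`` takes the deterministic best split with probability ``vr_alpha``
  and a uniformly random (variable, cut) pair otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from . import _tree_core as core
from ._rng import tree_seeds
from .exceptions import ValidationError

__all__ = [
    "EnsembleConfig",
    "Ensemble",
    "TreeView",
    "node_stats",
    "split_gain",
    "fit_tree",
    "fit_ensemble",
    "predict",
    "raw_importance",
]

_METHOD_CODES = {
    "rf": core.METHOD_RF,
    "rf_paired": core.METHOD_RF_PAIRED,
    "extra": core.METHOD_EXTRA,
    "vr": core.METHOD_VR,
}


@dataclass
class EnsembleConfig:
    """Knobs of one tree ensemble.

    ``n_test=None`` resolves to ceil(M/3) for M inputs (the regression-forest
    third); ``bootstrap=None`` resolves to True for rf/rf_paired and False
    for extra/vr (their original formulations).
    """

    n_tree: int = 1000
    n_test: int | None = None
    h_max: int = 32
    method: str = "rf"
    vr_alpha: float = 0.5
    bootstrap: bool | None = None
    min_node: int = 2
    importance: str = "variance"
    seed: int | None = None

    def resolved(self, n_inputs: int) -> "EnsembleConfig":
        """Validate against a concrete input count and fill defaults."""
        if self.method not in _METHOD_CODES:
            raise ValidationError(f"unknown ensemble method: {self.method!r}")
        if self.importance not in ("variance", "literal"):
            raise ValidationError(f"unknown importance mode: {self.importance!r}")
        if self.n_tree < 1:
            raise ValidationError("n_tree must be >= 1")
        if self.h_max < 1:
            raise ValidationError("h_max must be >= 1")
        if not (0.0 <= self.vr_alpha <= 1.0):
            raise ValidationError("vr_alpha must lie in [0, 1]")
        n_test = self.n_test
        if n_test is None:
            n_test = max(1, math.ceil(n_inputs / 3))
        if not (1 <= n_test <= n_inputs):
            raise ValidationError(
                f"n_test={n_test} outside [1, {n_inputs}] for {n_inputs} inputs"
            )
        if self.method == "rf_paired" and n_test // 2 < 1:
            raise ValidationError("rf_paired needs n_test >= 2 (paired candidates)")
        bootstrap = self.bootstrap
        if bootstrap is None:
            bootstrap = self.method in ("rf", "rf_paired")
        return replace(self, n_test=n_test, bootstrap=bootstrap)


# ---------------------------------------------------------------------------
# weighted node statistics (reference implementations used by tests and by
# the confidence normalization)
# ---------------------------------------------------------------------------


def node_stats(y, w, membership=None):
    """Weighted count, mean and sum of squared deviations of a node's rows.

    Returns ``(N_w, ybar_w, Sq_w)`` with N_w = sum w_k, ybar_w the weighted
    mean and Sq_w = sum w_k (y_k - ybar_w)^2 over the member rows.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if membership is not None:
        membership = np.asarray(membership, dtype=int)
        if membership.size == 0:
            raise ValidationError("node_stats: empty membership")
        y = y[membership]
        w = w[membership]
    if y.size == 0:
        raise ValidationError("node_stats: empty membership")
    if np.any(w <= 0):
        raise ValidationError("node_stats: weights must be positive")
    nw = w.sum()
    ybar = float((w * y).sum() / nw)
    sq = float((w * (y - ybar) ** 2).sum())
    return float(nw), ybar, sq


def split_gain(parent, left, right, literal: bool = False) -> float:
    """Gain I(nu) of a split from (N_w, ybar_w, Sq_w) triples.

    Default: the decrease in weighted SSE, Sq_w(p) - Sq_w(L) - Sq_w(R).
    ``literal`` multiplies each Sq_w by its weighted count.
    """
    pn, _, psq = parent
    ln, _, lsq = left
    rn, _, rsq = right
    if abs(pn - (ln + rn)) > 1e-8 * max(pn, 1.0):
        raise ValidationError(
            f"children weighted counts {ln}+{rn} do not partition parent {pn}"
        )
    if literal:
        return pn * psq - ln * lsq - rn * rsq
    return psq - lsq - rsq


# ---------------------------------------------------------------------------
# fitted objects
# ---------------------------------------------------------------------------


@dataclass
class TreeView:
    """Read-only view of one tree inside a fitted ensemble."""

    features: np.ndarray
    thresholds: np.ndarray
    lefts: np.ndarray
    rights: np.ndarray
    values: np.ndarray
    nws: np.ndarray
    sqs: np.ndarray
    n_nodes: int

    def is_leaf(self, node: int) -> bool:
        return self.features[node] < 0

    def children(self, node: int) -> tuple[int, int]:
        return int(self.lefts[node]), int(self.rights[node])

    @property
    def height(self) -> int:
        depth = np.zeros(self.n_nodes, dtype=int)
        h = 0
        for node in range(self.n_nodes):
            if not self.is_leaf(node):
                l, r = self.children(node)
                depth[l] = depth[r] = depth[node] + 1
                h = max(h, depth[node] + 1)
        return h

    def predict(self, X) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
        return core.forest_predict(
            self.features[None, : self.n_nodes],
            self.thresholds[None, : self.n_nodes],
            self.lefts[None, : self.n_nodes],
            self.rights[None, : self.n_nodes],
            self.values[None, : self.n_nodes],
            X,
        )


@dataclass
class Ensemble:
    """A fitted weighted tree ensemble."""

    config: EnsembleConfig
    n_rows: int
    n_features: int
    features: np.ndarray
    thresholds: np.ndarray
    lefts: np.ndarray
    rights: np.ndarray
    values: np.ndarray
    nws: np.ndarray
    sqs: np.ndarray
    n_nodes: np.ndarray
    imp: np.ndarray = field(repr=False)
    inbag: np.ndarray = field(repr=False)

    @property
    def n_tree(self) -> int:
        return self.features.shape[0]

    @property
    def oob_mask(self) -> np.ndarray:
        """Boolean (n_tree, n_rows): True where a row is out-of-bag."""
        return self.inbag == 0

    @property
    def per_tree_importances_(self) -> np.ndarray:
        return self.imp

    @property
    def importances_(self) -> np.ndarray:
        """Raw total gain per input, summed over trees (not normalized)."""
        return self.imp.sum(axis=0)

    def tree(self, i: int) -> TreeView:
        return TreeView(
            features=self.features[i],
            thresholds=self.thresholds[i],
            lefts=self.lefts[i],
            rights=self.rights[i],
            values=self.values[i],
            nws=self.nws[i],
            sqs=self.sqs[i],
            n_nodes=int(self.n_nodes[i]),
        )

    def predict(self, X, oob_only: bool = False):
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"query has {X.shape[1]} columns, ensemble expects {self.n_features}"
            )
        if not oob_only:
            return core.forest_predict(
                self.features, self.thresholds, self.lefts, self.rights, self.values, X
            )
        if X.shape[0] != self.n_rows:
            raise ValidationError(
                "oob_only prediction requires the training matrix itself"
            )
        pred, _ = core.forest_oob_predict(
            self.features,
            self.thresholds,
            self.lefts,
            self.rights,
            self.values,
            self.inbag,
            X,
        )
        return pred

    def oob_predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """OOB predictions plus a flag for rows in-bag in every tree."""
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
        if X.shape != (self.n_rows, self.n_features):
            raise ValidationError("oob_predict requires the training matrix itself")
        return core.forest_oob_predict(
            self.features,
            self.thresholds,
            self.lefts,
            self.rights,
            self.values,
            self.inbag,
            X,
        )


def fit_ensemble(X, y, w=None, ts_mask=None, config: EnsembleConfig | None = None, seed=None) -> Ensemble:
    """Fit an ensemble of weighted regression trees.

    ``ts_mask`` (time-series vs static rows) is accepted for interface
    symmetry; the two groups differ only through their per-row weights, so
    the tree code does not need the distinction.
    """
    del ts_mask
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if n < 2:
        raise ValidationError("need at least 2 training rows")
    if len(y) != n:
        raise ValidationError("X and y row counts differ")
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float).ravel()
    if len(w) != n:
        raise ValidationError("X and w row counts differ")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    cfg = (config or EnsembleConfig()).resolved(m)
    if seed is None:
        seed = cfg.seed
    seeds = tree_seeds(seed, cfg.n_tree)
    out = core.build_forest(
        X,
        y,
        w,
        cfg.n_tree,
        seeds,
        _METHOD_CODES[cfg.method],
        int(cfg.n_test),
        int(cfg.h_max),
        int(cfg.min_node),
        float(cfg.vr_alpha),
        cfg.importance == "literal",
        bool(cfg.bootstrap),
    )
    features, thresholds, lefts, rights, values, nws, sqs, n_nodes, imp, inbag = out
    return Ensemble(
        config=cfg,
        n_rows=n,
        n_features=m,
        features=features,
        thresholds=thresholds,
        lefts=lefts,
        rights=rights,
        values=values,
        nws=nws,
        sqs=sqs,
        n_nodes=n_nodes,
        imp=imp,
        inbag=inbag,
    )


def fit_tree(X, y, w=None, ts_mask=None, config: EnsembleConfig | None = None, seed=None) -> TreeView:
    """Fit a single tree on the given rows (no bootstrap)."""
    cfg = replace(config or EnsembleConfig(), n_tree=1, bootstrap=False)
    ens = fit_ensemble(X, y, w, ts_mask, cfg, seed)
    return ens.tree(0)


def predict(ensemble: Ensemble, X, oob_only: bool = False) -> np.ndarray:
    return ensemble.predict(X, oob_only=oob_only)


def raw_importance(ensemble: Ensemble, m: int) -> float:
    """Total split gain attributed to input ``m`` across all trees."""
    if not (0 <= m < ensemble.n_features):
        raise ValidationError(f"input index {m} out of range")
    return float(ensemble.importances_[m])
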