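"""Online random forest with Poisson online bagging.

The classifier is an ensemble of ``N`` depth-limited binary decision trees.
Training data arrive in batches (scribble pixels first, then seeds harvested
slice by slice).  Online bagging replaces the bootstrap: each incoming sample
is replicated ``k ~ Pois(lambda)`` times independently for every tree, so in
expectation each tree sees each sample ``lambda`` times.  A leaf stores the
weighted class counts of all samples routed to it; its posterior is the
positive fraction, and the forest posterior is the plain average over trees.

Growth happens online: a leaf buffers its samples and converts itself into a
split node once it has accumulated ``min_samples_split`` (weighted) samples
of both classes and its depth allows it.  The split is chosen to maximise
information gain over a random subset of features (default ``sqrt(F)``) and
a fixed number of thresholds drawn uniformly within the buffered value range.
How an online tree decides to split is not fixed by the classic batch
algorithm; this accumulate-then-split rule is the common streaming
adaptation and is the one implemented here.

Every tree owns an independent random stream spawned from the forest seed,
so results do not depend on tree iteration order and are reproducible.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ForestConfig", "OnlineRandomForest", "forest_init", "forest_update",
           "forest_predict"]

_MAX_BUFFER = 10_000  # per-leaf cap on buffered split candidates


@dataclass
class ForestConfig:
    """Forest hyper-parameters.

    Defaults follow the reference configuration: 20 trees of maximum depth
    10 with online-bagging rate ``lambda = 1``.
    """

    n_trees: int = 20
    max_depth: int = 10
    poisson_lambda: float = 1.0
    n_candidate_features: int = 0  # 0 -> ceil(sqrt(n_features))
    n_candidate_thresholds: int = 10
    min_samples_split: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.poisson_lambda < 0:
            raise ValueError("poisson_lambda must be >= 0")
        if self.n_candidate_thresholds < 1 or self.min_samples_split < 2:
            raise ValueError("invalid candidate/split configuration")


def _entropy(pos: np.ndarray, tot: np.ndarray) -> np.ndarray:
    """Weighted binary entropy; 0 where tot == 0."""
    tot = np.asarray(tot, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, pos / np.where(tot > 0, tot, 1.0), 0.0)
        h = -(np.where(p > 0, p * np.log2(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return np.where(tot > 0, h, 0.0)


class _Tree:
    """One decision tree stored as parallel node arrays (lists while growing)."""

    def __init__(self) -> None:
        self.feature: list[int] = [-1]       # -1 marks a leaf
        self.threshold: list[float] = [0.0]
        self.left: list[int] = [-1]
        self.right: list[int] = [-1]
        self.depth: list[int] = [0]
        self.pos: list[float] = [0.0]        # weighted positive count
        self.tot: list[float] = [0.0]        # weighted total count
        # per-leaf sample buffers feeding the split search
        self.buf: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {0: []}
        self._arrays: tuple[np.ndarray, ...] | None = None

    # -- routing ----------------------------------------------------------
    def _node_arrays(self) -> tuple[np.ndarray, ...]:
        if self._arrays is None:
            self._arrays = (
                np.asarray(self.feature, dtype=np.int64),
                np.asarray(self.threshold, dtype=np.float64),
                np.asarray(self.left, dtype=np.int64),
                np.asarray(self.right, dtype=np.int64),
                np.asarray(self.pos, dtype=np.float64),
                np.asarray(self.tot, dtype=np.float64),
            )
        return self._arrays

    def route(self, X: np.ndarray) -> np.ndarray:
        """Vectorised leaf index for every row of X."""
        feat, thr, left, right, _, _ = self._node_arrays()
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            at_leaf = feat[node] < 0
            if at_leaf.all():
                return node
            active = ~at_leaf
            f = feat[node[active]]
            go_right = X[active, f] >= thr[node[active]]
            nxt = np.where(go_right, right[node[active]], left[node[active]])
            node[active] = nxt

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, _, _, _, pos, tot = self._node_arrays()
        leaves = self.route(X)
        t = tot[leaves]
        with np.errstate(invalid="ignore"):
            p = np.where(t > 0, pos[leaves] / np.where(t > 0, t, 1.0), 0.5)
        return p

    # -- growth -----------------------------------------------------------
    def update(self, X: np.ndarray, y: np.ndarray, w: np.ndarray,
               cfg: ForestConfig, rng: np.random.Generator) -> None:
        leaves = self.route(X)
        touched = set()
        for leaf in np.unique(leaves):
            sel = leaves == leaf
            leaf = int(leaf)
            self.pos[leaf] += float(np.sum(w[sel] * y[sel]))
            self.tot[leaf] += float(np.sum(w[sel]))
            if self.depth[leaf] < cfg.max_depth and leaf in self.buf:
                buffered = sum(len(chunk[1]) for chunk in self.buf[leaf])
                if buffered < _MAX_BUFFER:
                    self.buf[leaf].append((X[sel], y[sel], w[sel]))
            touched.add(leaf)
        self._arrays = None
        queue = list(touched)
        while queue:
            leaf = queue.pop()
            queue.extend(self._maybe_split(leaf, cfg, rng))

    def _maybe_split(self, leaf: int, cfg: ForestConfig,
                     rng: np.random.Generator) -> list[int]:
        if self.feature[leaf] >= 0 or self.depth[leaf] >= cfg.max_depth:
            return []
        chunks = self.buf.get(leaf)
        if not chunks:
            return []
        X = np.concatenate([c[0] for c in chunks])
        y = np.concatenate([c[1] for c in chunks])
        w = np.concatenate([c[2] for c in chunks])
        if float(w.sum()) < cfg.min_samples_split:
            return []
        if y.min() == y.max():  # single class: nothing to gain
            return []
        n_features = X.shape[1]
        n_cand = cfg.n_candidate_features or max(1, math.isqrt(n_features - 1) + 1)
        n_cand = min(n_cand, n_features)
        feats = rng.choice(n_features, size=n_cand, replace=False)
        parent_h = _entropy(np.sum(w * y), w.sum())

        best = None  # (gain, feature, threshold)
        for f in feats:
            v = X[:, f]
            lo, hi = float(v.min()), float(v.max())
            if hi <= lo:
                continue
            thr = rng.uniform(lo, hi, size=cfg.n_candidate_thresholds)
            go_right = v[:, None] >= thr[None, :]
            wr = np.sum(np.where(go_right, w[:, None], 0.0), axis=0)
            wl = w.sum() - wr
            pr = np.sum(np.where(go_right, (w * y)[:, None], 0.0), axis=0)
            pl = np.sum(w * y) - pr
            valid = (wl > 0) & (wr > 0)
            if not valid.any():
                continue
            child_h = (wl * _entropy(pl, wl) + wr * _entropy(pr, wr)) / w.sum()
            gain = np.where(valid, parent_h - child_h, -np.inf)
            i = int(np.argmax(gain))
            if gain[i] > 0 and (best is None or gain[i] > best[0]):
                best = (float(gain[i]), int(f), float(thr[i]))
        if best is None:
            return []

        _, f, thr_v = best
        go_right = X[:, f] >= thr_v
        children = []
        for side in (~go_right, go_right):
            idx = len(self.feature)
            self.feature.append(-1)
            self.threshold.append(0.0)
            self.left.append(-1)
            self.right.append(-1)
            self.depth.append(self.depth[leaf] + 1)
            self.pos.append(float(np.sum(w[side] * y[side])))
            self.tot.append(float(np.sum(w[side])))
            if self.depth[idx] < cfg.max_depth:
                self.buf[idx] = [(X[side], y[side], w[side])]
            children.append(idx)
        self.feature[leaf] = f
        self.threshold[leaf] = thr_v
        self.left[leaf], self.right[leaf] = children
        del self.buf[leaf]
        self._arrays = None
        return children


class OnlineRandomForest:
    """Binary online random forest; see module docstring."""

    def __init__(self, config: ForestConfig | None = None,
                 feature_names: tuple[str, ...] | None = None) -> None:
        self.config = config or ForestConfig()
        self.config.validate()
        self.feature_names = tuple(feature_names) if feature_names else None
        self.trees = [_Tree() for _ in range(self.config.n_trees)]
        seq = np.random.SeedSequence(self.config.seed)
        self._rngs = [np.random.default_rng(s) for s in seq.spawn(self.config.n_trees)]
        self.n_features: int | None = len(self.feature_names) if self.feature_names else None
        self.n_seen = 0

    # ------------------------------------------------------------------
    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.n_features is None:
            self.n_features = X.shape[1]
        elif X.shape[1] != self.n_features:
            raise ValueError(
                f"feature arity mismatch: forest expects {self.n_features}, "
                f"got {X.shape[1]}")
        return X

    def update(self, X: np.ndarray, y) -> "OnlineRandomForest":
        """Absorb one batch of labeled samples with per-tree Poisson replication."""
        X = self._check_X(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if y.size and not np.all(np.isin(y, (0, 1))):
            raise ValueError("labels must be binary 0/1")
        y = y.astype(np.float64)
        if y.size == 0:
            return self
        lam = self.config.poisson_lambda
        for tree, rng in zip(self.trees, self._rngs):
            k = rng.poisson(lam, size=len(y))
            keep = k > 0
            if keep.any():
                tree.update(X[keep], y[keep], k[keep].astype(np.float64),
                            self.config, rng)
        self.n_seen += len(y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Foreground posterior averaged over the N trees."""
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty(0)
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)

    def copy(self) -> "OnlineRandomForest":
        return copy.deepcopy(self)

    # ------------------------------------------------------------------
    # serialization (topology, thresholds, counts; buffers are not kept,
    # so a loaded forest predicts identically but restarts split buffers)
    def to_json(self) -> str:
        doc = {
            "config": self.config.__dict__,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "n_features": self.n_features,
            "n_seen": self.n_seen,
            "trees": [
                {
                    "feature": t.feature,
                    "threshold": t.threshold,
                    "left": t.left,
                    "right": t.right,
                    "depth": t.depth,
                    "pos": t.pos,
                    "tot": t.tot,
                }
                for t in self.trees
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "OnlineRandomForest":
        doc = json.loads(text)
        cfg = ForestConfig(**doc["config"])
        forest = cls(cfg, feature_names=doc["feature_names"])
        forest.n_features = doc["n_features"]
        forest.n_seen = doc["n_seen"]
        forest.trees = []
        for td in doc["trees"]:
            t = _Tree()
            t.feature = [int(v) for v in td["feature"]]
            t.threshold = [float(v) for v in td["threshold"]]
            t.left = [int(v) for v in td["left"]]
            t.right = [int(v) for v in td["right"]]
            t.depth = [int(v) for v in td["depth"]]
            t.pos = [float(v) for v in td["pos"]]
            t.tot = [float(v) for v in td["tot"]]
            t.buf = {i: [] for i, f in enumerate(t.feature)
                     if f < 0 and t.depth[i] < cfg.max_depth}
            forest.trees.append(t)
        return forest


# functional aliases matching the operation names used elsewhere
def forest_init(config: ForestConfig,
                feature_names: tuple[str, ...] | None = None) -> OnlineRandomForest:
    return OnlineRandomForest(config, feature_names)


def forest_update(forest: OnlineRandomForest, batch, labels) -> OnlineRandomForest:
    values = getattr(batch, "values", batch)
    return forest.update(values, labels)


def forest_predict(forest: OnlineRandomForest, batch) -> np.ndarray:
    values = getattr(batch, "values", batch)
    return forest.predict_proba(values)
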