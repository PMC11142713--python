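"""The five occurrence models behind one fit/predict contract.

* climate envelope (Bioclim-style percentile similarity, presence-only);
* binomial GLM (logistic regression fitted by IRLS, written out here rather
  than delegated so that convergence, standard errors and separation handling
  are fully specified);
* Gaussian GLM on per-cell case counts (OLS; map predictions are min-max
  normalized to [0, 1] before ensembling, since the raw scale is a count);
* random forest (bootstrap + random feature subsets, Gini splits with
  deterministic tie-breaking);
* a maximum-entropy surrogate: presence/background logistic regression with a
  ridge penalty on the slopes. Exact Maxent feature classes and its
  regularization schedule are deliberately out of scope; the penalized
  logistic model is the standard glass-box stand-in.

Every model predicts a score in [0, 1]; ``predict_map`` paints scores onto the
stack's valid domain with nodata wherever any predictor is masked.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy import stats
from scipy.special import expit

from snakerisk.raster import RasterGrid
from snakerisk.stack import PredictorStack

__all__ = [
    "FittedModel",
    "EnvelopeModel",
    "BinomialGLM",
    "GaussianGLM",
    "RandomForest",
    "MaxentLike",
    "envelope_fit",
    "glm_binomial_fit",
    "glm_gaussian_fit",
    "forest_fit",
    "maxent_like_fit",
    "save_model",
    "load_model",
]

SEPARATION_COEF_LIMIT = 30.0  # |slope| beyond this on standardized inputs flags separation


class FittedModel:
    """Common contract: ``predict(X) -> scores in [0, 1]`` as a pure function
    of the stored parameters, plus map prediction over a stack."""

    kind: str = "abstract"

    def __init__(self, layer_names: list[str]):
        self.layer_names = list(layer_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _map_scores(self, scores: np.ndarray) -> np.ndarray:
        """Hook for models whose raw scale needs normalizing on maps."""
        return scores

    def predict_map(self, stack: PredictorStack) -> RasterGrid:
        """Predict over every jointly valid cell of ``stack``."""
        sub = stack.subset(self.layer_names)
        X, idx = sub.valid_matrix()
        scores = self._map_scores(self.predict(X))
        values = np.full(stack.shape, np.nan).ravel()
        values[idx] = scores
        values = values.reshape(stack.shape)
        mask = sub.combined_mask()
        return sub.template.with_values(values, mask=mask)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "FittedModel":
        kind = d["kind"]
        cls = _MODEL_KINDS.get(kind)
        if cls is None:
            raise ValueError(f"unknown model kind: {kind!r}")
        return cls._from_dict(d)


# -- climate envelope ---------------------------------------------------------


class EnvelopeModel(FittedModel):
    """Percentile-similarity climate envelope fitted on presence rows only.

    For layer v with n training values, ``p_v(x) = #(values <= x) / n`` and
    the similarity is ``s_v = 1 - |2 p_v - 1|``; the score is the minimum
    similarity across layers, and values outside the training range score 0.
    A layer whose training values are all identical scores 1 at the common
    value and 0 elsewhere.
    """

    kind = "envelope"

    def __init__(self, layer_names, training_values: list[np.ndarray]):
        super().__init__(layer_names)
        self.training_values = [np.sort(np.asarray(v, dtype=float)) for v in training_values]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.ones(len(X))
        for j, vals in enumerate(self.training_values):
            x = X[:, j]
            if vals[0] == vals[-1]:
                s = (x == vals[0]).astype(float)
            else:
                p = np.searchsorted(vals, x, side="right") / vals.size
                s = 1.0 - np.abs(2.0 * p - 1.0)
                s[(x < vals[0]) | (x > vals[-1])] = 0.0
            scores = np.minimum(scores, s)
        return scores

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "layer_names": self.layer_names,
            "training_values": [v.tolist() for v in self.training_values],
        }

    @classmethod
    def _from_dict(cls, d: dict) -> "EnvelopeModel":
        return cls(d["layer_names"], [np.asarray(v) for v in d["training_values"]])


def envelope_fit(presence_features: np.ndarray, layer_names: list[str]) -> EnvelopeModel:
    X = np.asarray(presence_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("envelope fit needs at least 2 presence points")
    return EnvelopeModel(layer_names, [X[:, j] for j in range(X.shape[1])])


def envelope_score(model: EnvelopeModel, x: np.ndarray) -> np.ndarray:
    return model.predict(x)


# -- IRLS core ----------------------------------------------------------------


def _irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 50,
):
    """Newton/IRLS for (optionally ridge-penalized) logistic regression.

    ``X`` includes the intercept column first; the ridge penalty applies to
    slopes only. Returns (beta, cov, n_iter, converged); ``cov`` is the
    inverse of the (penalized) Fisher information.
    """
    n, p = X.shape
    beta = np.zeros(p)
    D = np.zeros(p)
    D[1:] = ridge
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X.T * w) @ X + np.diag(D)
        g = X.T @ (y - mu) - D * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + np.diag(D))
    return beta, cov, it, converged


class _LinearScoreModel(FittedModel):
    """Shared parameter container for the three linear-in-features models."""

    def __init__(self, layer_names, intercept, coef, se, p_values, meta=None):
        super().__init__(layer_names)
        self.intercept = float(intercept)
        self.coef = np.asarray(coef, dtype=float)
        self.se = np.asarray(se, dtype=float)
        self.p_values = np.asarray(p_values, dtype=float)
        self.meta = dict(meta or {})

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coef

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "layer_names": self.layer_names,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "p_values": self.p_values.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def _from_dict(cls, d: dict):
        return cls(d["layer_names"], d["intercept"], d["coef"], d["se"], d["p_values"],
                   d.get("meta"))


class BinomialGLM(_LinearScoreModel):
    """Logistic regression; predictions are occurrence probabilities."""

    kind = "glm_binomial"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(X))


class MaxentLike(BinomialGLM):
    """Ridge-penalized presence/background logistic regression."""

    kind = "maxent_like"


class GaussianGLM(_LinearScoreModel):
    """OLS on per-cell counts; raw predictions are unbounded, so map
    predictions are min-max normalized to [0, 1] over valid cells."""

    kind = "glm_gaussian"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.linear_predictor(X)

    def _map_scores(self, scores: np.ndarray) -> np.ndarray:
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            return np.zeros_like(scores)
        return (scores - lo) / (hi - lo)


def _design(features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    return np.column_stack([np.ones(len(X)), X])


def glm_binomial_fit(
    features: np.ndarray,
    labels: np.ndarray,
    layer_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> BinomialGLM:
    """Fit logistic regression by IRLS with Wald standard errors/p-values."""
    y = np.asarray(labels, dtype=float)
    X = _design(features)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    sds = X[:, 1:].std(axis=0)
    if np.any(sds == 0):
        raise ValueError("constant predictor column(s) in design")
    beta, cov, n_iter, converged = _irls_logistic(X, y, ridge=0.0, tol=tol, max_iter=max_iter)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    separated = bool(np.max(np.abs(beta[1:])) > SEPARATION_COEF_LIMIT)
    if separated:
        warnings.warn("glm_binomial_fit: diverging coefficients suggest perfect separation")
    if layer_names is None:
        layer_names = [f"x{i}" for i in range(X.shape[1] - 1)]
    return BinomialGLM(
        layer_names, beta[0], beta[1:], se[1:], p[1:],
        meta={"intercept_se": se[0], "intercept_p": p[0], "n_iter": n_iter,
              "converged": converged, "separation_flag": separated},
    )


def glm_gaussian_fit(
    features: np.ndarray,
    counts: np.ndarray,
    layer_names: list[str] | None = None,
) -> GaussianGLM:
    """OLS of per-cell counts on predictors, with t-based p-values."""
    y = np.asarray(counts, dtype=float)
    X = _design(features)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = layer_names or [f"x{i}" for i in range(p - 1)]
        guilty = _collinear_columns(X[:, 1:], names)
        raise ValueError(f"rank-deficient design; collinear layers: {guilty}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    pv = 2.0 * stats.t.sf(np.abs(t), df=max(dof, 1))
    if layer_names is None:
        layer_names = [f"x{i}" for i in range(p - 1)]
    return GaussianGLM(
        layer_names, beta[0], beta[1:], se[1:], pv[1:],
        meta={"intercept_se": se[0], "intercept_p": pv[0], "sigma2": sigma2,
              "rss": float(resid @ resid)},
    )


def _collinear_columns(F: np.ndarray, names: list[str]) -> list[str]:
    """Name columns implicated in exact collinearity (best effort)."""
    guilty = []
    sds = F.std(axis=0)
    for i in np.flatnonzero(sds == 0):
        guilty.append(names[i])
    if F.shape[1] >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(F, rowvar=False)
        for i in range(F.shape[1]):
            for j in range(i + 1, F.shape[1]):
                if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 1 - 1e-10:
                    guilty.extend([names[i], names[j]])
    return sorted(set(guilty)) or list(names)


def maxent_like_fit(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    penalty: float = 1.0,
    layer_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MaxentLike:
    """Penalized presence/background logistic regression (ridge on slopes)."""
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    P = np.atleast_2d(np.asarray(presence_features, dtype=float))
    B = np.atleast_2d(np.asarray(background_features, dtype=float))
    if len(P) == 0 or len(B) == 0:
        raise ValueError("both presence and background sets must be non-empty")
    X = _design(np.concatenate([P, B]))
    y = np.concatenate([np.ones(len(P)), np.zeros(len(B))])
    beta, cov, n_iter, converged = _irls_logistic(X, y, ridge=penalty, tol=tol,
                                                  max_iter=max_iter)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if layer_names is None:
        layer_names = [f"x{i}" for i in range(X.shape[1] - 1)]
    return MaxentLike(
        layer_names, beta[0], beta[1:], se[1:], p[1:],
        meta={"penalty": penalty, "n_iter": n_iter, "converged": converged},
    )


# -- random forest ------------------------------------------------------------


def _gini(n1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary Gini impurity given class-1 counts and totals."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = n1 / n
        return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _grow_tree(X, y, mtry, rng, min_samples_split=2):
    """Grow one CART-style tree to purity.

    Splits maximize the Gini decrease over midpoint thresholds of ``mtry``
    randomly chosen features per node; ties break toward the lowest feature
    index (stack order) then the lowest threshold. Nodes are stored as flat
    arrays: feature -1 marks a leaf carrying the mean label.
    """
    p = X.shape[1]
    feature, threshold, left, right, value = [], [], [], [], []

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    root = new_node()
    stack = [(root, np.arange(len(y)))]
    while stack:
        node, idx = stack.pop()
        yy = y[idx]
        n = idx.size
        s1 = yy.sum()
        if n < min_samples_split or s1 == 0 or s1 == n:
            value[node] = s1 / n
            continue
        cand = np.sort(rng.choice(p, size=min(mtry, p), replace=False))
        parent = _gini(np.array([s1]), np.array([n]))[0]
        best = None  # (decrease, feat, threshold)
        for f in cand:
            xs = X[idx, f]
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            ys_s = yy[order]
            change = np.flatnonzero(xs_s[1:] > xs_s[:-1])
            if change.size == 0:
                continue
            c1 = np.cumsum(ys_s)
            nl = change + 1.0
            n1l = c1[change]
            nr = n - nl
            n1r = s1 - n1l
            child = (nl * _gini(n1l, nl) + nr * _gini(n1r, nr)) / n
            dec = parent - child
            k = int(np.argmax(dec))  # first max -> lowest threshold
            if dec[k] <= 1e-12:
                continue
            thr = 0.5 * (xs_s[change[k]] + xs_s[change[k] + 1])
            if best is None or dec[k] > best[0] + 1e-12:
                best = (dec[k], int(f), float(thr))
        if best is None:
            value[node] = s1 / n
            continue
        _, f, thr = best
        go_left = X[idx, f] <= thr
        feature[node] = f
        threshold[node] = thr
        ln, rn = new_node(), new_node()
        left[node] = ln
        right[node] = rn
        # push right first so the left child is grown first (deterministic
        # traversal order -> deterministic RNG consumption)
        stack.append((rn, idx[~go_left]))
        stack.append((ln, idx[go_left]))
    return {
        "feature": np.array(feature, dtype=int),
        "threshold": np.array(threshold, dtype=float),
        "left": np.array(left, dtype=int),
        "right": np.array(right, dtype=int),
        "value": np.array(value, dtype=float),
    }


def _tree_predict(tree, X):
    n = len(X)
    node = np.zeros(n, dtype=int)
    out = np.empty(n)
    active = np.arange(n)
    feature = tree["feature"]
    while active.size:
        f = feature[node[active]]
        at_leaf = f < 0
        leaves = active[at_leaf]
        out[leaves] = tree["value"][node[leaves]]
        active = active[~at_leaf]
        if active.size == 0:
            break
        nd = node[active]
        go_left = X[active, feature[nd]] <= tree["threshold"][nd]
        node[active] = np.where(go_left, tree["left"][nd], tree["right"][nd])
    return out


class RandomForest(FittedModel):
    """Bagged Gini decision trees; the score is the fraction of trees voting
    presence (leaf majority, ties to presence)."""

    kind = "random_forest"

    def __init__(self, layer_names, trees, seed=None, mtry=None):
        super().__init__(layer_names)
        self.trees = trees
        self.seed = seed
        self.mtry = mtry

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += _tree_predict(tree, X) >= 0.5
        return votes / len(self.trees)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "layer_names": self.layer_names,
            "seed": self.seed,
            "mtry": self.mtry,
            "trees": [{k: v.tolist() for k, v in t.items()} for t in self.trees],
        }

    @classmethod
    def _from_dict(cls, d: dict) -> "RandomForest":
        trees = [
            {
                "feature": np.asarray(t["feature"], dtype=int),
                "threshold": np.asarray(t["threshold"], dtype=float),
                "left": np.asarray(t["left"], dtype=int),
                "right": np.asarray(t["right"], dtype=int),
                "value": np.asarray(t["value"], dtype=float),
            }
            for t in d["trees"]
        ]
        return cls(d["layer_names"], trees, d.get("seed"), d.get("mtry"))


def forest_fit(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int | None = None,
    bootstrap: bool = True,
    layer_names: list[str] | None = None,
) -> RandomForest:
    """Fit a random forest classifier on presence/background labels."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(p))))
    rng = np.random.default_rng(seed)
    trees = []
    n = len(y)
    for _ in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        trees.append(_grow_tree(X[idx], y[idx], mtry, rng))
    if layer_names is None:
        layer_names = [f"x{i}" for i in range(p)]
    return RandomForest(layer_names, trees, seed=seed, mtry=mtry)


# -- serialization ------------------------------------------------------------

_MODEL_KINDS = {
    cls.kind: cls
    for cls in (EnvelopeModel, BinomialGLM, GaussianGLM, RandomForest, MaxentLike)
}


def save_model(model: FittedModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> FittedModel:
    with open(path) as fh:
        return FittedModel.from_dict(json.load(fh))
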