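"""Model evaluation (AUC, point-biserial correlation) and the weighted-mean
consensus map with its probability histogram."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from snakerisk.raster import RasterGrid

__all__ = [
    "EvaluationResult",
    "ConsensusMap",
    "auc",
    "correlation_test",
    "evaluate_scores",
    "consensus",
    "threshold_map",
    "probability_histogram",
]


@dataclass
class EvaluationResult:
    """Held-out evaluation of one model's scores."""

    model: str
    auc: float
    point_biserial_r: float
    p_value: float
    n_test_presence: int
    n_test_background: int


@dataclass
class ConsensusMap:
    """Weighted-mean ensemble surface with its normalized weights."""

    grid: RasterGrid
    weights: dict[str, float]


def auc(scores, labels) -> float:
    """Area under the ROC curve in the Mann-Whitney formulation,
    (concordant + 0.5 * tied) / (n1 * n0), computed via midranks (which is
    algebraically identical to exhaustive pair enumeration, ties included)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both presence and background labels")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def correlation_test(scores, labels) -> tuple[float, float]:
    """Point-biserial (Pearson) correlation between score and 0/1 label with a
    two-sided t-test p-value on n-2 degrees of freedom."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = len(scores)
    if (labels == 1).sum() < 3 or (labels == 0).sum() < 3:
        raise ValueError("correlation test needs at least 3 points per class")
    if scores.std() == 0:
        raise ValueError("score variance is zero; correlation undefined")
    r = float(np.corrcoef(scores, labels)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def evaluate_scores(model_name: str, scores, labels) -> EvaluationResult:
    """Bundle AUC and the correlation test for one model's held-out scores."""
    labels = np.asarray(labels)
    r, p = correlation_test(scores, labels)
    return EvaluationResult(
        model=model_name,
        auc=auc(scores, labels),
        point_biserial_r=r,
        p_value=p,
        n_test_presence=int((labels == 1).sum()),
        n_test_background=int((labels == 0).sum()),
    )


def consensus(
    maps: dict[str, RasterGrid],
    aucs: dict[str, float],
    scheme: str = "auc_excess",
) -> ConsensusMap:
    """Cellwise weighted mean of per-model probability maps.

    ``auc_excess`` weights each model by max(AUC - 0.5, 0) — skill above
    chance — normalized to sum to 1; if every model is at or below chance the
    weights fall back to equal with a warning. ``equal`` weights uniformly.
    Cells where only some models are valid average over the valid ones.
    """
    if set(maps) != set(aucs):
        raise ValueError("need exactly one AUC per map")
    names = list(maps)
    template = maps[names[0]]
    for name in names[1:]:
        if not maps[name].same_georef(template):
            raise ValueError(f"map {name!r} is not co-registered with {names[0]!r}")
    if scheme == "equal":
        raw = np.ones(len(names))
    elif scheme == "auc_excess":
        raw = np.array([max(aucs[n] - 0.5, 0.0) for n in names])
        if raw.sum() == 0:
            warnings.warn("all models at or below chance AUC; falling back to equal weights")
            raw = np.ones(len(names))
    else:
        raise ValueError(f"unknown consensus scheme: {scheme!r}")
    w = raw / raw.sum()
    num = np.zeros(template.shape)
    den = np.zeros(template.shape)
    for wi, name in zip(w, names):
        g = maps[name]
        ok = ~g.mask
        num[ok] += wi * g.values[ok]
        den[ok] += wi
    mask = den == 0
    values = np.where(mask, np.nan, num / np.where(mask, 1.0, den))
    grid = template.with_values(values, mask=mask)
    return ConsensusMap(grid=grid, weights=dict(zip(names, w)))


def threshold_map(grid: RasterGrid, cutoff: float = 0.5) -> RasterGrid:
    """Binary suitable (1) / unsuitable (0) map at a probability cutoff.

    Cells with probability >= cutoff are suitable; nodata is preserved.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    vals = np.where(grid.mask, np.nan, (grid.values >= cutoff).astype(float))
    return grid.with_values(vals)


def probability_histogram(grid: RasterGrid, n_bins: int = 10) -> np.ndarray:
    """Counts of valid cells per probability bin.

    Bins are half-open ``[k/n, (k+1)/n)`` with the last bin closed at 1, so
    the counts sum to the number of valid cells. Values outside [0, 1] raise.
    """
    vals = grid.valid_values()
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("probability map has values outside [0, 1]")
    counts, _ = np.histogram(vals, bins=np.linspace(0.0, 1.0, n_bins + 1))
    return counts
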