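"""Predictor preparation: standardization, collinearity pruning, and PCA.

Standardization parameters are estimated once on the training-period stack and
re-applied to scenario stacks (e.g. a 2070 climate projection) so that fitted
coefficients transfer between scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from snakerisk.stack import PredictorStack

__all__ = [
    "StandardizationParams",
    "PcaSummary",
    "standardize_stack",
    "apply_standardization",
    "prune_correlated",
    "pca_summary",
]


@dataclass
class StandardizationParams:
    """Per-layer mean and sample standard deviation (n-1 denominator) over
    valid cells."""

    means: dict[str, float]
    sds: dict[str, float]


@dataclass
class PcaSummary:
    """Eigen-decomposition of the inter-layer Pearson correlation matrix.

    ``fractions[i]`` is the share of total variance carried by component i
    (eigenvalue / number of layers); ``loadings[:, i]`` is its unit loading
    vector in layer order.
    """

    layer_names: list[str]
    eigenvalues: np.ndarray
    fractions: np.ndarray
    loadings: np.ndarray


def _layer_stats(name, grid):
    vals = grid.valid_values()
    if vals.size < 2:
        raise ValueError(f"layer {name!r} has fewer than 2 valid cells")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(f"layer {name!r} is constant (sd = 0); cannot standardize")
    return mean, sd


def standardize_stack(stack: PredictorStack) -> tuple[PredictorStack, StandardizationParams]:
    """Scale every layer to mean 0 / sample sd 1 over its valid cells."""
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name, grid in stack.items():
        means[name], sds[name] = _layer_stats(name, grid)
    params = StandardizationParams(means=means, sds=sds)
    return apply_standardization(stack, params), params


def apply_standardization(stack: PredictorStack, params: StandardizationParams) -> PredictorStack:
    """Standardize with previously estimated means/sds (scenario stacks reuse
    the training-period parameters)."""

    def _scale(name, grid):
        if name not in params.means:
            raise KeyError(f"no standardization parameters for layer {name!r}")
        return grid.with_values((grid.values - params.means[name]) / params.sds[name])

    return stack.map_layers(_scale)


def pairwise_correlation(stack: PredictorStack, a: str, b: str) -> float:
    """Pearson r between two layers over their jointly valid cells."""
    ga, gb = stack[a], stack[b]
    ok = ~(ga.mask | gb.mask)
    x, y = ga.values[ok], gb.values[ok]
    if x.size < 2:
        raise ValueError(f"layers {a!r} and {b!r} share fewer than 2 valid cells")
    return float(np.corrcoef(x, y)[0, 1])


def prune_correlated(
    stack: PredictorStack,
    threshold: float = 0.9,
    priority: list[str] | None = None,
) -> tuple[PredictorStack, list[tuple[str, str, float]]]:
    """Drop layers so that no retained pair has |Pearson r| > ``threshold``.

    ``priority`` orders the layers by scientific interest (earlier = keep);
    within an offending pair the lower-priority layer is dropped. The result
    is invariant to the stack's input layer order given a fixed priority list.

    Returns the pruned stack and a list of ``(kept, dropped, r)`` records.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers to prune")
    if priority is None:
        priority = stack.names
    missing = set(stack.names) - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover layers: {sorted(missing)}")
    order = [n for n in priority if n in stack]
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for name in order:
        clash = None
        for kept in retained:
            r = pairwise_correlation(stack, kept, name)
            if abs(r) > threshold:
                clash = (kept, name, r)
                break
        if clash is None:
            retained.append(name)
        else:
            dropped.append(clash)
    # restore the stack's original layer order for the survivors
    kept_in_order = [n for n in stack.names if n in set(retained)]
    return stack.subset(kept_in_order), dropped


def pca_summary(stack: PredictorStack) -> PcaSummary:
    """PCA of the inter-layer correlation matrix over jointly valid cells.

    The correlation matrix is scale-free, so the summary is identical whether
    computed before or after standardization.
    """
    if len(stack) < 2:
        raise ValueError("PCA needs at least 2 layers")
    X, _ = stack.valid_matrix()
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 jointly valid cells")
    sds = X.std(axis=0, ddof=1)
    bad = [stack.names[i] for i in np.flatnonzero(sds <= 0)]
    if bad:
        raise ValueError(f"constant layers have no correlation structure: {bad}")
    corr = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    fractions = eigvals / len(stack)
    return PcaSummary(
        layer_names=stack.names,
        eigenvalues=eigvals,
        fractions=fractions,
        loadings=eigvecs,
    )


def pca_report_frame(summary: PcaSummary, top: int = 3):
    """Tabular PCA report (component, eigenvalue, variance fraction, top
    absolute loadings) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, (ev, fr) in enumerate(zip(summary.eigenvalues, summary.fractions), start=1):
        load = summary.loadings[:, i - 1]
        idx = np.argsort(-np.abs(load))[:top]
        tops = "; ".join(f"{summary.layer_names[j]}={load[j]:+.3f}" for j in idx)
        rows.append({"component": f"PC{i}", "eigenvalue": ev, "fraction": fr, "top_loadings": tops})
    return pd.DataFrame(rows)
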