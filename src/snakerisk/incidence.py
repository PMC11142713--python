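"""Incidence machinery: backward-selected regression of occurrence on
predictors (plus human population), application of the fitted linear score
across a raster stack, and population-scaled incidence totals under current
and future scenarios.

The published equation this mirrors is printed as a linear combination of ten
standardized predictors with an intercept of -0.778, yet described as a
logistic regression with an adjusted R² — an ambiguity the module surfaces by
supporting both families. ``gaussian_identity`` is the default (it is the
family whose fit statistic is an adjusted R²); its linear risk score is
clamped to [0, 1] before being multiplied by population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from snakerisk.models import glm_binomial_fit, glm_gaussian_fit
from snakerisk.raster import RasterGrid
from snakerisk.stack import PredictorStack

__all__ = [
    "RegressionFit",
    "backward_select",
    "linear_score",
    "significance_stars",
    "incidence_map",
    "total_incidence",
    "population_at_risk",
    "compare_scenarios",
    "load_coefficients",
]

FAMILIES = ("gaussian_identity", "binomial_logit")


def significance_stars(p: float) -> str:
    """Render a p-value as significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class RegressionFit:
    """Backward-selection result: retained terms, coefficients, p-values,
    stars, fit statistic, and the replayable removal trace."""

    terms: list[str]
    intercept: float
    coef: dict[str, float]
    p_values: dict[str, float]
    stars: dict[str, str]
    r2_adjusted: float
    family: str
    trace: list[tuple[str, float]] = field(default_factory=list)
    alpha: float = 0.05

    def report_frame(self) -> pd.DataFrame:
        rows = [{"term": "(intercept)", "coefficient": self.intercept, "p_value": np.nan,
                 "stars": ""}]
        for t in self.terms:
            rows.append({"term": t, "coefficient": self.coef[t],
                         "p_value": self.p_values[t], "stars": self.stars[t]})
        return pd.DataFrame(rows)


def _fit_family(X: np.ndarray, y: np.ndarray, names: list[str], family: str):
    if family == "gaussian_identity":
        return glm_gaussian_fit(X, y, layer_names=names)
    if family == "binomial_logit":
        return glm_binomial_fit(X, y, layer_names=names)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _r2_adjusted(y: np.ndarray, fitted: np.ndarray, n_terms: int) -> float:
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    rss = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - rss / tss
    dof = n - n_terms - 1
    if dof <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / dof


def _mcfadden_r2(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    ll0 = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    if ll0 == 0:
        return 0.0
    return 1.0 - ll / ll0


def backward_select(
    features,
    response,
    family: str = "gaussian_identity",
    alpha: float = 0.05,
    layer_names: list[str] | None = None,
) -> RegressionFit:
    """Backward elimination: repeatedly refit and drop the single least
    significant term (largest p-value above ``alpha``) until every retained
    term is significant. The intercept is never dropped.

    ``features`` may be a pandas DataFrame (column names become term names)
    or an array with ``layer_names``. The fit statistic is adjusted R² for
    the Gaussian family and McFadden's pseudo-R² for the binomial family.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        names = list(layer_names) if layer_names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
    y = np.asarray(response, dtype=float)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("need n > p + 2 observations for backward selection")

    current = list(names)
    trace: list[tuple[str, float]] = []
    constant_response = float(y.std()) == 0.0
    if constant_response:
        current = []

    fit = None
    while current:
        cols = [names.index(t) for t in current]
        fit = _fit_family(X[:, cols], y, current, family)
        pv = dict(zip(current, fit.p_values))
        worst = max(current, key=lambda t: (pv[t], t))
        if pv[worst] > alpha:
            trace.append((worst, float(pv[worst])))
            current.remove(worst)
            fit = None
        else:
            break

    if not current:
        if not constant_response:
            warnings.warn("backward_select removed every term; returning intercept-only fit")
        intercept = float(y.mean())
        return RegressionFit(
            terms=[], intercept=intercept, coef={}, p_values={}, stars={},
            r2_adjusted=0.0, family=family, trace=trace, alpha=alpha,
        )

    coef = dict(zip(current, fit.coef))
    pvals = dict(zip(current, fit.p_values))
    stars = {t: significance_stars(p) for t, p in pvals.items()}
    cols = [names.index(t) for t in current]
    if family == "gaussian_identity":
        fitted = fit.predict(X[:, cols])
        stat = _r2_adjusted(y, fitted, len(current))
    else:
        stat = _mcfadden_r2(y, fit.linear_predictor(X[:, cols]))
    return RegressionFit(
        terms=current, intercept=fit.intercept, coef=coef, p_values=pvals,
        stars=stars, r2_adjusted=stat, family=family, trace=trace, alpha=alpha,
    )


# -- applying a fitted or printed equation ------------------------------------


def _coef_parts(fit) -> tuple[float, dict[str, float]]:
    if isinstance(fit, RegressionFit):
        return fit.intercept, fit.coef
    if isinstance(fit, dict):
        d = dict(fit)
        intercept = float(d.pop("intercept", d.pop("(intercept)", 0.0)))
        terms = d.pop("terms", None)
        if terms is not None:
            d = dict(terms)
        return intercept, {k: float(v) for k, v in d.items()}
    raise TypeError("fit must be a RegressionFit or a coefficient mapping")


def linear_score(fit, x, transform: str = "identity"):
    """Evaluate ``B0 + sum_j B_j * x_j`` for a fitted or printed equation.

    ``x`` maps term name -> value (scalar or array). A missing term raises a
    KeyError naming it. ``transform`` is ``"identity"`` or ``"logistic"``.
    """
    intercept, coef = _coef_parts(fit)
    total = intercept
    for term, b in coef.items():
        if term not in x:
            raise KeyError(f"predictor vector is missing term {term!r}")
        total = total + b * np.asarray(x[term], dtype=float)
    if transform == "logistic":
        return expit(total)
    if transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    return total


def load_coefficients(path) -> dict:
    """Load a printed-equation coefficient block from a YAML/JSON config:
    ``{intercept: ..., terms: {name: coefficient, ...}, family: ...}``."""
    import yaml

    with open(path) as fh:
        block = yaml.safe_load(fh)
    if "terms" not in block:
        raise ValueError(f"{path}: coefficient config needs a 'terms' mapping")
    return block


# -- population-scaled incidence ----------------------------------------------


def risk_map(fit, stack: PredictorStack, family: str | None = None) -> RasterGrid:
    """Per-cell risk in [0, 1]: the linear score through the family's response
    transform (identity scores are clamped to [0, 1])."""
    if family is None:
        if isinstance(fit, RegressionFit):
            family = fit.family
        elif isinstance(fit, dict):
            family = fit.get("family", "gaussian_identity")
        else:
            family = "gaussian_identity"
    _, coef = _coef_parts(fit)
    missing = set(coef) - set(stack.names)
    if missing:
        raise KeyError(f"stack is missing predictor layers: {sorted(missing)}")
    x = {name: stack[name].values for name in coef}
    score = linear_score(fit, x)
    if family == "binomial_logit":
        risk = expit(score)
    else:
        risk = np.clip(score, 0.0, 1.0)
    mask = stack.combined_mask()
    return stack.template.with_values(np.where(mask, np.nan, risk), mask=mask)


def incidence_map(
    fit,
    stack: PredictorStack,
    population: RasterGrid,
    family: str | None = None,
) -> tuple[RasterGrid, RasterGrid]:
    """(risk grid, per-cell incidence grid = risk x population).

    Nodata propagates from the stack and the population raster; negative
    population raises.
    """
    if not population.same_georef(stack.template):
        raise ValueError("population raster is not co-registered with the stack")
    if np.any(population.valid_values() < 0):
        raise ValueError("population raster has negative values")
    risk = risk_map(fit, stack, family=family)
    mask = risk.mask | population.mask
    inc = np.where(mask, np.nan, risk.values * population.values)
    return risk, risk.with_values(inc, mask=mask)


def total_incidence(incidence: RasterGrid) -> float:
    """Sum of per-cell incidence over the valid domain."""
    if incidence.n_valid == 0:
        raise ValueError("incidence grid has no valid cells")
    return float(incidence.valid_values().sum())


def population_at_risk(risk: RasterGrid, population: RasterGrid,
                       cutoff: float = 0.5) -> float:
    """Alternative aggregation: total population living in cells whose risk
    meets or exceeds ``cutoff``."""
    if not risk.same_georef(population):
        raise ValueError("risk and population grids are not co-registered")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    ok = ~(risk.mask | population.mask)
    sel = ok & (risk.values >= cutoff)
    return float(population.values[sel].sum())


def compare_scenarios(
    fit,
    scenarios: dict[str, tuple[PredictorStack, RasterGrid]],
    family: str | None = None,
) -> dict:
    """Per-scenario incidence totals plus risk-change grids vs the baseline.

    ``scenarios`` maps label -> (predictor stack, population raster); the
    first label is the baseline. Scenario stacks must already be standardized
    with the baseline (training-period) parameters so coefficients transfer.
    """
    if not scenarios:
        raise ValueError("no scenarios given")
    labels = list(scenarios)
    out: dict = {"totals": {}, "risk": {}, "incidence": {}, "risk_change": {}}
    base_risk = None
    for label in labels:
        stack, pop = scenarios[label]
        risk, inc = incidence_map(fit, stack, pop, family=family)
        out["risk"][label] = risk
        out["incidence"][label] = inc
        out["totals"][label] = total_incidence(inc)
        if base_risk is None:
            base_risk = risk
        else:
            mask = base_risk.mask | risk.mask
            delta = np.where(mask, np.nan, risk.values - base_risk.values)
            out["risk_change"][label] = risk.with_values(delta, mask=mask)
    base = labels[0]
    out["difference_vs_baseline"] = {
        lab: out["totals"][lab] - out["totals"][base] for lab in labels[1:]
    }
    return out
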