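"""Synthetic inputs with known truth: autocorrelated predictor surfaces, a
logistic occurrence process with stated coefficients, and hospital-style case
tables.

The generators define the package's "stated world":

* predictor layers are Gaussian white noise smoothed with an isotropic kernel
  (length-scale in cells) and affinely rescaled to a target mean/sd, with
  optional pairs mixed to a target inter-layer correlation — a stand-in for
  climate / elevation / population rasters;
* presence points are drawn from cells with probability proportional to
  ``logistic(b0 + b . x)``, the generative analogue of the fitted occurrence
  regression, so model fits can be checked against known coefficients;
* case tables mirror the marginal structure of a 16-year hospital snakebite
  register from south-eastern Bangladesh: 4,371 records, about two thirds of
  victims male, a monsoon (July-October) peak holding ~55% of dated cases,
  five clinically assigned bite-type categories dominated by non-envenoming
  bites, and field-wise missingness that reproduces the register's usable
  sub-dataset sizes (3,972 with sex, 4,331 with a bite date, 3,958
  geo-referenced, 4,268 with a sub-district address).

Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from snakerisk.raster import RasterGrid
from snakerisk.stack import PredictorStack

__all__ = [
    "FieldSpec",
    "OccurrenceProcessSpec",
    "CaseTableSpec",
    "gen_predictor_stack",
    "gen_occurrences",
    "gen_case_table",
    "BITE_TYPES",
]

BITE_TYPES = ("cobra", "green_pit_viper", "krait", "non_envenoming", "other_envenoming")

# monthly intensity: monsoon (Jul-Oct) carries 55% of cases, summer (Mar-Jun)
# 33%, winter (Nov-Feb) 12% — the seasonal profile of the hospital register
DEFAULT_MONTHLY_WEIGHTS = (
    0.03, 0.03,                      # Jan, Feb
    0.0825, 0.0825, 0.0825, 0.0825,  # Mar-Jun
    0.1375, 0.1375, 0.1375, 0.1375,  # Jul-Oct
    0.03, 0.03,                      # Nov, Dec
)

# bite-type composition: cobra ~12%, green pit viper ~11%, other envenoming
# ~10%, krait ~3%, remainder non-envenoming
DEFAULT_BITE_TYPE_PROBS = (0.12, 0.11, 0.03, 0.64, 0.10)

# the register's 16 recording years (an 8-year interruption excluded)
DEFAULT_YEARS = tuple(range(1993, 2004)) + tuple(range(2012, 2017))


@dataclass
class FieldSpec:
    """Specification of one synthetic predictor stack."""

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 0.00833333  # ~1 km in degrees at the equator
    origin_x: float = 91.0
    origin_y: float = 24.0
    layer_names: tuple[str, ...] = ("bio1", "bio12", "elevation")
    length_scale: float = 5.0  # smoothing sigma in cells; 0 = white noise
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    correlations: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_scale < 0:
            raise ValueError("length_scale must be >= 0")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        seen: set[str] = set()
        for a, b, r in self.correlations:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"requested correlation r={r} for ({a}, {b}) is infeasible")
            if a not in self.layer_names or b not in self.layer_names:
                raise ValueError(f"correlation pair ({a}, {b}) names unknown layers")
            if b in seen or a == b:
                raise ValueError("each layer may be the target of at most one correlation pair")
            seen.add(b)


@dataclass
class OccurrenceProcessSpec:
    """Known-truth logistic occurrence process on the cell grid."""

    beta: dict[str, float]
    beta0: float = 0.0
    n_presence: int = 998
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        vals = [self.beta0, *self.beta.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")


@dataclass
class CaseTableSpec:
    """Marginal structure of the synthetic hospital case table."""

    n_cases: int = 4371
    male_fraction: float = 2652 / 3972
    age_shape: float = 3.0   # gamma shape; mean ~27 y, matching reported means
    age_scale: float = 9.0   # gamma scale (years)
    monthly_weights: tuple[float, ...] = DEFAULT_MONTHLY_WEIGHTS
    bite_type_probs: tuple[float, ...] = DEFAULT_BITE_TYPE_PROBS
    years: tuple[int, ...] = DEFAULT_YEARS
    # per-field missingness chosen so expected usable sub-dataset sizes match
    # the register: sex 3972/4371, date 4331/4371, coordinates 3958/4371,
    # sub-district address 4268/4371
    missing_sex: float = 1 - 3972 / 4371
    missing_date: float = 1 - 4331 / 4371
    missing_age: float = 0.05
    missing_location: float = 1 - 3958 / 4371
    missing_address: float = 1 - 4268 / 4371
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("male_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("missing_sex", "missing_date", "missing_age",
                     "missing_location", "missing_address"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for vec, n in ((self.monthly_weights, 12), (self.bite_type_probs, len(BITE_TYPES))):
            if len(vec) != n:
                raise ValueError(f"expected {n} probabilities, got {len(vec)}")
            if any(p < 0 or p > 1 for p in vec):
                raise ValueError("probabilities must be in [0, 1]")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError("category probabilities must sum to 1")


def gen_predictor_stack(spec: FieldSpec) -> PredictorStack:
    """Generate co-registered, spatially autocorrelated predictor layers."""
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    std_fields: dict[str, np.ndarray] = {}
    for name in spec.layer_names:
        z = rng.standard_normal((nrows, ncols))
        if spec.length_scale > 0:
            z = ndimage.gaussian_filter(z, sigma=spec.length_scale, mode="wrap")
        z = (z - z.mean()) / z.std(ddof=1)
        std_fields[name] = z
    for a, b, r in spec.correlations:
        mixed = r * std_fields[a] + np.sqrt(1.0 - r * r) * std_fields[b]
        std_fields[b] = (mixed - mixed.mean()) / mixed.std(ddof=1)
    layers: dict[str, RasterGrid] = {}
    for name in spec.layer_names:
        mean = spec.means.get(name, 0.0)
        sd = spec.sds.get(name, 1.0)
        values = mean + sd * std_fields[name]
        layers[name] = RasterGrid(
            values=values,
            mask=np.zeros(spec.shape, dtype=bool),
            origin_x=spec.origin_x,
            origin_y=spec.origin_y,
            cell_size=spec.cell_size,
        )
    return PredictorStack(layers)


def cell_probabilities(stack: PredictorStack, spec: OccurrenceProcessSpec) -> RasterGrid:
    """Per-cell presence probability ``logistic(b0 + b . x)``."""
    eta = np.full(stack.shape, spec.beta0, dtype=float)
    for name, b in spec.beta.items():
        eta = eta + b * stack[name].values
    mask = stack.combined_mask()
    values = np.where(mask, np.nan, expit(eta))
    return stack.template.with_values(values, mask=mask)


def gen_occurrences(stack: PredictorStack, spec: OccurrenceProcessSpec) -> np.ndarray:
    """Draw presence points from the logistic occurrence process.

    Cells are sampled with replacement proportionally to their presence
    probability (several cases may share a locality, as in hospital data);
    each point is then placed uniformly inside its cell. Returns an
    ``(n_presence, 2)`` array of (x, y).
    """
    unknown = set(spec.beta) - set(stack.names)
    if unknown:
        raise KeyError(f"coefficients name layers absent from the stack: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    prob = cell_probabilities(stack, spec)
    valid = np.flatnonzero(~prob.mask.ravel())
    if valid.size == 0:
        raise ValueError("occurrence process has no valid cells to sample from")
    w = prob.values.ravel()[valid]
    total = w.sum()
    if total <= 0:
        raise ValueError("all cell probabilities are zero")
    chosen = rng.choice(valid, size=spec.n_presence, replace=True, p=w / total)
    nrows, ncols = stack.shape
    rows, cols = np.divmod(chosen, ncols)
    g = stack.template
    u = rng.random(spec.n_presence)
    v = rng.random(spec.n_presence)
    x = g.origin_x + (cols + u) * g.cell_size
    y = g.origin_y - (rows + v) * g.cell_size
    return np.column_stack([x, y])


def gen_case_table(
    spec: CaseTableSpec,
    stack: PredictorStack,
    occ: OccurrenceProcessSpec,
) -> pd.DataFrame:
    """Generate a hospital-style case table.

    Columns: age, sex, bite_date, bite_type, district, subdistrict,
    longitude, latitude. Fields are blanked independently at the spec's
    missingness rates after generation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female").astype(object)
    age = np.floor(rng.gamma(spec.age_shape, spec.age_scale, size=n)).clip(0, 99)
    months = rng.choice(np.arange(1, 13), size=n, p=np.asarray(spec.monthly_weights))
    years = rng.choice(np.asarray(spec.years), size=n)
    days = np.array(
        [rng.integers(1, calendar.monthrange(y, m)[1] + 1) for y, m in zip(years, months)]
    )
    dates = np.array([dt.date(y, m, d) for y, m, d in zip(years, months, days)], dtype=object)
    btype = rng.choice(np.array(BITE_TYPES, dtype=object), size=n,
                       p=np.asarray(spec.bite_type_probs))
    loc_spec = OccurrenceProcessSpec(
        beta=occ.beta, beta0=occ.beta0, n_presence=n,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    points = gen_occurrences(stack, loc_spec)
    # coarse administrative labels: a 2x2 partition of the grid extent stands
    # in for district boundaries, with 4 sub-districts per district
    g = stack.template
    width = g.shape[1] * g.cell_size
    height = g.shape[0] * g.cell_size
    dx = np.clip(((points[:, 0] - g.origin_x) / width * 2).astype(int), 0, 1)
    dy = np.clip(((g.origin_y - points[:, 1]) / height * 2).astype(int), 0, 1)
    district = np.array([f"district_{1 + 2 * j + i}" for i, j in zip(dx, dy)], dtype=object)
    sub = rng.integers(1, 5, size=n)
    subdistrict = np.array([f"{d}_upazila_{s}" for d, s in zip(district, sub)], dtype=object)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bite_date": dates,
            "bite_type": btype,
            "district": district,
            "subdistrict": subdistrict,
            "longitude": points[:, 0],
            "latitude": points[:, 1],
        }
    )
    blanks = {
        "sex": spec.missing_sex,
        "bite_date": spec.missing_date,
        "age": spec.missing_age,
    }
    for col, rate in blanks.items():
        if rate > 0:
            df.loc[rng.random(n) < rate, col] = np.nan
    if spec.missing_location > 0:
        drop = rng.random(n) < spec.missing_location
        df.loc[drop, ["longitude", "latitude"]] = np.nan
    if spec.missing_address > 0:
        drop = rng.random(n) < spec.missing_address
        df.loc[drop, ["district", "subdistrict"]] = np.nan
    df["bite_date"] = pd.to_datetime(df["bite_date"])
    return df
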