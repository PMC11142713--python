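"""Presence/background modelling dataset: background sampling, predictor
extraction at points, per-cell case counts, and the stratified train/test
split."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snakerisk.raster import RasterGrid, StudyArea
from snakerisk.stack import PredictorStack

__all__ = [
    "OccurrenceDataset",
    "sample_background",
    "extract_features",
    "split_train_test",
    "cases_per_cell",
    "build_dataset",
]

PRESENCE, BACKGROUND = 1, 0


@dataclass
class OccurrenceDataset:
    """Labelled presence/background points with extracted predictor vectors.

    ``points`` has columns x, y, label (1 = presence, 0 = background) and,
    after :func:`split_train_test`, a ``split`` column of {"train", "test"}.
    ``features`` is aligned row-for-row with ``points`` in stack layer order.
    """

    points: pd.DataFrame
    features: np.ndarray
    layer_names: list[str]
    n_excluded: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.points) != len(self.features):
            raise ValueError("points and features must be aligned")
        if self.features.ndim != 2 or self.features.shape[1] != len(self.layer_names):
            raise ValueError("feature matrix width must equal the number of layers")

    def rows(self, split: str | None = None, label: int | None = None):
        """(features, labels) for an optional split/label selection."""
        sel = np.ones(len(self.points), dtype=bool)
        if split is not None:
            sel &= (self.points["split"] == split).to_numpy()
        if label is not None:
            sel &= (self.points["label"] == label).to_numpy()
        return self.features[sel], self.points["label"].to_numpy()[sel]

    def to_frame(self) -> pd.DataFrame:
        df = self.points.copy()
        for i, name in enumerate(self.layer_names):
            df[name] = self.features[:, i]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer_names: list[str]) -> "OccurrenceDataset":
        features = df[layer_names].to_numpy(dtype=float)
        cols = [c for c in ("x", "y", "label", "split") if c in df.columns]
        return cls(points=df[cols].reset_index(drop=True), features=features,
                   layer_names=list(layer_names))


def sample_background(
    area: StudyArea,
    stack: PredictorStack,
    n: int = 1000,
    seed: int | None = None,
    max_batches: int = 1000,
) -> np.ndarray:
    """Draw ``n`` background points uniformly over polygon ∩ valid-domain by
    rejection sampling inside the polygon's bounding box.

    Returns an (n, 2) array of (x, y). Raises if nothing is ever accepted
    within the proposal budget (polygon entirely over masked cells).
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = area.bounds
    mask = stack.combined_mask()
    template = stack.template
    accepted: list[np.ndarray] = []
    got = 0
    for _ in range(max_batches):
        m = max(4 * (n - got), 1024)
        xs = rng.uniform(xmin, xmax, size=m)
        ys = rng.uniform(ymin, ymax, size=m)
        ok = area.contains_xy(xs, ys)
        rows, cols, inside = template.cell_of(xs, ys)
        ok &= inside
        ok &= ~mask[rows, cols]
        if ok.any():
            pts = np.column_stack([xs[ok], ys[ok]])
            accepted.append(pts)
            got += len(pts)
            if got >= n:
                return np.concatenate(accepted)[:n]
    raise RuntimeError(
        "background sampling failed: no valid cells under the polygon "
        f"after {max_batches} proposal batches"
    )


def extract_features(
    points: np.ndarray,
    stack: PredictorStack,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-layer cell values at point locations.

    Returns ``(features, keep)``: features has one row per *input* point
    (NaN rows for excluded points) and ``keep`` flags points that fall inside
    the extent in fully valid cells. Points in masked cells or outside the
    extent are flagged for exclusion and a summary warning is issued.
    """
    points = np.asarray(points, dtype=float)
    template = stack.template
    rows, cols, inside = template.cell_of(points[:, 0], points[:, 1])
    mask = stack.combined_mask()
    keep = inside & ~mask[rows, cols]
    features = np.full((len(points), len(stack)), np.nan)
    arr = stack.feature_array()  # (n_layers, nr, nc)
    features[keep] = arr[:, rows[keep], cols[keep]].T
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"extract_features: excluded {n_excluded} of {len(points)} points "
            "(outside extent or in nodata cells)"
        )
    return features, keep


def build_dataset(
    presence_xy: np.ndarray,
    background_xy: np.ndarray,
    stack: PredictorStack,
) -> OccurrenceDataset:
    """Combine presence and background points into one labelled dataset,
    dropping points that fail extraction (logged via warning)."""
    xy = np.concatenate([np.asarray(presence_xy, float), np.asarray(background_xy, float)])
    labels = np.concatenate(
        [np.ones(len(presence_xy), dtype=int), np.zeros(len(background_xy), dtype=int)]
    )
    features, keep = extract_features(xy, stack)
    points = pd.DataFrame({"x": xy[keep, 0], "y": xy[keep, 1], "label": labels[keep]})
    return OccurrenceDataset(
        points=points.reset_index(drop=True),
        features=features[keep],
        layer_names=stack.names,
        n_excluded=int((~keep).sum()),
    )


def split_train_test(
    ds: OccurrenceDataset,
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> OccurrenceDataset:
    """Stratified-by-label random split; train size is floored per class and
    the remainder goes to test. The assignment is stored in the ``split``
    column and is reproducible under ``seed``."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = ds.points["label"].to_numpy()
    rng = np.random.default_rng(seed)
    split = np.empty(len(labels), dtype=object)
    for lab in (PRESENCE, BACKGROUND):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 5:
            raise ValueError(f"class {lab} has {idx.size} points; need at least 5 to split")
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * idx.size))
        split[perm[:n_train]] = "train"
        split[perm[n_train:]] = "test"
    points = ds.points.copy()
    points["split"] = split
    return OccurrenceDataset(points=points, features=ds.features,
                             layer_names=ds.layer_names, n_excluded=ds.n_excluded, seed=seed)


def cases_per_cell(points: np.ndarray, template: RasterGrid) -> RasterGrid:
    """Count presence points per grid cell (the response of the Gaussian
    count GLM). Masked template cells stay masked; points outside the extent
    or in masked cells are ignored."""
    points = np.asarray(points, dtype=float)
    counts = np.zeros(template.shape, dtype=float)
    if len(points):
        rows, cols, inside = template.cell_of(points[:, 0], points[:, 1])
        ok = inside & ~template.mask[rows, cols]
        np.add.at(counts, (rows[ok], cols[ok]), 1.0)
    counts = np.where(template.mask, np.nan, counts)
    return template.with_values(counts)
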