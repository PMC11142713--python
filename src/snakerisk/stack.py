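"""Named, co-registered collections of predictor grids."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from snakerisk.raster import RasterGrid, read_grid, write_ascii_grid

__all__ = ["PredictorStack"]


class PredictorStack:
    """Ordered mapping of layer name -> :class:`RasterGrid`, all sharing one
    georeference. The union of the per-layer nodata masks defines the stack's
    valid domain (a cell must carry every predictor to be usable)."""

    def __init__(self, layers: dict[str, RasterGrid]):
        if not layers:
            raise ValueError("PredictorStack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        first = layers[names[0]]
        for name in names[1:]:
            if not layers[name].same_georef(first):
                raise ValueError(f"layer {name!r} is not co-registered with {names[0]!r}")
        self._layers: dict[str, RasterGrid] = dict(layers)

    # -- mapping-style access -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self):
        return iter(self._layers)

    def __contains__(self, name) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def items(self):
        return self._layers.items()

    @property
    def template(self) -> RasterGrid:
        """First layer, used as a georeference template."""
        return self._layers[self.names[0]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.template.shape

    def combined_mask(self) -> np.ndarray:
        """Union of all layer masks: True where the stack is unusable."""
        mask = np.zeros(self.shape, dtype=bool)
        for g in self._layers.values():
            mask |= g.mask
        return mask

    def feature_array(self) -> np.ndarray:
        """Stack values as (n_layers, nrows, ncols), nodata as NaN."""
        return np.stack([g.values for g in self._layers.values()])

    def valid_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_cells, n_layers) matrix over the jointly valid domain and
        the flat indices of those cells."""
        mask = self.combined_mask()
        idx = np.flatnonzero(~mask.ravel())
        cols = [g.values.ravel()[idx] for g in self._layers.values()]
        return np.column_stack(cols), idx

    def subset(self, names) -> "PredictorStack":
        return PredictorStack({n: self._layers[n] for n in names})

    def map_layers(self, fn) -> "PredictorStack":
        """Apply ``fn(name, grid) -> grid`` to every layer."""
        return PredictorStack({n: fn(n, g) for n, g in self._layers.items()})

    # -- I/O ------------------------------------------------------------------

    def write_dir(self, directory) -> None:
        """Write each layer as ``<name>.asc`` in ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, g in self._layers.items():
            write_ascii_grid(g, directory / f"{name}.asc")

    @classmethod
    def read_dir(cls, directory, names: list[str] | None = None) -> "PredictorStack":
        """Read layers from a directory of rasters. ``names`` fixes the layer
        order; by default ``*.asc`` files are read in sorted name order."""
        directory = Path(directory)
        if names is None:
            names = sorted(p.stem for p in directory.glob("*.asc"))
        layers = {}
        for name in names:
            for ext in (".asc", ".tif", ".tiff"):
                p = directory / f"{name}{ext}"
                if p.exists():
                    layers[name] = read_grid(p)
                    break
            else:
                raise FileNotFoundError(f"no raster found for layer {name!r} in {directory}")
        return cls(layers)
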