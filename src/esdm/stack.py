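"""Predictor stacks: alignment, terrain derivatives, distance rasters,
iterative VIF screening and multi-GCM averaging.

A :class:`PredictorStack` is a named, co-registered collection of
:class:`~esdm.grid.RasterGrid` layers — the climate/terrain/distance/land-cover
set that a suitability model is fitted on. All layers share the grid transform
and the nodata mask; operations that could break that invariant (alignment,
averaging) re-establish it by taking the union of member masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import GridError, RasterGrid

__all__ = [
    "PredictorStack",
    "VifReport",
    "align",
    "terrain",
    "distance_raster",
    "vif_screen",
    "gcm_mean",
    "cover_fractions",
    "AlignmentError",
    "FLAT_ASPECT",
]

#: Sentinel aspect value for cells with zero gradient (aspect undefined).
FLAT_ASPECT = -1.0


class AlignmentError(ValueError):
    pass


class PredictorStack:
    """Ordered mapping of layer name -> RasterGrid, all co-registered."""

    def __init__(self, layers: dict[str, RasterGrid], harmonise_mask: bool = True):
        if not layers:
            raise GridError("a PredictorStack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise GridError("layer names must be unique")
        template = next(iter(layers.values()))
        for name, layer in layers.items():
            if not layer.same_grid(template):
                raise GridError(f"layer {name!r} is not co-registered with the stack")
        if harmonise_mask:
            common = np.logical_and.reduce([g.mask for g in layers.values()])
            layers = {
                name: g.with_values(np.where(common, g.values, np.nan))
                for name, g in layers.items()
            }
        self._layers = dict(layers)

    # -- mapping interface ---------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    @property
    def template(self) -> RasterGrid:
        return next(iter(self._layers.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.template.mask

    def subset(self, names) -> "PredictorStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"unknown layer(s): {missing}")
        return PredictorStack({n: self._layers[n] for n in names}, harmonise_mask=False)

    def with_layer(self, name: str, layer: RasterGrid) -> "PredictorStack":
        new = dict(self._layers)
        new[name] = layer
        return PredictorStack(new)

    def to_matrix(self, names=None):
        """(X, rows, cols): an (n_valid, n_layers) design matrix over valid
        cells plus the cell indices each row came from."""
        names = list(names) if names is not None else self.names
        mask = self.mask
        rows, cols = np.nonzero(mask)
        X = np.column_stack([self._layers[n].values[rows, cols] for n in names])
        return X, rows, cols

    def values_at(self, x, y, names=None) -> np.ndarray:
        names = list(names) if names is not None else self.names
        return np.column_stack([self._layers[n].values_at(x, y) for n in names])


# ---------------------------------------------------------------------------
# alignment


def _resample(layer: RasterGrid, template: RasterGrid, order: int) -> np.ndarray:
    X, Y = template.centre_grids()
    # fractional array indices of template cell centres in the source grid
    cols = (X - layer.x_min) / layer.cell_size - 0.5
    rows = (layer.y_max - Y) / layer.cell_size - 0.5
    return ndimage.map_coordinates(
        layer.values, [rows, cols], order=order, mode="constant", cval=np.nan
    )


def align(layers: dict[str, RasterGrid], template: RasterGrid,
          categorical: set[str] | None = None) -> PredictorStack:
    """Resample every layer onto the template grid.

    Continuous layers are interpolated bilinearly, names listed in
    ``categorical`` use nearest-neighbour. Cells falling outside a source
    layer's extent become nodata, and the union of nodata masks is applied.
    """
    categorical = categorical or set()
    out: dict[str, RasterGrid] = {}
    for name, layer in layers.items():
        xo, yo, x1, y1 = layer.extent
        tx0, ty0, tx1, ty1 = template.extent
        if x1 <= tx0 or tx1 <= xo or y1 <= ty0 or ty1 <= yo:
            raise AlignmentError(f"layer {name!r} does not overlap the template extent")
        if layer.same_grid(template):
            out[name] = layer.with_values(layer.values)
            continue
        order = 0 if name in categorical else 1
        out[name] = RasterGrid(
            _resample(layer, template, order), template.x_min, template.y_max,
            template.cell_size,
        )
    return PredictorStack(out)


# ---------------------------------------------------------------------------
# terrain derivatives


def terrain(dem: RasterGrid) -> dict[str, RasterGrid]:
    """Horn 3x3 slope (degrees) and compass aspect (degrees, 0 = north,
    clockwise) from a planar DEM whose elevations share the horizontal unit.

    Border cells have no full 3x3 neighbourhood and are nodata; flat interior
    cells get slope 0 and the :data:`FLAT_ASPECT` sentinel.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise GridError("terrain needs at least a 3x3 DEM")
    z = dem.values
    cs = dem.cell_size
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8 * cs)
    # row index grows southward, so the row-derivative is -d/dy
    ky = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float) / (8 * cs)
    gx = ndimage.correlate(z, kx, mode="nearest")
    gy = -ndimage.correlate(z, ky, mode="nearest")
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # compass bearing of the downslope direction (-gx, -gy)
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(np.hypot(gx, gy) == 0, FLAT_ASPECT, aspect)
    border = np.zeros(z.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    invalid = border | ~dem.mask
    slope = np.where(invalid, np.nan, slope)
    aspect = np.where(invalid, np.nan, aspect)
    return {"slope": dem.with_values(slope), "aspect": dem.with_values(aspect)}


# ---------------------------------------------------------------------------
# distance rasters


def distance_raster(features, template: RasterGrid) -> RasterGrid:
    """Planar Euclidean distance from each cell centre to the nearest feature.

    ``features`` is either an (n, 2) array of point coordinates or a sequence
    of shapely geometries. A cell that contains a point feature (or whose
    centre lies inside a polygon) gets distance 0.
    """
    feats = list(features) if not isinstance(features, np.ndarray) else features
    if len(feats) == 0:
        raise ValueError("feature set is empty")
    X, Y = template.centre_grids()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    first = feats[0] if not isinstance(feats, np.ndarray) else None
    if first is None or not hasattr(first, "geom_type"):
        coords = np.asarray(feats, dtype=float).reshape(-1, 2)
        dist, _ = cKDTree(coords).query(pts)
        dist = dist.reshape(template.shape)
        row, col = template.index_of(coords[:, 0], coords[:, 1])
        on = row >= 0
        dist[row[on], col[on]] = 0.0
    else:
        import shapely

        geoms = np.asarray(list(feats), dtype=object)
        tree = shapely.STRtree(geoms)
        cell_pts = shapely.points(pts[:, 0], pts[:, 1])
        nearest = tree.nearest(cell_pts)
        dist = shapely.distance(cell_pts, geoms[nearest]).reshape(template.shape)
    dist = np.where(template.mask, dist, np.nan)
    return template.with_values(dist)


# ---------------------------------------------------------------------------
# VIF screening


@dataclass
class VifReport:
    """Trace of an iterative variance-inflation-factor screen."""

    steps: list[tuple[str, float]]          # (dropped layer, VIF at drop time)
    retained: dict[str, float]              # final VIF per retained layer
    threshold: float
    n_cells: int

    @property
    def dropped(self) -> list[str]:
        return [name for name, _ in self.steps]


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R^2_j) regressing column j on the others (with intercept)."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    out = np.empty(p)
    for j in range(p):
        y = Xc[:, j]
        sst = float(y @ y)
        if sst <= 0:  # constant layer carries no collinearity signal
            out[j] = 1.0
            continue
        A = np.delete(Xc, j, axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        r2 = 1.0 - float(resid @ resid) / sst
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(stack: PredictorStack, sample_cells: int = 10_000,
               threshold: float = 5.0, seed: int = 0):
    """Iteratively drop the largest-VIF layer until all VIFs are below the
    threshold, computing VIFs on a seeded subsample of valid cells.

    Returns ``(VifReport, reduced PredictorStack)``. Ties on the maximum VIF
    (e.g. an exactly duplicated layer, where both VIFs are infinite) are broken
    by dropping the lexicographically later name.
    """
    if len(stack) < 2:
        raise ValueError("VIF screening needs at least two layers")
    X_all, _, _ = stack.to_matrix()
    n_valid = X_all.shape[0]
    if n_valid < 2:
        raise ValueError("not enough valid cells to screen")
    rng = np.random.default_rng(seed)
    if n_valid > sample_cells:
        idx = rng.choice(n_valid, size=sample_cells, replace=False)
        X_all = X_all[idx]
    names = list(stack.names)
    cols = {n: i for i, n in enumerate(names)}
    steps: list[tuple[str, float]] = []
    current = list(names)
    while len(current) >= 2:
        X = X_all[:, [cols[n] for n in current]]
        vifs = _vifs(X)
        vmax = vifs.max()
        if vmax < threshold:
            break
        tied = [current[i] for i in range(len(current)) if vifs[i] == vmax]
        drop = max(tied)  # lexicographically later name
        steps.append((drop, float(vmax)))
        current.remove(drop)
    final = _vifs(X_all[:, [cols[n] for n in current]]) if len(current) >= 2 else \
        np.ones(len(current))
    report = VifReport(
        steps=steps,
        retained={n: float(v) for n, v in zip(current, final)},
        threshold=threshold,
        n_cells=X_all.shape[0],
    )
    return report, stack.subset(current)


# ---------------------------------------------------------------------------
# GCM averaging


def gcm_mean(stacks) -> PredictorStack:
    """Cell-wise arithmetic mean of co-registered stacks, layer by layer.

    Emulates the standard practice of averaging several global circulation
    models into one consensus climate before projecting. Nodata propagates:
    a cell is nodata in the mean if any member is nodata there.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no stacks to average")
    names = stacks[0].names
    for s in stacks[1:]:
        if s.names != names:
            raise ValueError("stacks have mismatched layer names")
        if not s.template.same_grid(stacks[0].template):
            raise GridError("stacks are not co-registered")
    out = {}
    for name in names:
        vals = np.mean([s[name].values for s in stacks], axis=0)
        out[name] = stacks[0][name].with_values(vals)
    return PredictorStack(out)


# ---------------------------------------------------------------------------
# land-cover fractions


def cover_fractions(categorical: RasterGrid, classes, block: int) -> dict[str, RasterGrid]:
    """Fraction-in-cell rasters from a finer categorical raster, by block
    aggregation: each ``block x block`` window of the input becomes one output
    cell whose value is the fraction of window cells equal to the class."""
    if block < 1 or categorical.n_rows % block or categorical.n_cols % block:
        raise GridError("block must divide both raster dimensions")
    out = {}
    nr, nc = categorical.n_rows // block, categorical.n_cols // block
    for cls in classes:
        ind = (categorical.values == cls).astype(float)
        ind = np.where(categorical.mask, ind, np.nan)
        frac = ind.reshape(nr, block, nc, block).mean(axis=(1, 3))
        out[f"frac_{cls}"] = RasterGrid(
            frac, categorical.x_min, categorical.y_max, categorical.cell_size * block
        )
    return out


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
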