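"""Synthetic landscapes with known ground truth.

Everything the analysis consumes can be generated here with the statistical
structure the method assumes: a stack of smooth, standardised predictor fields
with an engineered collinearity structure; a "true" suitability surface defined
by a logistic model on those predictors; presence records sampled with an
observer-accessibility bias; a pool of surrogate-species records sharing that
bias (the raw material for a survey-effort layer); perturbed future climate
stacks from several pseudo-GCMs; and Voronoi zone polygons plus wind-farm
point tables for the overlay stages.

The world is planar with km units; one pixel is ``cell_size`` km square, and
occurrence coordinates are cell centres, so grid membership is exact in tests.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .grid import GridError, RasterGrid
from .stack import PredictorStack

__all__ = [
    "LandscapeSpec",
    "TrueSuitability",
    "BiasField",
    "ZoneSet",
    "make_stack",
    "make_truth",
    "make_bias",
    "sample_presences",
    "make_target_group",
    "make_futures",
    "make_zones",
    "make_windfarms",
]


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic predictor stack.

    ``extent`` is (x_min, y_min, x_max, y_max) in km and must be an integer
    number of cells in each direction; ``collinear_pairs`` is a list of
    ``(source_index, target_index, correlation)`` with correlation in [0, 1);
    ``smoothness`` is the Gaussian-kernel radius (sigma, in cells) applied to
    the white-noise fields.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    cell_size: float = 1.0
    n_predictors: int = 5
    collinear_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    smoothness: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise GridError("extent is empty")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")
        for dim in (x1 - x0, y1 - y0):
            n = dim / self.cell_size
            if abs(n - round(n)) > 1e-9:
                raise GridError("extent must be an integer multiple of cell_size")
        if self.n_predictors < 1:
            raise GridError("need at least one predictor")
        for i, j, rho in self.collinear_pairs:
            if not (0 <= rho < 1):
                raise GridError(f"pair correlation must be in [0,1), got {rho}")
            if i == j or not (0 <= i < self.n_predictors and 0 <= j < self.n_predictors):
                raise GridError(f"invalid collinear pair ({i}, {j})")

    @property
    def shape(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.extent
        return (int(round((y1 - y0) / self.cell_size)),
                int(round((x1 - x0) / self.cell_size)))

    def template(self) -> RasterGrid:
        nrows, ncols = self.shape
        return RasterGrid(np.zeros((nrows, ncols)), self.extent[0], self.extent[3],
                          self.cell_size)


@dataclass
class TrueSuitability:
    """Known logistic suitability surface used as ground truth."""

    coefficients: dict[str, float]
    intercept: float
    surface: RasterGrid


@dataclass
class BiasField:
    """Relative observation accessibility in [0, 1]; max value is 1."""

    surface: RasterGrid

    def __post_init__(self) -> None:
        v = self.surface.values
        ok = np.isfinite(v)
        if not ok.any() or np.nanmin(v) < 0:
            raise GridError("bias field must be non-negative with data")
        peak = np.nanmax(v)
        if peak <= 0:
            raise GridError("bias field is identically zero")
        if abs(peak - 1.0) > 1e-12:
            self.surface = self.surface.with_values(v / peak)


@dataclass
class ZoneSet:
    """Labelled planar polygons partitioning an extent."""

    labels: list[str]
    polygons: list  # shapely polygons

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.polygons):
            raise ValueError("labels and polygons differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("zone labels must be unique")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    return z


def _standardise(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def make_stack(spec: LandscapeSpec) -> PredictorStack:
    """Generate the predictor stack described by ``spec``.

    Fields are Gaussian white noise blurred at the requested smoothness, then
    orthogonalised over cells (Gram–Schmidt) and standardised to mean 0 / sd 1,
    so that the only correlation in the stack is the engineered one: for each
    ``(i, j, rho)`` pair, layer j is rebuilt as
    ``rho * layer_i + sqrt(1 - rho^2) * residual`` and the empirical
    correlation equals rho up to float rounding.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    n = spec.n_predictors
    fields = np.stack([_smooth_field(rng, shape, spec.smoothness).ravel()
                       for _ in range(n)])
    # centre, then orthogonalise the fields over cells
    fields -= fields.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(fields.T)
    fields = q.T
    fields = np.stack([_standardise(f) for f in fields])
    for i, j, rho in spec.collinear_pairs:
        fields[j] = rho * fields[i] + np.sqrt(1 - rho * rho) * fields[j]
        fields[j] = _standardise(fields[j])
    x0, _, _, y1 = spec.extent
    layers = {
        f"env{k + 1:02d}": RasterGrid(fields[k].reshape(shape), x0, y1, spec.cell_size)
        for k in range(n)
    }
    return PredictorStack(layers, harmonise_mask=False)


def make_truth(stack: PredictorStack, coefficients: dict[str, float],
               intercept: float = 0.0) -> TrueSuitability:
    """Cell-wise inverse-logit suitability from a linear model on stack layers."""
    missing = [k for k in coefficients if k not in stack]
    if missing:
        raise KeyError(f"coefficients name unknown layer(s): {missing}")
    eta = np.full(stack.template.shape, float(intercept))
    for name, beta in coefficients.items():
        eta = eta + beta * stack[name].values
    surface = 1.0 / (1.0 + np.exp(-eta))
    surface = np.where(stack.mask, surface, np.nan)
    return TrueSuitability(dict(coefficients), float(intercept),
                           stack.template.with_values(surface))


def make_bias(template: RasterGrid, kind: str = "smooth", smoothness: float = 8.0,
              low: float = 0.5, seed: int = 0) -> BiasField:
    """An accessibility field emulating uneven survey effort.

    ``kind="smooth"`` gives a blurred random field rescaled to [low, 1] (a
    town-and-roads gradient analogue); ``kind="blocks"`` splits the extent into
    a well-surveyed right half (1.0) and an under-surveyed left half (``low``).
    """
    rng = np.random.default_rng(seed)
    if kind == "smooth":
        f = _smooth_field(rng, template.shape, smoothness)
        f = (f - f.min()) / (f.max() - f.min())
        v = low + (1.0 - low) * f
    elif kind == "blocks":
        v = np.full(template.shape, low)
        v[:, template.n_cols // 2:] = 1.0
    else:
        raise ValueError(f"unknown bias kind {kind!r}")
    v = np.where(template.mask, v, np.nan)
    return BiasField(template.with_values(v))


def _occurrence_frame(xs, ys, species, rng, id_offset=0) -> pd.DataFrame:
    n = len(xs)
    years = rng.integers(1970, 2025, size=n)
    return pd.DataFrame(
        {
            "id": np.arange(id_offset, id_offset + n),
            "species": species,
            "lon": xs,
            "lat": ys,
            "date": [f"{y}-01-01" for y in years],
            "basis_of_record": "human observation",
        }
    )


def sample_presences(truth: TrueSuitability, bias: BiasField, n_target: int,
                     seed: int, species: str = "focal") -> pd.DataFrame:
    """Presence records drawn cell-wise with probability proportional to
    truth x bias; coordinates are cell centres (duplicates allowed)."""
    grid = truth.surface
    if not grid.same_grid(bias.surface):
        raise GridError("truth and bias are not co-registered")
    p = grid.values * bias.surface.values
    p = np.where(np.isfinite(p), p, 0.0).ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot sample: truth x bias is zero everywhere")
    rng = np.random.default_rng(seed)
    flat = rng.choice(p.size, size=n_target, replace=True, p=p / total)
    rows, cols = np.unravel_index(flat, grid.shape)
    xs, ys = grid.centre_of(rows, cols)
    return _occurrence_frame(xs, ys, species, rng)


def make_surrogate_truths(stack: PredictorStack, n_species: int = 19,
                          coef_sd: float = 1.5, seed: int = 0) -> list[TrueSuitability]:
    """Diverse niches for target-group surrogate species.

    Each surrogate gets its own random logistic coefficients (N(0, coef_sd)
    per layer), so the pooled record density tracks the shared accessibility
    bias rather than any single species' niche — the premise that makes a
    target-group survey-effort layer informative about observers, not habitat.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_species):
        coefs = {name: float(rng.normal(0.0, coef_sd)) for name in stack.names}
        out.append(make_truth(stack, coefs, intercept=float(rng.normal(0.0, 0.5))))
    return out


def make_target_group(truth_list, bias: BiasField, n_species: int = 19,
                      n_per_species: int = 200, seed: int = 0) -> pd.DataFrame:
    """Pooled occurrences of surrogate species sharing the focal bias field.

    Mirrors the target-group approach to survey-effort estimation: records of
    several similarly detectable species, all filtered through the same
    accessibility bias, stand in for where observers actually looked. Species
    cycle through ``truth_list`` if there are fewer truths than species.
    """
    if n_species < 1:
        raise ValueError("need at least one surrogate species")
    truths = list(truth_list)
    frames = []
    offset = 0
    for k in range(n_species):
        truth = truths[k % len(truths)]
        f = sample_presences(truth, bias, n_per_species, seed=seed + 1000 + k,
                             species=f"surrogate_{k + 1:02d}")
        f["id"] += offset
        offset += len(f)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def make_futures(stack: PredictorStack, scenario_deltas: dict[str, dict[str, float]],
                 n_gcms: int = 5, gcm_noise_sd: float = 0.1, seed: int = 0,
                 smoothness: float = 3.0) -> dict[str, list[PredictorStack]]:
    """Per-scenario, per-pseudo-GCM future stacks.

    Each scenario applies its per-layer delta uniformly; each GCM adds its own
    smooth noise field (sd ``gcm_noise_sd``) on top, emulating disagreement
    between circulation models. Returns {scenario: [stack, ...]}.
    """
    if n_gcms < 1:
        raise ValueError("need at least one GCM")
    for scen, deltas in scenario_deltas.items():
        unknown = [k for k in deltas if k not in stack]
        if unknown:
            raise KeyError(f"scenario {scen!r} shifts unknown layer(s): {unknown}")
    rng = np.random.default_rng(seed)
    out: dict[str, list[PredictorStack]] = {}
    for scen, deltas in scenario_deltas.items():
        members = []
        for _ in range(n_gcms):
            layers = {}
            for name, grid in stack.items():
                v = grid.values + deltas.get(name, 0.0)
                if gcm_noise_sd > 0:
                    noise = _smooth_field(rng, grid.shape, smoothness)
                    noise = noise / noise.std() * gcm_noise_sd
                    v = v + noise
                layers[name] = grid.with_values(v)
            members.append(PredictorStack(layers, harmonise_mask=False))
        out[scen] = members
    return out


def make_zones(extent, n_zones: int, seed: int = 0) -> ZoneSet:
    """Voronoi polygons of seeded random points, clipped to the extent.

    The polygons partition the extent exactly (no gaps or overlaps beyond
    float rounding), standing in for states/bioregions/protected areas.
    """
    x0, y0, x1, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise GridError("degenerate extent")
    if n_zones < 1:
        raise ValueError("need at least one zone")
    frame = box(x0, y0, x1, y1)
    if n_zones == 1:
        return ZoneSet(["zone_01"], [frame])
    rng = np.random.default_rng(seed)
    pts = np.column_stack([
        rng.uniform(x0, x1, size=n_zones),
        rng.uniform(y0, y1, size=n_zones),
    ])
    cells = voronoi_diagram(MultiPoint([Point(*p) for p in pts]), envelope=frame)
    polys: list = [None] * n_zones
    for cell in cells.geoms:
        clipped = cell.intersection(frame)
        for k, p in enumerate(pts):
            if polys[k] is None and cell.covers(Point(*p)):
                polys[k] = clipped
                break
    if any(p is None for p in polys):
        raise RuntimeError("voronoi cell assignment failed")
    labels = [f"zone_{k + 1:02d}" for k in range(n_zones)]
    return ZoneSet(labels, polys)


STATUSES = ("operating", "under_construction", "proposed")


def make_windfarms(extent, n_farms: int, capacity_range_mw=(10.0, 400.0),
                   status_probs=(1 / 3, 1 / 3, 1 / 3), seed: int = 0) -> pd.DataFrame:
    """Random wind-farm points with capacity (MW) and development status."""
    x0, y0, x1, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise GridError("degenerate extent")
    lo, hi = capacity_range_mw
    if lo <= 0 or hi < lo:
        raise ValueError("capacities must be positive")
    probs = np.asarray(status_probs, dtype=float)
    if probs.min() < 0 or probs.sum() <= 0:
        raise ValueError("invalid status probabilities")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "name": [f"farm_{k + 1:03d}" for k in range(n_farms)],
            "x": rng.uniform(x0, x1, size=n_farms),
            "y": rng.uniform(y0, y1, size=n_farms),
            "capacity_mw": rng.uniform(lo, hi, size=n_farms),
            "status": rng.choice(STATUSES, size=n_farms, p=probs / probs.sum()),
        }
    )
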