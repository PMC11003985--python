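"""Spatial statistics for brain-wide cell-position data.

Four analyses applied to 2D projections of detected cell positions:

* PCA axes of the point cloud, giving data-driven anatomical directions.
* Parcellation: parallel section lines perpendicular to the first principal
  axis (optionally crossed with a second family along the first axis),
  spaced a fixed distance apart, and the fraction of cells per parcel.
* Smoothed density maps: Gaussian kernel density (Scott bandwidth) on a
  uniform grid with padded limits, plus contour lines.
* Barrel-wise enrichment: an area-normalized relative fraction index
  ``fr_b = (#Cells_b / #Cells_tot) * (#Area_tot / #Area_b)`` per barrel
  column, tested against a null built by uniformly repositioning all cells
  of a layer over the barrel field (one-tailed permutation test).

Positions are in abstract atlas pixels; a raster of integer labels encodes
the barrel masks (0 = background/septa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import Polygon
from shapely.ops import unary_union
from sklearn.decomposition import PCA

from whiskvis.exceptions import DegenerateGeometryError, InvalidParameterError

__all__ = [
    "CellCloud", "BarrelMap", "ParcellationResult", "DensityMap",
    "PermutationResult", "CoverageResult",
    "pca_axes", "parcellate", "density_map",
    "barrel_fraction_index", "barrel_permutation_test",
    "parcel_visual_coverage",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CellCloud:
    """Labeled 3D point cloud of detected cells (atlas-like units)."""

    points: np.ndarray
    labels: np.ndarray
    projection_axes: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidParameterError("points must be an (N, 3) array")
        if self.points.shape[0] < 1:
            raise InvalidParameterError("need at least one point")
        if not np.all(np.isfinite(self.points)):
            raise InvalidParameterError("points must be finite")
        if len(self.labels) != len(self.points):
            raise InvalidParameterError("labels must match points in length")

    @property
    def points2d(self) -> np.ndarray:
        """Projection onto the configured 2D working plane."""
        return self.points[:, list(self.projection_axes)]

    def subset(self, label: str) -> np.ndarray:
        return self.points2d[self.labels == label]


@dataclass
class BarrelMap:
    """2D integer label raster of barrel columns (0 = background/septa)."""

    raster: np.ndarray
    pixel_area: float = 1.0

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise InvalidParameterError("raster must be 2D")
        if not np.issubdtype(self.raster.dtype, np.integer):
            raise InvalidParameterError("raster must hold integer labels")
        if self.raster.min() < 0:
            raise InvalidParameterError("labels must be non-negative")
        if len(self.barrel_ids) == 0:
            raise InvalidParameterError("raster must contain at least one barrel")

    @property
    def barrel_ids(self) -> np.ndarray:
        ids = np.unique(self.raster)
        return ids[ids > 0]

    @property
    def areas(self) -> dict[int, int]:
        """Pixel count per barrel."""
        ids, counts = np.unique(self.raster[self.raster > 0],
                                return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def area_total(self) -> int:
        """Pixel count of the whole depicted barrel field (the raster)."""
        return int(self.raster.size)

    def labels_at(self, xy: np.ndarray) -> np.ndarray:
        """Barrel label at each (x, y) position; 0 outside the raster.

        Pixel convention: position (x, y) falls in raster[int(y), int(x)];
        cells exactly on a mask boundary take that pixel's label.
        """
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        col = np.floor(xy[:, 0]).astype(int)
        row = np.floor(xy[:, 1]).astype(int)
        h, w = self.raster.shape
        ok = (col >= 0) & (col < w) & (row >= 0) & (row < h)
        out = np.zeros(len(xy), dtype=self.raster.dtype)
        out[ok] = self.raster[row[ok], col[ok]]
        return out


@dataclass
class ParcellationResult:
    """PC axes, section lines, and per-parcel cell fractions.

    ``section_lines`` holds ``(slope, intercept)`` pairs in the working
    plane; a vertical line is encoded as ``(inf, x-position)``.  ``parcels``
    maps parcel ids ``(i1, i2)`` (strip indices along pc1 and pc2; ``i2`` is
    always 0 without the cross grid) to polygonal cells covering the data
    extent.
    """

    pc1: np.ndarray
    pc2: np.ndarray
    explained: np.ndarray
    section_lines: list[tuple[float, float]]
    parcels: dict[tuple[int, int], Polygon]
    per_parcel_fraction: dict[tuple[int, int], float]
    assignments: np.ndarray  # (N, 2) strip indices per point
    spacing: float


@dataclass
class DensityMap:
    """Gaussian-KDE density on a regular grid, evaluated with padded limits.

    ``x``/``y``/``density`` cover the unpadded data extent (the padding is
    cut off after evaluation); the ``padded_*`` fields keep the full
    evaluation for normalization checks.  ``contours`` is a list of
    polylines (arrays of (x, y)) at automatically chosen levels.
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    argmax: tuple[float, float]
    contours: list[np.ndarray]
    levels: np.ndarray
    padded_x: np.ndarray
    padded_y: np.ndarray
    padded_density: np.ndarray
    bandwidth: tuple[float, float]


@dataclass
class PermutationResult:
    """Observed enrichment indices, permutation nulls and significance."""

    layers: list[str]
    barrel_ids: np.ndarray
    fr_obs: dict[str, np.ndarray]
    null: dict[str, np.ndarray]  # (n_shuffles, n_barrels) per layer
    p: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]
    alpha: float
    n_shuffles: int
    method: str


@dataclass
class CoverageResult:
    """Visual-space patches per parcel and the merged high-fraction region."""

    patches: dict[tuple[int, int], Polygon]
    weights: dict[tuple[int, int], float]
    merged: Polygon
    threshold: float


# ---------------------------------------------------------------------------
# PCA axes and parcellation
# ---------------------------------------------------------------------------

def pca_axes(points2d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First two principal axes of a 2D point cloud.

    Returns unit vectors ``pc1``, ``pc2`` and the explained-variance
    fractions (descending, summing to 1).  Sign convention: ``pc1`` has a
    non-negative x-component (ties broken toward +y); ``pc2`` completes a
    right-handed pair.
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points2d must be an (N, 2) array")
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise DegenerateGeometryError(
            "need at least two non-identical points for PCA")
    pca = PCA(n_components=2).fit(pts)
    pc1 = pca.components_[0]
    if pc1[0] < 0 or (pc1[0] == 0 and pc1[1] < 0):
        pc1 = -pc1
    pc2 = np.array([-pc1[1], pc1[0]])  # right-handed orthonormal complement
    explained = pca.explained_variance_ratio_.copy()
    return pc1, pc2, explained


def _strip_index(proj: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    # a point exactly on a boundary belongs to the lower-index side
    return np.searchsorted(bounds, proj, side="left")


def _boundaries(proj: np.ndarray, spacing: float) -> np.ndarray:
    span = proj.max() - proj.min()
    n = int(np.floor(span / spacing + 1e-12))
    return proj.min() + spacing * np.arange(1, n + 1)


def _line_params(direction: np.ndarray, point: np.ndarray
                 ) -> tuple[float, float]:
    """(slope, intercept) of the line through ``point`` along ``direction``;
    vertical lines are encoded as (inf, x-position)."""
    dx, dy = direction
    if abs(dx) < 1e-12:
        return (float("inf"), float(point[0]))
    slope = dy / dx
    return (float(slope), float(point[1] - slope * point[0]))


def parcellate(points2d: np.ndarray,
               axes: tuple[np.ndarray, np.ndarray] | None = None,
               spacing: float = 200.0,
               cross: bool = False) -> ParcellationResult:
    """Section a point cloud into strips perpendicular to its first PC axis.

    Section lines have the slope of the second principal component, are
    mutually parallel and spaced exactly ``spacing`` apart along the first
    component (implemented by shifting their intercepts).  With
    ``cross=True`` a second family along pc1 cuts the strips into a grid
    (used for 2D parcellation of horizontal projections).  Every point is
    assigned to exactly one parcel; points on a line belong to the
    lower-index side.
    """
    pts = np.asarray(points2d, dtype=float)
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    if axes is None:
        pc1, pc2, explained = pca_axes(pts) if len(pts) > 1 and \
            not np.allclose(pts, pts[0]) else (np.array([1.0, 0.0]),
                                               np.array([0.0, 1.0]),
                                               np.array([1.0, 0.0]))
    else:
        pc1, pc2 = np.asarray(axes[0], float), np.asarray(axes[1], float)
        explained = np.array([np.nan, np.nan])

    proj1 = pts @ pc1
    proj2 = pts @ pc2
    bounds1 = _boundaries(proj1, spacing)
    idx1 = _strip_index(proj1, bounds1)
    if cross:
        bounds2 = _boundaries(proj2, spacing)
        idx2 = _strip_index(proj2, bounds2)
    else:
        bounds2 = np.array([])
        idx2 = np.zeros(len(pts), dtype=int)

    lines = [_line_params(pc2, c * pc1) for c in bounds1]
    lines += [_line_params(pc1, c * pc2) for c in bounds2]

    # polygonal parcels: strip rectangles in PC coordinates mapped back
    e1 = np.concatenate([[proj1.min()], bounds1, [max(proj1.max(),
                                                      bounds1[-1] if len(bounds1) else proj1.min())]]) \
        if len(bounds1) else np.array([proj1.min(), proj1.max()])
    e2 = np.concatenate([[proj2.min()], bounds2, [proj2.max()]]) \
        if len(bounds2) else np.array([proj2.min(), proj2.max()])
    if e1[-1] <= e1[-2]:
        e1[-1] = e1[-2] + spacing  # keep last (possibly empty) strip non-degenerate
    parcels: dict[tuple[int, int], Polygon] = {}
    for i in range(len(e1) - 1):
        for j in range(len(e2) - 1):
            corners_pc = [(e1[i], e2[j]), (e1[i + 1], e2[j]),
                          (e1[i + 1], e2[j + 1]), (e1[i], e2[j + 1])]
            xy = [c1 * pc1 + c2 * pc2 for c1, c2 in corners_pc]
            parcels[(i, j)] = Polygon(xy)

    n = len(pts)
    counts: dict[tuple[int, int], int] = {}
    for i, j in zip(idx1, idx2):
        counts[(int(i), int(j))] = counts.get((int(i), int(j)), 0) + 1
    frac = {pid: c / n for pid, c in counts.items()}

    return ParcellationResult(pc1=pc1, pc2=pc2, explained=explained,
                              section_lines=lines, parcels=parcels,
                              per_parcel_fraction=frac,
                              assignments=np.column_stack([idx1, idx2]),
                              spacing=spacing)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def density_map(points2d: np.ndarray,
                grid_step: float = 58.0,
                padding_bandwidths: float = 3.0,
                rng: np.random.Generator | None = None) -> DensityMap:
    """Smoothed cell-density map: Gaussian KDE on a uniform grid.

    The kernel bandwidth follows Scott's rule; the grid spans the data
    limits padded by ``padding_bandwidths`` kernel bandwidths per side (to
    relax edge effects), and the padding is cut off after evaluation.
    Contour levels are chosen automatically (matplotlib's locator).
    """
    pts = np.asarray(points2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise InvalidParameterError("need at least two 2D points")
    if grid_step <= 0:
        raise InvalidParameterError("grid_step must be positive")
    try:
        kde = gaussian_kde(pts.T, bw_method="scott")
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; jittering points for KDE")
        rng = rng or np.random.default_rng(0)
        scale = max(np.ptp(pts), 1.0) * 1e-6
        pts = pts + rng.normal(0.0, scale, size=pts.shape)
        kde = gaussian_kde(pts.T, bw_method="scott")

    bw = kde.factor * pts.std(axis=0, ddof=1)
    (x0, y0), (x1, y1) = pts.min(axis=0), pts.max(axis=0)
    pad = padding_bandwidths * bw
    gx = np.arange(x0 - pad[0], x1 + pad[0] + grid_step, grid_step)
    gy = np.arange(y0 - pad[1], y1 + pad[1] + grid_step, grid_step)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)

    keep_x = (gx >= x0) & (gx <= x1)
    keep_y = (gy >= y0) & (gy <= y1)
    d_cut = dens[np.ix_(keep_x, keep_y)]
    gx_cut, gy_cut = gx[keep_x], gy[keep_y]
    if d_cut.size == 0:  # degenerate extent smaller than one step
        d_cut, gx_cut, gy_cut = dens, gx, gy
    i, j = np.unravel_index(np.argmax(d_cut), d_cut.shape)
    argmax = (float(gx_cut[i]), float(gy_cut[j]))

    contours, levels = _auto_contours(gx_cut, gy_cut, d_cut)
    return DensityMap(x=gx_cut, y=gy_cut, density=d_cut, argmax=argmax,
                      contours=contours, levels=levels,
                      padded_x=gx, padded_y=gy, padded_density=dens,
                      bandwidth=(float(bw[0]), float(bw[1])))


def _auto_contours(gx: np.ndarray, gy: np.ndarray, dens: np.ndarray
                   ) -> tuple[list[np.ndarray], np.ndarray]:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if min(dens.shape) < 2:
        return [], np.array([])
    fig, ax = plt.subplots()
    try:
        cs = ax.contour(gx, gy, dens.T)  # automatic level selection
        polylines = [np.asarray(p.vertices)
                     for path in cs.get_paths() for p in [path]]
        levels = np.asarray(cs.levels)
    finally:
        plt.close(fig)
    return polylines, levels


# ---------------------------------------------------------------------------
# barrel enrichment
# ---------------------------------------------------------------------------

def barrel_fraction_index(cells_per_layer: Mapping[str, np.ndarray],
                          barrel_map: BarrelMap) -> dict[str, dict[int, float]]:
    """Relative fraction index ``fr_b`` per barrel and layer.

    ``fr_b = (#Cells_b / #Cells_tot) * (#Area_tot / #Area_b)`` where
    ``#Cells_tot`` is the total cell count over *all* layers (putting both
    layers on the same scale) and areas are pixel counts of barrel ``b``
    and of the whole depicted barrel field.  Cells outside every barrel
    contribute to ``#Cells_tot`` only.
    """
    areas = barrel_map.areas
    area_tot = barrel_map.area_total
    for b, a in areas.items():
        if a == 0:
            raise InvalidParameterError(f"barrel {b} has zero area")
    n_tot = sum(len(np.asarray(c).reshape(-1, 2))
                for c in cells_per_layer.values())
    if n_tot == 0:
        raise InvalidParameterError("no cells in any layer")
    out: dict[str, dict[int, float]] = {}
    for layer, cells in cells_per_layer.items():
        labels = barrel_map.labels_at(cells)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        count_map = dict(zip(ids.tolist(), counts.tolist()))
        out[layer] = {int(b): (count_map.get(b, 0) / n_tot)
                      * (area_tot / areas[b])
                      for b in barrel_map.barrel_ids}
    return out


def barrel_permutation_test(cells_per_layer: Mapping[str, np.ndarray],
                            barrel_map: BarrelMap,
                            n_shuffles: int = 2500,
                            alpha: float = 0.001,
                            seed: int | np.random.Generator | None = None,
                            method: Literal["per-barrel", "max-stat"]
                            = "per-barrel") -> PermutationResult:
    """One-tailed permutation test of per-barrel enrichment.

    For each layer, the null repositions all of that layer's cells
    uniformly over the whole rectangular barrel-field region (septa
    included) and recomputes ``fr_b``; under this null the per-barrel cell
    counts are exactly multinomial with probabilities proportional to
    barrel pixel areas, which is how the shuffles are drawn.  Empirical
    p-values use the add-one rule, ``p = (1 + #{fr_sh >= fr_obs}) /
    (1 + n_shuffles)``, so they are never zero; ``method="max-stat"``
    instead compares each observed index against the per-shuffle maximum
    over barrels (family-wise control).
    """
    if n_shuffles < 100:
        raise InvalidParameterError("n_shuffles must be at least 100")
    if seed is None:
        raise InvalidParameterError("a seed is required for the shuffles")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    for layer, cells in cells_per_layer.items():
        if len(np.asarray(cells).reshape(-1, 2)) < 1:
            raise InvalidParameterError(f"layer {layer!r} has no cells")

    fr_obs_all = barrel_fraction_index(cells_per_layer, barrel_map)
    ids = barrel_map.barrel_ids
    areas = barrel_map.areas
    area_tot = barrel_map.area_total
    area_vec = np.array([areas[int(b)] for b in ids], dtype=float)
    n_tot = sum(len(np.asarray(c).reshape(-1, 2))
                for c in cells_per_layer.values())

    # uniform over the rectangular field: P(cell in barrel b) = area_b / area_tot
    probs = np.concatenate([area_vec / area_tot,
                            [1.0 - area_vec.sum() / area_tot]])
    scale = area_tot / area_vec / n_tot  # fr = count * scale

    fr_obs: dict[str, np.ndarray] = {}
    null: dict[str, np.ndarray] = {}
    pvals: dict[str, np.ndarray] = {}
    signif: dict[str, np.ndarray] = {}
    for layer, cells in cells_per_layer.items():
        n_layer = len(np.asarray(cells).reshape(-1, 2))
        obs = np.array([fr_obs_all[layer][int(b)] for b in ids])
        counts = rng.multinomial(n_layer, probs, size=n_shuffles)[:, :-1]
        fr_sh = counts * scale
        if method == "per-barrel":
            exceed = (fr_sh >= obs).sum(axis=0)
        elif method == "max-stat":
            exceed = (fr_sh.max(axis=1)[:, None] >= obs).sum(axis=0)
        else:
            raise InvalidParameterError(f"unknown method {method!r}")
        p = (1.0 + exceed) / (1.0 + n_shuffles)
        fr_obs[layer] = obs
        null[layer] = fr_sh
        pvals[layer] = p
        signif[layer] = p < alpha

    return PermutationResult(layers=list(cells_per_layer), barrel_ids=ids,
                             fr_obs=fr_obs, null=null, p=pvals,
                             significant=signif, alpha=alpha,
                             n_shuffles=n_shuffles, method=method)


# ---------------------------------------------------------------------------
# visual-space assignment of parcels
# ---------------------------------------------------------------------------

def parcel_visual_coverage(parcellation: ParcellationResult,
                           retinotopy: Callable[[np.ndarray], np.ndarray],
                           threshold: float = 0.05,
                           densify: float | None = None) -> CoverageResult:
    """Assign visual-space coordinates to cortical parcels.

    Each parcel polygon's boundary vertices are mapped through the
    retinotopy (cortical (x, y) -> (azimuth, elevation)); the parcel's cell
    fraction becomes the patch weight.  Parcels with vertices outside the
    retinotopy's rectangular ``domain`` (if the interpolant declares one)
    are excluded with a warning.  ``merged`` is the union of patches whose
    fraction reaches ``threshold``.
    """
    domain = getattr(retinotopy, "domain", None)
    patches: dict[tuple[int, int], Polygon] = {}
    weights: dict[tuple[int, int], float] = {}
    to_merge = []
    for pid, poly in parcellation.parcels.items():
        frac = parcellation.per_parcel_fraction.get(pid, 0.0)
        if frac == 0.0:
            continue
        boundary = poly.exterior
        if densify:
            boundary = boundary.segmentize(densify)
        xy = np.asarray(boundary.coords)
        if domain is not None:
            x0, x1, y0, y1 = domain
            tol = 1e-9 * max(abs(x1 - x0), abs(y1 - y0), 1.0)
            if (xy[:, 0].min() < x0 - tol or xy[:, 0].max() > x1 + tol
                    or xy[:, 1].min() < y0 - tol or xy[:, 1].max() > y1 + tol):
                warnings.warn(
                    f"parcel {pid} lies outside the retinotopy domain; "
                    "excluded")
                continue
        mapped = np.asarray(retinotopy(xy))
        patch = Polygon(mapped)
        if not patch.is_valid:
            patch = patch.buffer(0)
        patches[pid] = patch
        weights[pid] = frac
        if frac >= threshold:
            to_merge.append(patch)
    merged = unary_union(to_merge) if to_merge else Polygon()
    return CoverageResult(patches=patches, weights=weights,
                          merged=merged, threshold=threshold)
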