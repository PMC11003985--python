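"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of ``(config, seed)`` and returns the
domain object together with a plain-dict "sidecar" recording the latent
ground truth used (axis directions, variance splits, enrichment factors,
eye position, ...), which the recovery tests consume.  Independent RNG
streams are derived per generator by hashing the block name into the
master seed's spawn key, so adding draws to one generator never perturbs
another.

What the generators emulate — and what they do not: the whisker generator
produces a 24-whisker left mystacial pad (rows A–E, arcs 1–4 plus the
greek straddlers alpha–delta) with caudal whiskers longest and planar
intrinsic curvature, but real whisker shapes are traced, not parametric;
the cell-cloud and barrel generators reproduce the *statistical* structure
(anisotropy, density gradients, per-barrel enrichment) of imaged cell
maps, not their anatomy.  Units: mm for geometry, abstract atlas pixels
for clouds and rasters, degrees for angular data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from whiskvis.exceptions import InvalidParameterError
from whiskvis.geometry import (
    ARCS, GREEK_LABELS, ROWS, VisualSpaceMap, Whisker, WhiskerArray,
)
from whiskvis.spatial import BarrelMap, CellCloud

__all__ = [
    "GeneratorConfig", "WhiskerGenConfig", "VisualSpaceConfig",
    "CloudConfig", "BarrelGenConfig", "RetinotopyConfig",
    "derive_rng", "gen_whisker_array", "gen_visual_space",
    "gen_cell_cloud", "gen_barrel_map", "gen_retinotopy", "Retinotopy",
]


def derive_rng(seed: int, block: str) -> np.random.Generator:
    """Independent RNG stream for one generator block of a master seed."""
    key = zlib.crc32(block.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class WhiskerGenConfig:
    """Parametric left whisker pad.

    Basepoints sit on a grid over the mystacial pad (caudal arcs at low x);
    nominal lengths decrease rostrally (greek/arc-1 whiskers longest);
    emergence azimuths point caudo-laterally at rest, elevations follow the
    row (dorsal rows up).  ``curvature`` is the quadratic sag per unit
    squared arc position (dimensionless fraction of length).
    """

    #: nominal length (mm) per arc, caudal to rostral
    length_by_arc: Mapping[str, float] = field(default_factory=lambda: {
        "greek": 22.0, "1": 19.0, "2": 15.0, "3": 11.0, "4": 8.0})
    #: emergence azimuth (deg from nose-ward axis) per arc at rest
    azimuth_by_arc: Mapping[str, float] = field(default_factory=lambda: {
        "greek": 135.0, "1": 125.0, "2": 115.0, "3": 105.0, "4": 95.0})
    #: emergence elevation (deg) per row
    elevation_by_row: Mapping[str, float] = field(default_factory=lambda: {
        "A": 25.0, "B": 12.0, "C": 0.0, "D": -12.0, "E": -25.0})
    pad_origin: tuple[float, float, float] = (4.0, 5.0, 2.0)
    arc_spacing: float = 2.0      # mm along x (rostral)
    row_spacing: float = 1.0      # mm along -z (ventral)
    pad_bulge: float = 0.3        # mm lateral bulge at pad center
    curvature: float = 0.18      # fractional quadratic sag
    angle_jitter: float = 3.0     # deg s.d. on emergence angles
    length_jitter: float = 0.04   # fractional s.d. on lengths
    zeta_jitter: float = 8.0      # deg s.d. on twist around ventral (0 deg)
    n_points: int = 50            # polyline samples
    eye: tuple[float, float, float] = (0.0, 3.0, 5.0)


@dataclass
class VisualSpaceConfig:
    """VISp coverage template: lower nasal visual field of the left eye,
    azimuth 0–90 deg, elevation −25 to +60 deg."""

    azimuth_range: tuple[float, float] = (0.0, 90.0)
    elevation_range: tuple[float, float] = (-25.0, 60.0)
    dilation: float = 0.0


@dataclass
class CloudConfig:
    """Anisotropic Gaussian-mixture cell cloud in atlas pixels."""

    n: int = 10_000
    center: tuple[float, float] = (500.0, 500.0)
    axis_angle_deg: float = 30.0   # direction of the dominant 2D axis
    total_std: float = 300.0       # sqrt of total 2D variance
    var_split: float = 0.8         # fraction of variance along the main axis
    n_components: int = 1
    component_offset: float = 0.0  # spacing of extra components along axis
    z_center: float = 100.0
    z_std: float = 20.0
    layer: str = "L2/3"


@dataclass
class BarrelGenConfig:
    """Grid of elliptical barrel columns plus enriched cells."""

    n_rows: int = 4
    n_cols: int = 5
    pitch: int = 100               # px between barrel centers
    radius: tuple[int, int] = (40, 40)
    margin: int = 50               # px border around the grid
    n_cells: int = 2000
    layers: tuple[str, ...] = ("L2/3", "L6")
    layer_weights: tuple[float, ...] = (0.5, 0.5)
    #: per-barrel density multiplier (barrel id -> factor); 1 elsewhere
    enrichment: Mapping[int, float] = field(default_factory=dict)


@dataclass
class RetinotopyConfig:
    """Cortical (x, y) -> visual (azimuth, elevation) map over a box."""

    kind: Literal["identity", "affine", "gradient"] = "affine"
    domain: tuple[float, float, float, float] = (0.0, 1000.0, 0.0, 1000.0)
    azimuth_range: tuple[float, float] = (0.0, 90.0)
    elevation_range: tuple[float, float] = (-25.0, 60.0)
    warp: float = 0.15             # relative sinusoidal warp (gradient kind)


@dataclass
class GeneratorConfig:
    """Master configuration: one block per generator plus the seed."""

    seed: int
    whiskers: WhiskerGenConfig = field(default_factory=WhiskerGenConfig)
    visual_space: VisualSpaceConfig = field(default_factory=VisualSpaceConfig)
    cloud: CloudConfig = field(default_factory=CloudConfig)
    barrels: BarrelGenConfig = field(default_factory=BarrelGenConfig)
    retinotopy: RetinotopyConfig = field(default_factory=RetinotopyConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")


# ---------------------------------------------------------------------------
# whisker array
# ---------------------------------------------------------------------------

def _unit_from_angles(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    az, el = np.deg2rad(azimuth_deg), np.deg2rad(elevation_deg)
    return np.array([np.cos(el) * np.cos(az),
                     np.cos(el) * np.sin(az),
                     np.sin(el)])


def _build_whisker(row: str, arc: str, basepoint: np.ndarray, phi_w: float,
                   theta_w: float, zeta_w: float, nominal_length: float,
                   curvature: float, n_points: int) -> Whisker:
    from whiskvis.geometry import rotate_about

    t = _unit_from_angles(theta_w, phi_w)
    # ventral curvature direction: -z projected out of the tangent
    down = np.array([0.0, 0.0, -1.0])
    c = down - (down @ t) * t
    c = c / np.linalg.norm(c)
    # twist selects the curvature plane (0 deg = ventral)
    c = rotate_about(c[None, :], np.zeros(3), t, zeta_w)[0]

    s = np.linspace(0.0, 1.0, n_points)[:, None]
    poly = basepoint + s * nominal_length * t \
        + curvature * (s ** 2) * nominal_length * c
    length = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
    return Whisker(row=row, arc=arc, basepoint=basepoint, phi_w=phi_w,
                   theta_w=theta_w, zeta_w=zeta_w, length=length,
                   polyline=poly)


def gen_whisker_array(config: WhiskerGenConfig | None = None,
                      seed: int = 0) -> tuple[WhiskerArray, dict]:
    """Generate a 24-whisker left pad with eye position and ground truth.

    The 20 row/arc whiskers occupy a 5x4 grid; the four greek whiskers
    (alpha-delta, rows A-D) sit one arc spacing caudal to arc 1.  Mean
    nominal length decreases monotonically from greek/arc-1 to arc-4.
    """
    cfg = config or WhiskerGenConfig()
    rng = derive_rng(seed, "whiskers")
    x0, y0, z0 = cfg.pad_origin
    whiskers = []
    truth_angles = {}
    for ri, row in enumerate(ROWS):
        for arc in ARCS:
            if arc == "greek":
                if row == "E":
                    continue
                x = x0
                z = z0 - (ri + 0.5) * cfg.row_spacing
            else:
                x = x0 + int(arc) * cfg.arc_spacing
                z = z0 - ri * cfg.row_spacing
            # lateral pad bulge, maximal at the pad center
            mid = 2.5 * cfg.arc_spacing
            y = y0 + cfg.pad_bulge * (1 - ((x - x0 - mid) / mid) ** 2)
            base = np.array([x, y, z])

            theta = cfg.azimuth_by_arc[arc] + rng.normal(0, cfg.angle_jitter)
            phi = cfg.elevation_by_row[row] + rng.normal(0, cfg.angle_jitter)
            zeta = rng.normal(0.0, cfg.zeta_jitter)
            L = cfg.length_by_arc[arc] * (1 + rng.normal(0, cfg.length_jitter))
            w = _build_whisker(row, arc, base, phi, theta, zeta, L,
                               cfg.curvature, cfg.n_points)
            whiskers.append(w)
            truth_angles[w.label] = {"phi_w": phi, "theta_w": theta,
                                     "zeta_w": zeta, "nominal_length": L}
    array = WhiskerArray(whiskers=whiskers, eye=np.array(cfg.eye),
                         head_frame=np.eye(3))
    sidecar = {"seed": seed, "block": "whiskers", "units": "mm",
               "eye": list(cfg.eye), "curvature": cfg.curvature,
               "length_by_arc": dict(cfg.length_by_arc),
               "angles": truth_angles}
    return array, sidecar


def gen_visual_space(config: VisualSpaceConfig | None = None,
                     seed: int = 0) -> tuple[VisualSpaceMap, dict]:
    """VISp visual-space coverage polygon (deterministic template).

    A rectangle over the configured azimuth/elevation ranges with the
    temporal-dorsal corner bevelled, approximating the wedge-shaped
    coverage of retinotopic maps.
    """
    cfg = config or VisualSpaceConfig()
    a0, a1 = cfg.azimuth_range
    e0, e1 = cfg.elevation_range
    bevel_a = a0 + 0.7 * (a1 - a0)
    bevel_e = e0 + 0.7 * (e1 - e0)
    vertices = np.array([
        [a0, e0], [a1, e0], [a1, bevel_e], [bevel_a, e1], [a0, e1]])
    vmap = VisualSpaceMap(vertices=vertices, dilation=cfg.dilation)
    sidecar = {"seed": seed, "block": "visual_space", "units": "deg",
               "azimuth_range": list(cfg.azimuth_range),
               "elevation_range": list(cfg.elevation_range)}
    return vmap, sidecar


# ---------------------------------------------------------------------------
# cell clouds and barrel maps
# ---------------------------------------------------------------------------

def gen_cell_cloud(config: CloudConfig | None = None,
                   seed: int = 0) -> tuple[CellCloud, dict]:
    """Anisotropic 3D cell cloud with a known 2D axis and variance split."""
    cfg = config or CloudConfig()
    if not 0.5 <= cfg.var_split < 1.0:
        raise InvalidParameterError("var_split must be in [0.5, 1)")
    rng = derive_rng(seed, "cloud")
    ang = np.deg2rad(cfg.axis_angle_deg)
    u = np.array([np.cos(ang), np.sin(ang)])
    v = np.array([-np.sin(ang), np.cos(ang)])
    s1 = cfg.total_std * np.sqrt(cfg.var_split)
    s2 = cfg.total_std * np.sqrt(1 - cfg.var_split)

    comp = rng.integers(0, cfg.n_components, size=cfg.n)
    offsets = (comp - (cfg.n_components - 1) / 2) * cfg.component_offset
    a = rng.normal(0, s1, cfg.n) + offsets
    b = rng.normal(0, s2, cfg.n)
    xy = np.asarray(cfg.center) + a[:, None] * u + b[:, None] * v
    z = rng.normal(cfg.z_center, cfg.z_std, cfg.n)
    points = np.column_stack([xy, z])
    labels = np.full(cfg.n, cfg.layer)
    cloud = CellCloud(points=points, labels=labels)
    sidecar = {"seed": seed, "block": "cloud", "units": "atlas px",
               "axis_angle_deg": cfg.axis_angle_deg,
               "var_split": cfg.var_split, "center": list(cfg.center),
               "density_peak": list(cfg.center), "n": cfg.n}
    return cloud, sidecar


def gen_barrel_map(config: BarrelGenConfig | None = None,
                   seed: int = 0
                   ) -> tuple[BarrelMap, dict[str, np.ndarray], dict]:
    """Elliptical barrel-column raster plus per-layer enriched cells.

    Returns ``(barrel_map, cells_per_layer, sidecar)``.  Cells are placed
    uniformly over the rectangular field except that pixels of barrel ``b``
    are oversampled by ``enrichment[b]`` (default 1 = uniform expectation).
    """
    cfg = config or BarrelGenConfig()
    rng = derive_rng(seed, "barrels")
    h = 2 * cfg.margin + (cfg.n_rows - 1) * cfg.pitch
    w = 2 * cfg.margin + (cfg.n_cols - 1) * cfg.pitch
    raster = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    bid = 0
    centers = {}
    for r in range(cfg.n_rows):
        for c in range(cfg.n_cols):
            bid += 1
            cy = cfg.margin + r * cfg.pitch
            cx = cfg.margin + c * cfg.pitch
            mask = (((xx - cx) / cfg.radius[0]) ** 2
                    + ((yy - cy) / cfg.radius[1]) ** 2) <= 1.0
            raster[mask] = bid
            centers[bid] = (cx, cy)
    barrel_map = BarrelMap(raster=raster)

    # per-pixel sampling weights: enrichment factor inside barrels, 1 outside
    weights = np.ones(raster.size)
    flat = raster.ravel()
    for b, f in cfg.enrichment.items():
        if f < 0:
            raise InvalidParameterError("enrichment factors must be >= 0")
        weights[flat == b] = f
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]

    if len(cfg.layer_weights) != len(cfg.layers):
        raise InvalidParameterError("layer_weights must match layers")
    n_per = rng.multinomial(cfg.n_cells,
                            np.asarray(cfg.layer_weights, float)
                            / sum(cfg.layer_weights))
    cells: dict[str, np.ndarray] = {}
    for layer, n in zip(cfg.layers, n_per):
        idx = np.searchsorted(cdf, rng.random(n))
        py, px = np.unravel_index(idx, raster.shape)
        cells[layer] = np.column_stack([px + rng.random(n),
                                        py + rng.random(n)])
    sidecar = {"seed": seed, "block": "barrels", "units": "atlas px",
               "n_barrels": bid, "centers": {str(k): list(v)
                                             for k, v in centers.items()},
               "enrichment": {str(k): v for k, v in cfg.enrichment.items()},
               "raster_shape": [h, w]}
    return barrel_map, cells, sidecar


# ---------------------------------------------------------------------------
# retinotopy
# ---------------------------------------------------------------------------

class Retinotopy:
    """Smooth map from cortical (x, y) pixels to (azimuth, elevation) deg.

    Kinds: ``identity`` (degrees equal pixels, for congruence tests),
    ``affine`` (linear gradient over the domain box), and ``gradient``
    (affine plus a sinusoidal warp, still monotone — hence invertible —
    for ``warp`` < 1/(2*pi)).
    """

    def __init__(self, config: RetinotopyConfig):
        self.config = config
        self.domain = config.domain

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        cfg = self.config
        if cfg.kind == "identity":
            return xy.copy()
        x0, x1, y0, y1 = cfg.domain
        u = (xy[:, 0] - x0) / (x1 - x0)
        v = (xy[:, 1] - y0) / (y1 - y0)
        if cfg.kind == "gradient":
            u = u + cfg.warp / (2 * np.pi) * np.sin(2 * np.pi * u)
            v = v + cfg.warp / (2 * np.pi) * np.sin(2 * np.pi * v)
        a0, a1 = cfg.azimuth_range
        e0, e1 = cfg.elevation_range
        return np.column_stack([a0 + u * (a1 - a0), e0 + v * (e1 - e0)])

    def jacobian(self, xy: np.ndarray) -> np.ndarray:
        """Diagonal Jacobian entries (the map is axis-separable)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        cfg = self.config
        if cfg.kind == "identity":
            return np.ones_like(xy)
        x0, x1, y0, y1 = cfg.domain
        u = (xy[:, 0] - x0) / (x1 - x0)
        v = (xy[:, 1] - y0) / (y1 - y0)
        du, dv = np.ones_like(u), np.ones_like(v)
        if cfg.kind == "gradient":
            du = 1 + cfg.warp * np.cos(2 * np.pi * u)
            dv = 1 + cfg.warp * np.cos(2 * np.pi * v)
        a0, a1 = cfg.azimuth_range
        e0, e1 = cfg.elevation_range
        return np.column_stack([du * (a1 - a0) / (x1 - x0),
                                dv * (e1 - e0) / (y1 - y0)])


def gen_retinotopy(config: RetinotopyConfig | None = None,
                   seed: int = 0) -> tuple[Retinotopy, dict]:
    cfg = config or RetinotopyConfig()
    if cfg.kind == "gradient" and not 0 <= cfg.warp < 1.0:
        raise InvalidParameterError("warp must be in [0, 1) for invertibility")
    ret = Retinotopy(cfg)
    sidecar = {"seed": seed, "block": "retinotopy", "kind": cfg.kind,
               "domain": list(cfg.domain),
               "azimuth_range": list(cfg.azimuth_range),
               "elevation_range": list(cfg.elevation_range),
               "warp": cfg.warp}
    return ret, sidecar
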