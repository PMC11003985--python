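"""3D whisker-array geometry and overlap with visual space.

Coordinate conventions (used everywhere in the package):

* Right-handed head frame: ``x`` nose-ward (rostral), ``y`` toward the
  animal's left (lateral on the analysed side), ``z`` up.  The horizontal
  (``xy``) plane is parallel to the bregma–lambda plane.
* Eye-centered spherical coordinates for the left eye: azimuth is measured
  in the horizontal plane from the nose-ward axis (0° straight ahead,
  positive toward left-lateral/caudal), elevation from the horizontal plane
  (positive up).
* Whisker emergence angles: ``phi_w`` (elevation) and ``theta_w`` (azimuth)
  of the tangent at the base; twist ``zeta_w`` selects the plane of the
  whisker's intrinsic curvature (0° = ventrally directed curvature,
  180° dorsal, 90° rostral, -90° caudal).

Whisking kinematics: each row of whiskers moves in a "whisking plane"
fitted through the row's basepoints and tips.  Protraction/retraction is a
rotation of each whisker about its own basepoint around the plane normal
(positive angles protract, i.e. sweep tips nose-ward); the plane itself can
be inclined by rotating it about the row's mean base-to-tip direction; roll
is a rotation of each whisker about its own longitudinal (base-to-tip) axis
by row-specific angles, applied after protraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from shapely.geometry import Point, Polygon

from whiskvis.exceptions import DegenerateGeometryError, InvalidParameterError

ROWS = ("A", "B", "C", "D", "E")
ARCS = ("greek", "1", "2", "3", "4")
GREEK_LABELS = {"A": "alpha", "B": "beta", "C": "gamma", "D": "delta"}

#: Row-specific roll angles (deg) applied at the end of protraction;
#: half the maximal roll excursion reported for the first whisker column.
ROLL_ANGLES = {"A": -36.8, "B": -14.0, "C": 23.8, "D": 16.2, "E": 26.7}

__all__ = [
    "ROWS", "ARCS", "ROLL_ANGLES",
    "Whisker", "WhiskerArray", "WhiskingPlane", "VisualSpaceMap",
    "TipUncertainty", "EyeSpherical", "OverlapResult",
    "rotate_about", "to_eye_spherical", "fit_whisking_plane",
    "fit_whisking_planes", "rotate_in_plane", "incline_planes",
    "apply_roll", "whisk_scenario", "tips_in_space",
    "propagate_tip_uncertainty", "arc_summary",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Whisker:
    """A single whisker: identity, emergence angles, and 3D polyline (mm).

    ``row`` is the mystacial-pad row A–E; ``arc`` is "1"–"4" (caudal to
    rostral) or "greek" for the caudal-most straddlers (alpha–delta, which
    belong kinematically to rows A–D).  The polyline runs base to tip with
    planar intrinsic curvature in the plane selected by ``zeta_w``.
    """

    row: str
    arc: str
    basepoint: np.ndarray
    phi_w: float
    theta_w: float
    zeta_w: float
    length: float
    polyline: np.ndarray

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise InvalidParameterError(f"unknown row {self.row!r}")
        if self.arc not in ARCS:
            raise InvalidParameterError(f"unknown arc {self.arc!r}")
        if self.arc == "greek" and self.row == "E":
            raise InvalidParameterError("greek whiskers span rows A-D only")
        self.basepoint = np.asarray(self.basepoint, dtype=float)
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 3:
            raise InvalidParameterError("polyline must be an (N, 3) array")
        if self.polyline.shape[0] < 2:
            raise InvalidParameterError("polyline needs at least 2 points")
        if not np.allclose(self.polyline[0], self.basepoint, atol=1e-9):
            raise InvalidParameterError("polyline must start at the basepoint")
        arc_len = float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0),
                                              axis=1)))
        if self.length <= 0 or abs(arc_len - self.length) > 0.01 * self.length:
            raise InvalidParameterError(
                f"cumulative chord length {arc_len:.4f} mm deviates more than "
                f"1% from the declared length {self.length:.4f} mm")

    @property
    def label(self) -> str:
        """Conventional name, e.g. ``"C2"`` or ``"alpha"``."""
        if self.arc == "greek":
            return GREEK_LABELS[self.row]
        return f"{self.row}{self.arc}"

    @property
    def tip(self) -> np.ndarray:
        return self.polyline[-1]

    @property
    def chord(self) -> np.ndarray:
        """Base-to-tip vector (the longitudinal roll axis)."""
        return self.tip - self.basepoint

    def with_polyline(self, polyline: np.ndarray, **angles: float) -> "Whisker":
        return replace(self, polyline=np.asarray(polyline, dtype=float),
                       **angles)


@dataclass
class WhiskerArray:
    """The 24 large whiskers of the left mystacial pad plus the left eye."""

    whiskers: list[Whisker]
    eye: np.ndarray
    head_frame: np.ndarray = field(
        default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if len(self.whiskers) != 24:
            raise InvalidParameterError(
                f"a whisker array has exactly 24 whiskers, got "
                f"{len(self.whiskers)}")
        labels = [w.label for w in self.whiskers]
        if len(set(labels)) != 24:
            raise InvalidParameterError("whisker ids must be unique")
        self.eye = np.asarray(self.eye, dtype=float)
        self.head_frame = np.asarray(self.head_frame, dtype=float)
        if not np.all(np.isfinite(self.eye)):
            raise InvalidParameterError("eye position must be finite")
        if self.head_frame.shape != (3, 3) or not np.allclose(
                self.head_frame @ self.head_frame.T, np.eye(3), atol=1e-9):
            raise InvalidParameterError("head_frame must be orthonormal (3x3)")

    def __iter__(self):
        return iter(self.whiskers)

    def __getitem__(self, label: str) -> Whisker:
        for w in self.whiskers:
            if w.label == label:
                return w
        raise KeyError(label)

    def row_whiskers(self, row: str, include_greek: bool = False
                     ) -> list[Whisker]:
        return [w for w in self.whiskers
                if w.row == row and (include_greek or w.arc != "greek")]

    def with_whiskers(self, whiskers: list[Whisker]) -> "WhiskerArray":
        return replace(self, whiskers=whiskers)


@dataclass
class WhiskingPlane:
    """Best-fit plane of one row's whisking motion.

    ``normal`` is the rotation axis for protraction/retraction; the sign is
    chosen so that a positive rotation sweeps tips nose-ward (protraction).
    ``in_plane_mean`` is the row's mean base-to-tip direction projected into
    the plane; inclining the plane rotates ``normal`` about this vector.
    """

    row: str
    normal: np.ndarray
    in_plane_mean: np.ndarray
    inclination: float = 0.0

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.in_plane_mean = np.asarray(self.in_plane_mean, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1) > 1e-9 or \
                abs(np.linalg.norm(self.in_plane_mean) - 1) > 1e-9:
            raise InvalidParameterError("plane vectors must be unit length")
        if abs(float(self.normal @ self.in_plane_mean)) > 1e-9:
            raise InvalidParameterError(
                "normal must be perpendicular to in_plane_mean")


@dataclass
class VisualSpaceMap:
    """Visual-space coverage of VISp as a polygon in (azimuth, elevation) deg.

    ``dilation`` buffers the polygon outward (in degrees) to emulate eye
    movements extending the covered field; the angular domain is small
    enough that planar buffering in degree space is adequate.
    """

    vertices: np.ndarray
    dilation: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.dilation < 0:
            raise InvalidParameterError("dilation must be non-negative")
        if len(self.vertices):
            az, el = self.vertices[:, 0], self.vertices[:, 1]
            if az.min() < -30 or az.max() > 120 or \
                    el.min() < -60 or el.max() > 90:
                raise InvalidParameterError(
                    "polygon outside the sane angular domain "
                    "(azimuth [-30, 120], elevation [-60, 90])")
            poly = Polygon(self.vertices)
            if not poly.is_valid:
                raise InvalidParameterError("polygon is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        if len(self.vertices) < 3:
            return Polygon()
        poly = Polygon(self.vertices)
        if self.dilation > 0:
            poly = poly.buffer(self.dilation)
        return poly

    def dilated(self, degrees: float) -> "VisualSpaceMap":
        return replace(self, dilation=degrees)


@dataclass
class TipUncertainty:
    """Radius of the uncertainty sphere around one whisker tip (mm)."""

    whisker: str
    sphere_radius: float
    components: dict[str, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.sphere_radius) or self.sphere_radius < 0.5:
            raise InvalidParameterError(
                "sphere radius must be finite and at least the 0.5 mm "
                "basepoint floor")


class EyeSpherical(NamedTuple):
    r: float
    azimuth: float
    elevation: float
    at_pole: bool


class OverlapResult(NamedTuple):
    fraction: float
    inside: dict[str, bool]
    tip_coords: pd.DataFrame


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def rotate_about(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                 angle_deg: float) -> np.ndarray:
    """Rotate points about an axis through ``origin`` (Rodrigues rotation)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise DegenerateGeometryError("rotation axis has zero length")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    return rot.apply(np.asarray(points, dtype=float) - origin) + origin


def to_eye_spherical(point: np.ndarray, array: WhiskerArray) -> EyeSpherical:
    """Express a 3D point in the left-eye-centered spherical frame.

    Returns distance (mm), azimuth and elevation (deg).  A point on the
    vertical axis through the eye has undefined azimuth; it is reported as
    0 with ``at_pole=True``.
    """
    v = array.head_frame @ (np.asarray(point, dtype=float) - array.eye)
    r = float(np.linalg.norm(v))
    if r == 0:
        raise DegenerateGeometryError("point coincides with the eye center")
    elevation = float(np.degrees(np.arcsin(np.clip(v[2] / r, -1, 1))))
    horiz = float(np.hypot(v[0], v[1]))
    if horiz < 1e-12 * r:
        return EyeSpherical(r, 0.0, elevation, True)
    azimuth = float(np.degrees(np.arctan2(v[1], v[0])))
    return EyeSpherical(r, azimuth, elevation, False)


# ---------------------------------------------------------------------------
# whisking planes
# ---------------------------------------------------------------------------

def fit_whisking_plane(row_whiskers: Sequence[Whisker],
                       forward: np.ndarray = (1.0, 0.0, 0.0)
                       ) -> WhiskingPlane:
    """Least-squares plane through a row's basepoints and tips.

    The plane normal is the direction of least variance of the 2n points
    (from an SVD of the centered coordinates); its sign is chosen so that a
    positive in-plane rotation moves the mean base-to-tip direction toward
    ``forward`` (nose-ward), making positive angles protraction.
    """
    if len(row_whiskers) < 2:
        raise InvalidParameterError("need at least 2 whiskers to fit a plane")
    rows = {w.row for w in row_whiskers}
    if len(rows) != 1:
        raise InvalidParameterError("whiskers must come from a single row")
    pts = np.concatenate([[w.basepoint, w.tip] for w in row_whiskers])
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "basepoints and tips are collinear; plane is not unique")
    normal = vt[2]

    mean_chord = np.mean([w.chord for w in row_whiskers], axis=0)
    in_plane = mean_chord - (mean_chord @ normal) * normal
    nrm = np.linalg.norm(in_plane)
    if nrm < 1e-12:
        raise DegenerateGeometryError(
            "mean base-to-tip vector is perpendicular to the plane")
    in_plane = in_plane / nrm

    forward = np.asarray(forward, dtype=float)
    if float(np.cross(normal, in_plane) @ forward) < 0:
        normal = -normal
    return WhiskingPlane(row=rows.pop(), normal=normal, in_plane_mean=in_plane)


def fit_whisking_planes(array: WhiskerArray) -> dict[str, WhiskingPlane]:
    """Fit one whisking plane per row A–E from the row's arc 1–4 whiskers."""
    forward = array.head_frame[0]
    return {row: fit_whisking_plane(array.row_whiskers(row), forward)
            for row in ROWS}


def incline_planes(planes: Mapping[str, WhiskingPlane],
                   inclination_deg: float) -> dict[str, WhiskingPlane]:
    """Rotate each plane about its mean base-to-tip vector (inclination)."""
    out = {}
    for row, plane in planes.items():
        normal = rotate_about(plane.normal[None, :], np.zeros(3),
                              plane.in_plane_mean, inclination_deg)[0]
        normal /= np.linalg.norm(normal)
        out[row] = WhiskingPlane(row=row, normal=normal,
                                 in_plane_mean=plane.in_plane_mean,
                                 inclination=plane.inclination
                                 + inclination_deg)
    return out


# ---------------------------------------------------------------------------
# whisking transforms (all isometries about each whisker's basepoint)
# ---------------------------------------------------------------------------

def rotate_in_plane(array: WhiskerArray, angle_deg: float,
                    planes: Mapping[str, WhiskingPlane] | None = None
                    ) -> WhiskerArray:
    """Protract (+) or retract (-) every whisker parallel to its row's plane.

    Each polyline is rotated about the axis through its own basepoint along
    the plane normal; greek whiskers use the plane of their row (alpha-delta
    follow rows A-D).
    """
    if planes is None:
        planes = fit_whisking_planes(array)
    new = []
    for w in array.whiskers:
        if w.row not in planes:
            raise InvalidParameterError(f"no whisking plane for row {w.row!r}")
        poly = rotate_about(w.polyline, w.basepoint,
                            planes[w.row].normal, angle_deg)
        new.append(w.with_polyline(poly))
    return array.with_whiskers(new)


def apply_roll(array: WhiskerArray, scale: float = 1.0) -> WhiskerArray:
    """Rotate each whisker about its own base-to-tip axis by the row angle.

    Applied after protraction; ``scale`` multiplies the row-specific angles
    (0.5, 1 and 2 are the standard variants).  Basepoint and tip lie on the
    axis and are invariant.
    """
    new = []
    for w in array.whiskers:
        chord = w.chord
        if np.linalg.norm(chord) < 1e-12:
            raise DegenerateGeometryError(
                f"whisker {w.label} has zero base-to-tip length")
        angle = scale * ROLL_ANGLES[w.row]
        poly = rotate_about(w.polyline, w.basepoint, chord, angle)
        new.append(w.with_polyline(poly))
    return array.with_whiskers(new)


def whisk_scenario(array: WhiskerArray, angle_deg: float,
                   inclination_deg: float = 0.0,
                   roll_scale: float = 0.0) -> WhiskerArray:
    """Compose a whisking pose: incline planes, rotate in plane, then roll.

    ``angle_deg`` is +40 for full protraction, -40 for full retraction and
    0 for the intermediate (resting) position, which returns the input
    coordinates unchanged when inclination and roll are zero as well.
    """
    if angle_deg == 0.0 and inclination_deg == 0.0 and roll_scale == 0.0:
        return array
    planes = fit_whisking_planes(array)
    if inclination_deg != 0.0:
        planes = incline_planes(planes, inclination_deg)
    out = rotate_in_plane(array, angle_deg, planes)
    if roll_scale != 0.0:
        out = apply_roll(out, roll_scale)
    return out


# ---------------------------------------------------------------------------
# overlap with visual space
# ---------------------------------------------------------------------------

def tips_in_space(array: WhiskerArray, vmap: VisualSpaceMap) -> OverlapResult:
    """Fraction of whisker tips inside the visual-space polygon.

    Tips are converted to eye-centered (azimuth, elevation) and tested
    against the (optionally dilated) polygon; tips exactly on the boundary
    count as inside.
    """
    poly = vmap.polygon
    if not poly.is_valid:
        raise InvalidParameterError("visual-space polygon is invalid")
    rows = []
    inside: dict[str, bool] = {}
    for w in array.whiskers:
        sph = to_eye_spherical(w.tip, array)
        hit = bool(poly.covers(Point(sph.azimuth, sph.elevation))) \
            if not poly.is_empty else False
        inside[w.label] = hit
        rows.append({"whisker": w.label, "r_tip": sph.r,
                     "azimuth": sph.azimuth, "elevation": sph.elevation,
                     "inside": hit})
    fraction = sum(inside.values()) / len(inside)
    return OverlapResult(fraction=fraction, inside=inside,
                         tip_coords=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# uncertainty propagation
# ---------------------------------------------------------------------------

def _perturb_tip(w: Whisker, d_phi: float, d_theta: float, d_zeta: float,
                 up: np.ndarray) -> np.ndarray:
    """Tip position after rotating the whole whisker about its basepoint by
    small adjustments of the emergence/twist angles."""
    poly = w.polyline
    if d_theta:
        poly = rotate_about(poly, w.basepoint, up, d_theta)
    if d_phi:
        tangent = poly[1] - poly[0]
        t_h = tangent - (tangent @ up) * up
        if np.linalg.norm(t_h) < 1e-12:
            axis = np.cross(up, tangent)
        else:
            axis = np.cross(up, t_h)
        poly = rotate_about(poly, w.basepoint, axis, d_phi)
    if d_zeta:
        tangent = poly[1] - poly[0]
        poly = rotate_about(poly, w.basepoint, tangent, d_zeta)
    return poly[-1]


def propagate_tip_uncertainty(whisker: Whisker,
                              d_angle: float = 2.0,
                              d_zeta: float = 4.0,
                              basepoint_err: float = 0.5,
                              up: np.ndarray = (0.0, 0.0, 1.0)
                              ) -> TipUncertainty:
    """Uncertainty-sphere radius around a whisker tip.

    Six perturbed variants of the whisker are generated (±``d_angle`` on the
    emergence elevation and azimuth, ±``d_zeta`` on the twist); each source's
    uncertainty is the mean Euclidean tip displacement of its ± pair.  The
    three sources combine in quadrature and the basepoint uncertainty
    (default 0.5 mm) is added to the resulting radius.
    """
    up = np.asarray(up, dtype=float)
    up = up / np.linalg.norm(up)
    tip = whisker.tip
    components: dict[str, float] = {}
    for name, (dp, dt, dz) in {
            "phi": (d_angle, 0.0, 0.0),
            "theta": (0.0, d_angle, 0.0),
            "zeta": (0.0, 0.0, d_zeta)}.items():
        d_plus = np.linalg.norm(_perturb_tip(whisker, dp, dt, dz, up) - tip)
        d_minus = np.linalg.norm(_perturb_tip(whisker, -dp, -dt, -dz, up) - tip)
        components[name] = float((d_plus + d_minus) / 2.0)
    radius = float(np.sqrt(sum(c ** 2 for c in components.values()))
                   + basepoint_err)
    components["basepoint"] = float(basepoint_err)
    return TipUncertainty(whisker=whisker.label, sphere_radius=radius,
                          components=components)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def arc_summary(arrays: WhiskerArray | Iterable[WhiskerArray]) -> pd.DataFrame:
    """Per-arc mean whisker length and mean eye-to-tip distance, with s.e.m.

    Accepts one array or several (e.g. one per animal, or one per whisking
    scenario); means are taken per array and the standard error is computed
    across arrays (0 for a single array).  Empty arcs are omitted with a
    warning.
    """
    if isinstance(arrays, WhiskerArray):
        arrays = [arrays]
    arrays = list(arrays)
    if not arrays:
        raise InvalidParameterError("need at least one whisker array")

    per_array = []
    for i, arr in enumerate(arrays):
        for w in arr.whiskers:
            sph = to_eye_spherical(w.tip, arr)
            per_array.append({"array": i, "arc": w.arc,
                              "length": w.length, "r_tip": sph.r})
    df = pd.DataFrame(per_array)
    rows = []
    for arc in ARCS:
        sub = df[df["arc"] == arc]
        if sub.empty:
            warnings.warn(f"arc {arc!r} has no whiskers; omitted")
            continue
        means = sub.groupby("array")[["length", "r_tip"]].mean()
        n = len(means)
        sem = means.std(ddof=1) / np.sqrt(n) if n > 1 else means.iloc[0] * 0.0
        rows.append({"arc": arc, "n_arrays": n,
                     "mean_length": float(means["length"].mean()),
                     "sem_length": float(sem["length"]),
                     "mean_r_tip": float(means["r_tip"].mean()),
                     "sem_r_tip": float(sem["r_tip"])})
    return pd.DataFrame(rows)
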