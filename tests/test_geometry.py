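"""Whisker-geometry unit, oracle and property tests.

Rotation results are checked against independent oracles (explicit
rotation matrices, Rodrigues axis-angle formulas, chord-length formulas,
Monte-Carlo sampling) rather than against the implementation itself.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from whiskvis.exceptions import DegenerateGeometryError, InvalidParameterError
from whiskvis.geometry import (
    ROLL_ANGLES, VisualSpaceMap, Whisker, WhiskerArray, apply_roll,
    arc_summary, fit_whisking_plane, fit_whisking_planes, incline_planes,
    propagate_tip_uncertainty, rotate_about, rotate_in_plane, tips_in_space,
    to_eye_spherical, whisk_scenario,
)
from whiskvis.synth import gen_whisker_array


def straight_whisker(row, arc, basepoint, direction, length, n=10):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0, 1, n)[:, None]
    poly = np.asarray(basepoint, float) + s * length * direction
    return Whisker(row=row, arc=arc, basepoint=basepoint, phi_w=0.0,
                   theta_w=0.0, zeta_w=0.0, length=length, polyline=poly)


def tip_array(tips_angular, eye=(0.0, 0.0, 0.0), r=10.0):
    """24 straight whiskers whose tips sit at prescribed (az, el) degrees."""
    whiskers = []
    rows = ["A", "B", "C", "D", "E"]
    k = 0
    for row in rows:
        for arc in ["1", "2", "3", "4"]:
            az, el = np.deg2rad(tips_angular[k])
            d = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az),
                          np.sin(el)])
            base = np.asarray(eye) + 0.4 * r * d
            whiskers.append(straight_whisker(row, arc, base, d, 0.6 * r))
            k += 1
    for row in ["A", "B", "C", "D"]:
        az, el = np.deg2rad(tips_angular[k])
        d = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az),
                      np.sin(el)])
        base = np.asarray(eye) + 0.4 * r * d
        whiskers.append(straight_whisker(row, "greek", base, d, 0.6 * r))
        k += 1
    return WhiskerArray(whiskers=whiskers, eye=np.asarray(eye, float))


class TestEyeSpherical:
    def test_noseward_horizontal_point(self, whisker_array):
        array, _ = whisker_array
        p = array.eye + 7.0 * array.head_frame[0]
        sph = to_eye_spherical(p, array)
        assert sph.r == pytest.approx(7.0)
        assert sph.azimuth == pytest.approx(0.0, abs=1e-12)
        assert sph.elevation == pytest.approx(0.0, abs=1e-12)

    def test_pole_reported_with_flag(self, whisker_array):
        array, _ = whisker_array
        p = array.eye + 3.0 * array.head_frame[2]
        sph = to_eye_spherical(p, array)
        assert sph.elevation == pytest.approx(90.0)
        assert sph.azimuth == 0.0 and sph.at_pole

    def test_point_at_eye_rejected(self, whisker_array):
        array, _ = whisker_array
        with pytest.raises(DegenerateGeometryError):
            to_eye_spherical(array.eye, array)

    def test_arbitrary_point_against_rotation_oracle(self, rng):
        frame = Rotation.random(random_state=7).as_matrix()
        eye = rng.normal(size=3)
        w = straight_whisker("C", "2", eye + np.array([5, 0, 0]),
                             [1, 1, 0], 4.0)
        # need a full array for the signature; reuse one whisker 24 times
        arr, _ = gen_whisker_array(seed=3)
        arr = WhiskerArray(whiskers=arr.whiskers, eye=eye, head_frame=frame)
        for _ in range(50):
            p = eye + rng.normal(scale=10.0, size=3)
            sph = to_eye_spherical(p, arr)
            v = frame @ (p - eye)  # oracle: explicit frame change
            r = np.linalg.norm(v)
            assert sph.r == pytest.approx(r)
            assert sph.elevation == pytest.approx(
                np.degrees(np.arctan2(v[2], np.hypot(v[0], v[1]))), abs=1e-9)
            if not sph.at_pole:
                assert sph.azimuth == pytest.approx(
                    np.degrees(np.arctan2(v[1], v[0])), abs=1e-9)


class TestWhiskingPlane:
    def test_coplanar_points_fit_exactly(self):
        # whiskers constructed in the y = const plane
        ws = [straight_whisker("B", str(i + 1), np.array([i, 2.0, 0.0]),
                               [-1, 0, 0.3 * i + 0.1], 5.0)
              for i in range(4)]
        plane = fit_whisking_plane(ws)
        pts = np.concatenate([[w.basepoint, w.tip] for w in ws])
        residual = np.abs((pts - pts.mean(0)) @ plane.normal)
        assert residual.max() < 1e-12

    def test_two_whisker_coplanar_row(self):
        ws = [straight_whisker("D", "1", np.array([0.0, 1.0, 0.0]),
                               [-1, 0, 1], 4.0),
              straight_whisker("D", "2", np.array([2.0, 1.0, 0.0]),
                               [-1, 0, 2], 4.0)]
        plane = fit_whisking_plane(ws)
        pts = np.concatenate([[w.basepoint, w.tip] for w in ws])
        residual = np.abs((pts - pts.mean(0)) @ plane.normal)
        assert residual.max() < 1e-12

    def test_jittered_plane_recovered_within_two_degrees(self, rng):
        true_normal = np.array([0.0, 1.0, 0.0])
        ws = []
        for i in range(4):
            base = np.array([2.0 * i, 3.0, 0.0])
            d = np.array([-1.0, 0.0, 0.4 + 0.2 * i])
            tip = base + 15.0 * d / np.linalg.norm(d)
            tip = tip + rng.normal(0, 0.05, 3)
            base = base + rng.normal(0, 0.05, 3)
            poly = np.linspace(base, tip, 8)
            L = float(np.sum(np.linalg.norm(np.diff(poly, 0o1, 0), axis=1)))
            ws.append(Whisker(row="C", arc=str(i + 1), basepoint=base,
                              phi_w=0, theta_w=0, zeta_w=0, length=L,
                              polyline=poly))
        plane = fit_whisking_plane(ws)
        cosang = abs(plane.normal @ true_normal)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0

    def test_collinear_points_rejected(self):
        ws = [straight_whisker("A", "1", np.array([0.0, 0, 0]), [1, 0, 0], 2.0),
              straight_whisker("A", "2", np.array([3.0, 0, 0]), [1, 0, 0], 2.0)]
        with pytest.raises(DegenerateGeometryError):
            fit_whisking_plane(ws)


class TestRigidTransforms:
    def test_zero_angle_is_identity(self, whisker_array):
        array, _ = whisker_array
        out = whisk_scenario(array, 0.0)
        for a, b in zip(array.whiskers, out.whiskers):
            assert np.array_equal(a.polyline, b.polyline)

    def test_protraction_then_retraction_inverts(self, whisker_array):
        array, _ = whisker_array
        planes = fit_whisking_planes(array)
        back = rotate_in_plane(rotate_in_plane(array, 40.0, planes),
                               -40.0, planes)
        for a, b in zip(array.whiskers, back.whiskers):
            assert np.allclose(a.polyline, b.polyline, atol=1e-9)

    @pytest.mark.parametrize("transform", [
        lambda arr: rotate_in_plane(arr, 25.0),
        lambda arr: apply_roll(arr, 1.0),
        lambda arr: whisk_scenario(arr, 40.0, inclination_deg=20.0,
                                   roll_scale=2.0),
    ])
    def test_transforms_are_isometries(self, whisker_array, transform):
        array, _ = whisker_array
        out = transform(array)
        for a, b in zip(array.whiskers, out.whiskers):
            da = np.linalg.norm(a.polyline[:, None] - a.polyline[None], axis=2)
            db = np.linalg.norm(b.polyline[:, None] - b.polyline[None], axis=2)
            assert np.max(np.abs(da - db)) < 1e-9
            assert np.allclose(a.basepoint, b.basepoint, atol=1e-9)

    def test_protraction_moves_tips_noseward(self, whisker_array):
        array, _ = whisker_array
        pro = rotate_in_plane(array, 40.0)
        fwd = array.head_frame[0]
        gain = [((p.tip - p.basepoint) - (a.tip - a.basepoint)) @ fwd
                for a, p in zip(array.whiskers, pro.whiskers)]
        assert np.mean(np.array(gain) > 0) > 0.9

    def test_incline_planes_composes_to_identity(self, whisker_array):
        array, _ = whisker_array
        planes = fit_whisking_planes(array)
        again = incline_planes(incline_planes(planes, 20.0), -20.0)
        for row in planes:
            assert np.allclose(planes[row].normal, again[row].normal,
                               atol=1e-12)

    def test_incline_matches_rodrigues_oracle(self, whisker_array):
        array, _ = whisker_array
        planes = fit_whisking_planes(array)
        out = incline_planes(planes, 20.0)
        for row, plane in planes.items():
            k = plane.in_plane_mean
            n = plane.normal
            th = np.deg2rad(20.0)
            oracle = (n * np.cos(th) + np.cross(k, n) * np.sin(th)
                      + k * (k @ n) * (1 - np.cos(th)))
            assert np.allclose(out[row].normal, oracle, atol=1e-12)

    def test_roll_full_turn_is_identity(self, whisker_array):
        array, _ = whisker_array
        out = array
        scale = 360.0 / ROLL_ANGLES["C"]
        rolled = apply_roll(out, scale)
        a, b = out["C2"], rolled["C2"]
        assert np.allclose(a.polyline, b.polyline, atol=1e-9)

    def test_roll_leaves_tip_fixed(self, whisker_array):
        array, _ = whisker_array
        rolled = apply_roll(array, 2.0)
        for a, b in zip(array.whiskers, rolled.whiskers):
            assert np.allclose(a.tip, b.tip, atol=1e-9)

    def test_a_row_roll_angle_matches_convention(self, whisker_array):
        """At scale 1 the A-row rotates by -36.8 deg about its chord."""
        array, _ = whisker_array
        rolled = apply_roll(array, 1.0)
        w0, w1 = array["A2"], rolled["A2"]
        axis = w0.chord / np.linalg.norm(w0.chord)
        # recover the rotation angle from a mid-shaft point off the axis
        p0 = w0.polyline[25] - w0.basepoint
        p1 = w1.polyline[25] - w1.basepoint
        u0 = p0 - (p0 @ axis) * axis
        u1 = p1 - (p1 @ axis) * axis
        cosang = (u0 @ u1) / (np.linalg.norm(u0) * np.linalg.norm(u1))
        sinang = np.cross(u0, u1) @ axis / (np.linalg.norm(u0)
                                            * np.linalg.norm(u1))
        angle = np.degrees(np.arctan2(sinang, cosang))
        assert angle == pytest.approx(-36.8, abs=1e-6)


class TestTipsInSpace:
    def test_full_domain_polygon_contains_everything(self, rng):
        angular = rng.uniform([-25, -55], [115, 85], size=(24, 2))
        arr = tip_array(angular)
        vmap = VisualSpaceMap(vertices=np.array(
            [[-30, -60], [120, -60], [120, 90], [-30, 90]]))
        assert tips_in_space(arr, vmap).fraction == 1.0

    def test_empty_polygon_contains_nothing(self, whisker_array):
        array, _ = whisker_array
        vmap = VisualSpaceMap(vertices=np.empty((0, 2)))
        assert tips_in_space(array, vmap).fraction == 0.0

    def test_constructed_fraction_matches_ray_casting_oracle(self, rng):
        angular = rng.uniform([-20, -50], [110, 80], size=(24, 2))
        angular[:3] = [[10.5, 10.5], [10.2, 10.8], [10.8, 10.2]]
        angular[3:] += np.where(angular[3:] < [11, 11], 30, 0)  # keep out
        arr = tip_array(angular)
        square = np.array([[10, 10], [11, 10], [11, 11], [10, 11]])
        res = tips_in_space(arr, VisualSpaceMap(vertices=square))
        assert res.fraction == pytest.approx(3 / 24)

        # independent ray-casting oracle on the angular tip coordinates
        def ray_cast(pt, poly):
            x, y = pt
            inside = False
            for i in range(len(poly)):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % len(poly)]
                if (y1 > y) != (y2 > y):
                    xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
                    if x < xin:
                        inside = not inside
            return inside

        coords = res.tip_coords[["azimuth", "elevation"]].to_numpy()
        oracle = np.mean([ray_cast(c, square) for c in coords])
        assert res.fraction == pytest.approx(oracle)

    def test_dilation_only_adds_tips(self, whisker_array, visual_space):
        array, _ = whisker_array
        base = tips_in_space(array, visual_space)
        dil = tips_in_space(array, visual_space.dilated(20.0))
        assert dil.fraction >= base.fraction
        for k in base.inside:
            assert dil.inside[k] >= base.inside[k]

    def test_protraction_beats_retraction(self, whisker_array, visual_space):
        array, _ = whisker_array
        pro = tips_in_space(whisk_scenario(array, 40.0), visual_space)
        ret = tips_in_space(whisk_scenario(array, -40.0), visual_space)
        assert pro.fraction >= ret.fraction


class TestTipUncertainty:
    def test_zero_perturbations_hit_basepoint_floor(self, whisker_array):
        array, _ = whisker_array
        unc = propagate_tip_uncertainty(array["B2"], d_angle=0.0, d_zeta=0.0)
        assert unc.sphere_radius == pytest.approx(0.5)

    def test_straight_whisker_chord_formula(self):
        L = 12.0
        w = straight_whisker("C", "3", np.zeros(3), [1, 0, 0], L)
        unc = propagate_tip_uncertainty(w, d_angle=2.0, d_zeta=0.0,
                                        basepoint_err=0.0)
        expected = 2 * L * np.sin(np.deg2rad(1.0))  # chord of a 2 deg swing
        assert unc.components["theta"] == pytest.approx(expected, rel=1e-9)
        assert unc.components["phi"] == pytest.approx(expected, rel=1e-9)
        assert unc.components["zeta"] == pytest.approx(0.0, abs=1e-12)

    def test_radius_grows_with_length(self):
        radii = []
        for L in (5.0, 10.0, 20.0, 30.0):
            w = straight_whisker("C", "3", np.zeros(3), [1, 0.3, -0.2], L)
            radii.append(propagate_tip_uncertainty(w).sphere_radius)
        assert np.all(np.diff(radii) > 0)

    def test_matches_monte_carlo_oracle(self, whisker_array):
        """Quadrature-combined radius within 25% of a sampled oracle.

        Oracle: 1e4 uniform draws in the angular boxes (phi, theta within
        +-2 deg, zeta within +-4 deg); the oracle sphere radius is the
        maximal tip displacement over draws plus the 0.5 mm basepoint term.
        """
        from whiskvis.geometry import _perturb_tip
        array, _ = whisker_array
        rng = np.random.default_rng(99)
        for label in ("A1", "C2", "E4", "alpha"):
            w = array[label]
            draws = rng.uniform([-2, -2, -4], [2, 2, 4], size=(10_000, 3))
            up = np.array([0.0, 0.0, 1.0])
            disp = np.array([
                np.linalg.norm(_perturb_tip(w, dp, dt, dz, up) - w.tip)
                for dp, dt, dz in draws])
            oracle = disp.max() + 0.5
            radius = propagate_tip_uncertainty(w).sphere_radius
            assert abs(radius - oracle) / oracle < 0.25


class TestArcSummary:
    def test_single_array_has_zero_sem(self, whisker_array):
        array, _ = whisker_array
        df = arc_summary(array)
        assert np.allclose(df["sem_length"], 0.0)
        assert np.allclose(df["sem_r_tip"], 0.0)

    def test_duplicated_arrays_have_zero_sem(self, whisker_array):
        array, _ = whisker_array
        df = arc_summary([array, array, array])
        assert np.allclose(df["sem_length"], 0.0, atol=1e-12)
        assert (df["n_arrays"] == 3).all()

    def test_caudal_arcs_are_longest(self, whisker_array):
        array, _ = whisker_array
        df = arc_summary(array).set_index("arc")
        lengths = df.loc[["greek", "1", "2", "3", "4"], "mean_length"]
        assert np.all(np.diff(lengths.to_numpy()) < 0)


class TestValidation:
    def test_array_requires_24_whiskers(self, whisker_array):
        array, _ = whisker_array
        with pytest.raises(InvalidParameterError):
            WhiskerArray(whiskers=array.whiskers[:23], eye=array.eye)

    def test_polyline_must_start_at_basepoint(self):
        with pytest.raises(InvalidParameterError):
            Whisker(row="A", arc="1", basepoint=np.zeros(3), phi_w=0,
                    theta_w=0, zeta_w=0, length=1.0,
                    polyline=np.array([[1.0, 0, 0], [2.0, 0, 0]]))

    def test_length_mismatch_rejected(self):
        poly = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(InvalidParameterError):
            Whisker(row="A", arc="1", basepoint=np.zeros(3), phi_w=0,
                    theta_w=0, zeta_w=0, length=2.0, polyline=poly)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(InvalidParameterError):
            VisualSpaceMap(vertices=np.array(
                [[0, 0], [10, 10], [10, 0], [0, 10]]))
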