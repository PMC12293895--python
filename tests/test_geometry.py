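"""Centerline angles, the cylindrical rotation model, and the sacral screen."""

import dataclasses
import math

import numpy as np
import pytest

from spinemark import (
    CaseLandmarks,
    Line2D,
    Point2D,
    angles_to_frame,
    compute_case_angles,
    centerline_ap,
    centerline_lateral,
    flexion_extension_angle,
    lateral_bending_angle,
    rotation_angle,
    s1_rotation_screen,
    sacral_rotation_r,
    signed_angle_between,
)
from spinemark.geometry import GeometryError
from spinemark.landmarks import (
    APSacrumMarkers,
    APVertebraMarkers,
    LatVertebraMarkers,
)
from spinemark.simulate import SpineGenParams, generate_case


def _lat_rect(level="L1"):
    return LatVertebraMarkers(level, Point2D(0, 0), Point2D(4, 0),
                              Point2D(0, 10), Point2D(4, 10))


def _rotate(pt: Point2D, deg: float, about=(2.0, 5.0)) -> Point2D:
    r = math.radians(deg)
    dx, dy = pt.x - about[0], pt.y - about[1]
    return Point2D(about[0] + dx * math.cos(r) - dy * math.sin(r),
                   about[1] + dx * math.sin(r) + dy * math.cos(r))


class TestCenterlines:
    def test_axis_aligned_rectangle_gives_vertical_centerline(self):
        cl = centerline_lateral(_lat_rect())
        assert (cl.p, cl.q) == (Point2D(2, 0), Point2D(2, 10))

    def test_rotated_rectangle_rotates_centerline(self):
        v = _lat_rect()
        rot = LatVertebraMarkers("L1", *(_rotate(getattr(v, n), 10)
                                         for n in ("g1", "g2", "h1", "h2")))
        cl0, cl1 = centerline_lateral(v), centerline_lateral(rot)
        assert abs(signed_angle_between(cl1, cl0)) == pytest.approx(10.0, abs=1e-12)
        # and the rotation is undone by rotating back
        back = LatVertebraMarkers("L1", *(_rotate(getattr(rot, n), -10)
                                          for n in ("g1", "g2", "h1", "h2")))
        assert signed_angle_between(centerline_lateral(back), cl0) == pytest.approx(
            0.0, abs=1e-9)

    def test_trapezoid_uses_endplate_midpoints(self):
        """A wedged vertebra's centerline joins the midpoints, not edge bisectors."""
        v = LatVertebraMarkers("L1", Point2D(0, 0), Point2D(6, 0),
                               Point2D(1, 10), Point2D(3, 10))
        cl = centerline_lateral(v)
        assert (cl.p, cl.q) == (Point2D(3, 0), Point2D(2, 10))

    def test_ap_centerline_same_construction(self):
        v = APVertebraMarkers("L1", Point2D(4, 0), Point2D(0, 0),
                              Point2D(4, 10), Point2D(0, 10),
                              Point2D(2.5, 5), Point2D(1.5, 5))
        cl = centerline_ap(v)
        assert (cl.p, cl.q) == (Point2D(2, 0), Point2D(2, 10))

    def test_degenerate_midpoints_raise(self):
        v = LatVertebraMarkers("L1", Point2D(0, 0), Point2D(4, 0),
                               Point2D(4, 0), Point2D(0, 0))
        with pytest.raises(GeometryError):
            centerline_lateral(v)


class TestSignedAngle:
    def test_identical_lines_zero(self):
        l = Line2D(Point2D(0, 0), Point2D(0, 10))
        assert signed_angle_between(l, l) == 0.0

    def test_clockwise_tilt_is_positive(self):
        """Upper line tilted 10 deg toward +x at its top reads +10."""
        lower = Line2D(Point2D(0, 0), Point2D(0, 10))
        s = math.sin(math.radians(10)) * 10
        c = math.cos(math.radians(10)) * 10
        upper = Line2D(Point2D(s, 0), Point2D(0, c))
        assert signed_angle_between(upper, lower) == pytest.approx(10.0, abs=1e-12)
        assert signed_angle_between(lower, upper) == pytest.approx(-10.0, abs=1e-12)

    def test_rigid_rotation_invariance(self, rng):
        for _ in range(50):
            pts = rng.uniform(-50, 50, size=(4, 2))
            l1 = Line2D(Point2D(*pts[0]), Point2D(*pts[1]))
            l2 = Line2D(Point2D(*pts[2]), Point2D(*pts[3]))
            base = signed_angle_between(l1, l2)
            theta = rng.uniform(-40, 40)
            r1 = Line2D(_rotate(l1.p, theta), _rotate(l1.q, theta))
            r2 = Line2D(_rotate(l2.p, theta), _rotate(l2.q, theta))
            assert signed_angle_between(r1, r2) == pytest.approx(base, abs=1e-9)


class TestSegmentalAngles:
    def test_parallel_stack_reads_zero(self):
        params = SpineGenParams(n_cases=1, jitter_sd=0.0, sagittal_sd=0.0,
                                sagittal_mean=(0,) * 5, coronal_sd=0.0,
                                axial_sd=0.0, alpha_sd=0.0, s1_tilt_sd=0.0,
                                ap_s1_tilt_sd=0.0, sacral_sigma=0.0, seed=0)
        case, _ = generate_case(params, 0)
        for lvl in ("L1", "L2", "L3", "L4", "L5"):
            assert flexion_extension_angle(case, lvl) == pytest.approx(0, abs=1e-9)
            mag, _side = lateral_bending_angle(case, lvl)
            assert mag == pytest.approx(0, abs=1e-9)
            assert rotation_angle(case.ap_vertebrae[lvl]).beta_deg == pytest.approx(
                0, abs=1e-9)

    def test_forced_segmental_angle_recovers_exactly(self):
        params = SpineGenParams(n_cases=1, jitter_sd=0.0, sagittal_sd=0.0,
                                sagittal_mean=(0, 0, 7, 0, 0), coronal_sd=0.0,
                                axial_sd=0.0, s1_tilt_sd=0.0, ap_s1_tilt_sd=0.0,
                                sacral_sigma=0.0, seed=1)
        case, _ = generate_case(params, 0)
        assert flexion_extension_angle(case, "L3") == pytest.approx(7.0, abs=1e-9)
        assert flexion_extension_angle(case, "L2") == pytest.approx(0.0, abs=1e-9)

    def test_l5_reference_is_s1_normal(self):
        """L5 centerline perpendicular to the S1 line reads 0 by convention."""
        params = SpineGenParams(n_cases=1, jitter_sd=0.0, sagittal_sd=0.0,
                                sagittal_mean=(0,) * 5, coronal_sd=0.0,
                                axial_sd=0.0, s1_tilt_sd=6.0, ap_s1_tilt_sd=0.0,
                                sacral_sigma=0.0, seed=5)
        case, truth = generate_case(params, 0)
        assert abs(truth[4].sagittal_angle) < 1e-12
        assert flexion_extension_angle(case, "L5") == pytest.approx(0.0, abs=1e-9)

    def test_bending_side_and_mirror_symmetry(self):
        params = SpineGenParams(n_cases=1, jitter_sd=0.0, coronal_sd=4.0,
                                sagittal_sd=0.0, axial_sd=3.0, seed=9)
        case, truth = generate_case(params, 0)
        mirrored = _mirror_ap(case)
        for i, lvl in enumerate(("L1", "L2", "L3", "L4", "L5")):
            mag, side = lateral_bending_angle(case, lvl)
            assert mag == pytest.approx(truth[i].coronal_angle, abs=1e-9)
            assert side == truth[i].coronal_side
            mmag, mside = lateral_bending_angle(mirrored, lvl)
            assert mmag == pytest.approx(mag, abs=1e-9)
            assert mside == {"left": "right", "right": "left", "none": "none"}[side]
            beta = rotation_angle(case.ap_vertebrae[lvl]).beta_deg
            mbeta = rotation_angle(mirrored.ap_vertebrae[lvl]).beta_deg
            assert mbeta == pytest.approx(-beta, abs=1e-9)


def _mirror_ap(case: CaseLandmarks) -> CaseLandmarks:
    """Mirror AP coordinates left-right and relabel patient sides."""
    def m(p: Point2D) -> Point2D:
        return Point2D(-p.x, p.y)

    ap = {}
    for lvl, v in case.ap_vertebrae.items():
        ap[lvl] = APVertebraMarkers(lvl, a1=m(v.a2), a2=m(v.a1), b1=m(v.b2),
                                    b2=m(v.b1), c1=m(v.c2), c2=m(v.c1))
    s = case.ap_sacrum
    sac = APSacrumMarkers(d1=m(s.d2), d2=m(s.d1), e1=m(s.e2), e2=m(s.e1), f=m(s.f))
    return dataclasses.replace(case, ap_vertebrae=ap, ap_sacrum=sac)


class TestRotationModel:
    def _vertebra(self, X, Y, R=1.0):
        # axis-aligned body of width 2R; pedicle points at signed offsets
        return APVertebraMarkers("L2",
                                 a1=Point2D(R, 0), a2=Point2D(-R, 0),
                                 b1=Point2D(R, 2), b2=Point2D(-R, 2),
                                 c1=Point2D(Y, 1), c2=Point2D(-X, 1))

    def test_symmetric_pedicles_mean_no_rotation(self):
        res = rotation_angle(self._vertebra(0.5, 0.5))
        assert res.beta_deg == 0.0

    @pytest.mark.parametrize("t1, t2", [(40.0, 20.0), (60.0, 30.0)])
    def test_arcsin_arithmetic(self, t1, t2):
        X = math.sin(math.radians(t1))
        Y = math.sin(math.radians(t2))
        res = rotation_angle(self._vertebra(X, Y))
        assert res.beta_deg == pytest.approx((t1 - t2) / 2, abs=1e-12)
        assert res.alpha_deg == pytest.approx((t1 + t2) / 2, abs=1e-12)

    def test_offset_beyond_radius_raises(self):
        with pytest.raises(GeometryError, match="pedicle"):
            rotation_angle(self._vertebra(1.2, 0.5))

    def test_slight_overshoot_clamps_to_radius(self):
        res = rotation_angle(self._vertebra(1.01, math.sin(math.radians(30))))
        assert res.beta_deg == pytest.approx((90.0 - 30.0) / 2, abs=1e-12)

    def test_matches_numeric_inversion_of_forward_model(self, rng):
        """The arcsin solution equals a root-finder inversion of the
        cylinder projection on random (alpha, beta, R) triples."""
        from scipy.optimize import fsolve
        for _ in range(200):
            alpha = rng.uniform(15, 60)
            beta = rng.uniform(-12, 12)
            if abs(beta) >= alpha - 1 or alpha + abs(beta) >= 89:
                continue
            R = rng.uniform(20, 60)
            X = R * math.sin(math.radians(alpha + beta))
            Y = R * math.sin(math.radians(alpha - beta))
            res = rotation_angle(self._vertebra(X / R, Y / R, R=1.0))
            def eqs(v):
                a, b = v
                return (math.sin(a + b) - X / R, math.sin(a - b) - Y / R)
            a_hat, b_hat = fsolve(eqs, (math.radians(40), 0.0), xtol=1e-13)
            assert res.beta_deg == pytest.approx(math.degrees(b_hat), abs=1e-6)


class TestSacralScreen:
    def test_centered_projection_gives_zero(self):
        s = APSacrumMarkers(Point2D(0, -5), Point2D(10, -5),
                            Point2D(0, 0), Point2D(10, 0), Point2D(5, 7))
        assert sacral_rotation_r(s) == 0.0

    @pytest.mark.parametrize("h, expected", [
        (Point2D(7, 5), 0.4),   # P2=(7,0): d1=5, d2=3
        (Point2D(2, -4), 0.6),  # P2=(2,0): d2=2
    ])
    def test_hand_geometry(self, h, expected):
        s = APSacrumMarkers(Point2D(0, -5), Point2D(10, -5),
                            Point2D(0, 0), Point2D(10, 0), h)
        assert sacral_rotation_r(s) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_ala_raises(self):
        s = APSacrumMarkers(Point2D(0, -5), Point2D(10, -5),
                            Point2D(3, 0), Point2D(3, 0), Point2D(5, 7))
        with pytest.raises(GeometryError):
            sacral_rotation_r(s)

    def test_boxplot_fence_worked_example(self):
        cutoff, mask = s1_rotation_screen([0.0, 0.02, 0.04, 0.06, 0.20])
        assert cutoff == pytest.approx(0.12, abs=1e-12)
        assert mask.tolist() == [True, True, True, True, False]

    def test_all_equal_values_fail_screen(self):
        cutoff, mask = s1_rotation_screen([0.05] * 6)
        assert cutoff == pytest.approx(0.05)
        assert not mask.any()

    def test_too_few_values_refused(self):
        with pytest.raises(GeometryError):
            s1_rotation_screen([0.1, 0.2, 0.3])


class TestCohortAngles:
    def test_matches_ground_truth_on_zero_jitter_cohort(self, noiseless_cohort):
        comp = angles_to_frame(compute_case_angles(noiseless_cohort.cases))
        truth = angles_to_frame(noiseless_cohort.truth)
        m = comp.merge(truth, on=["case_id", "level"], suffixes=("_c", "_t"))
        assert len(m) == len(truth)
        for col in ("sagittal_angle", "coronal_angle", "s1_r"):
            assert np.nanmax(np.abs(m[f"{col}_c"] - m[f"{col}_t"])) < 1e-9
        assert (m.s1_pass_c == m.s1_pass_t).all()

    def test_l5_axial_present_only_for_screen_passers(self, noiseless_cohort):
        comp = angles_to_frame(compute_case_angles(noiseless_cohort.cases))
        l5 = comp[comp.level == "L5"]
        assert (l5.axial_angle.notna() == l5.s1_pass).all()
        n_fail = int((~l5.s1_pass).sum())
        assert comp.axial_angle.notna().sum() == len(comp) - n_fail
        assert n_fail > 0  # the screen actually excludes someone

    def test_rigid_transform_of_views_changes_no_angle(self, noiseless_cohort, rng):
        """Rotating, translating, and scaling all coordinates of a view
        leaves every angle unchanged to 1e-9 degrees."""
        case = noiseless_cohort.cases[0]
        theta, scale = rng.uniform(-30, 30), rng.uniform(0.5, 2.0)
        shift = rng.uniform(-100, 100, size=2)

        def xform(p: Point2D) -> Point2D:
            r = math.radians(theta)
            x = scale * (p.x * math.cos(r) - p.y * math.sin(r)) + shift[0]
            y = scale * (p.x * math.sin(r) + p.y * math.cos(r)) + shift[1]
            return Point2D(x, y)

        def map_obj(obj):
            kw = {}
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                kw[f.name] = xform(v) if isinstance(v, Point2D) else v
            return type(obj)(**kw)

        moved = CaseLandmarks(
            case.case_id,
            {l: map_obj(v) for l, v in case.ap_vertebrae.items()},
            map_obj(case.ap_sacrum),
            {l: map_obj(v) for l, v in case.lat_vertebrae.items()},
            map_obj(case.lat_sacrum))
        for lvl in ("L1", "L2", "L3", "L4", "L5"):
            assert flexion_extension_angle(moved, lvl) == pytest.approx(
                flexion_extension_angle(case, lvl), abs=1e-9)
            assert lateral_bending_angle(moved, lvl)[0] == pytest.approx(
                lateral_bending_angle(case, lvl)[0], abs=1e-9)
            assert rotation_angle(moved.ap_vertebrae[lvl]).beta_deg == pytest.approx(
                rotation_angle(case.ap_vertebrae[lvl]).beta_deg, abs=1e-9)
        assert sacral_rotation_r(moved.ap_sacrum) == pytest.approx(
            sacral_rotation_r(case.ap_sacrum), abs=1e-12)
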