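"""Closed-form source solutions: values, branches, symmetries, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import stemdiff as sd
from stemdiff.diffusion import QUAD_RTOL_ACCEPT

from conftest import D, DS, Q0, TAU


def plane_integral_radial(f, rmax=np.inf):
    """∫ f(ρ) 2πρ dρ for a radially symmetric density."""
    val, _ = integrate.quad(lambda u: 2 * math.pi * u * f(u), 0, rmax,
                            limit=300)
    return val


# ---------------------------------------------------------------------------
# instantaneous point source
# ---------------------------------------------------------------------------

class TestInstantaneousPoint:
    def test_unit_constants(self):
        # isotropic d=2, D=1, Q0=4π, t−t0=1 at the origin -> exactly 1
        ev = sd.SourceEvent(sd.SourceProfile.point(4 * math.pi,
                                                   instantaneous=True))
        med = sd.DiffusionMedium((1.0, 1.0))
        assert sd.phi_instantaneous_point((0.0, 0.0), 1.0, ev, med) \
            == pytest.approx(1.0, rel=1e-14)

    def test_conservation(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(3.5, instantaneous=True))
        med = sd.DiffusionMedium((0.7, 1.3))
        for t in (0.3, 2.0):
            val, _ = integrate.dblquad(
                lambda y, x: sd.phi_instantaneous_point((x, y), t, ev, med),
                -30, 30, -30, 30, epsrel=1e-9)
            assert val == pytest.approx(3.5, rel=1e-6)

    def test_anisotropy_contours(self):
        # D=diag(0.25, 0.5): (1,0) and (0,√2) sit on the same ellipse
        ev = sd.SourceEvent(sd.SourceProfile.point(1.0, instantaneous=True))
        med = sd.DiffusionMedium((0.25, 0.5))
        for t in (0.1, 1.0, 7.0):
            a = sd.phi_instantaneous_point((1.0, 0.0), t, ev, med)
            b = sd.phi_instantaneous_point((0.0, math.sqrt(2)), t, ev, med)
            assert a == pytest.approx(b, rel=1e-12)

    def test_not_yet_active(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(1.0, instantaneous=True),
                            t0=1.0)
        with pytest.raises(ValueError):
            sd.phi_instantaneous_point((0.0, 0.0), 0.5, ev,
                                       sd.DiffusionMedium((1.0, 1.0)))

    def test_positive_coefficients_required(self):
        with pytest.raises(ValueError):
            sd.DiffusionMedium((1.0, -0.1))


# ---------------------------------------------------------------------------
# continuous point source
# ---------------------------------------------------------------------------

class TestContinuousPoint:
    def test_log_branch_unit_constants(self):
        # D=1, Q0=4π, τ=1, at the source, t−t0=2 -> ln 2
        ev = sd.SourceEvent(sd.SourceProfile.point(4 * math.pi), tau=1.0)
        med = sd.DiffusionMedium((1.0, 1.0))
        val = sd.phi_continuous_point((0.0, 0.0), 2.0, ev, med)
        assert val == pytest.approx(math.log(2.0), rel=1e-14)

    def test_singular_at_source_during_dwell(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(1.0), tau=1.0)
        med = sd.DiffusionMedium((1.0, 1.0))
        assert np.isinf(sd.phi_continuous_point((0.0, 0.0), 0.5, ev, med))

    def test_zero_before_activation(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(1.0), t0=1.0, tau=1.0)
        med = sd.DiffusionMedium((1.0, 1.0))
        assert sd.phi_continuous_point((0.3, 0.0), 0.5, ev, med) == 0.0

    @pytest.mark.parametrize("r", [(0.2, 0.1), (1.0, -0.5)])
    def test_branch_continuity(self, r):
        ev = sd.SourceEvent(sd.SourceProfile.point(2.0), tau=0.8)
        med = sd.DiffusionMedium((0.4, 0.4))
        eps = 1e-10
        lo = sd.phi_continuous_point(r, 0.8 - eps, ev, med)
        hi = sd.phi_continuous_point(r, 0.8 + eps, ev, med)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_isotropic_equals_degenerate_anisotropic(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(3.0), tau=0.5)
        iso = sd.DiffusionMedium(0.25)
        aniso = sd.DiffusionMedium((0.25, 0.25))
        pts = np.array([[0.1, 0.2], [1.0, 0.0], [-0.4, 0.7]])
        # degenerate anisotropic medium is 2-D; the scalar medium is promoted
        med1 = sd.DiffusionMedium((iso.D[0], iso.D[0]))
        for t in (0.3, 1.2):
            np.testing.assert_allclose(
                sd.phi_continuous_point(pts, t, ev, med1),
                sd.phi_continuous_point(pts, t, ev, aniso), rtol=0)

    def test_conservation_on_and_off(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(2.0), tau=0.5)
        med = sd.DiffusionMedium((0.5, 0.5))
        for t in (0.25, 2.0):
            tot = plane_integral_radial(
                lambda u: sd.phi_continuous_point((u, 0.0), t, ev, med))
            assert tot == pytest.approx(sd.total_species(ev, t), rel=1e-4)


# ---------------------------------------------------------------------------
# circular disc source
# ---------------------------------------------------------------------------

class TestCircularDisc:
    EV = sd.SourceEvent(sd.SourceProfile(kind="circular_disc", Q0=2.0,
                                         rs=0.2), tau=1.0)
    MED = sd.DiffusionMedium((0.25, 0.25))

    def test_conservation_at_dwell_end(self):
        tot = plane_integral_radial(
            lambda u: sd.phi_circular_disc((u, 0.0), 1.0, self.EV, self.MED,
                                           rtol=1e-7))
        assert tot == pytest.approx(2.0 * 1.0, rel=1e-4)

    def test_rotational_symmetry(self):
        rho = 0.3
        vals = [sd.phi_circular_disc((rho * math.cos(a), rho * math.sin(a)),
                                     0.7, self.EV, self.MED)
                for a in (0.0, 1.1, 2.5, 4.0)]
        assert np.ptp(vals) / vals[0] < 1e-8

    def test_small_radius_limit_is_point_source(self):
        pt_ev = sd.SourceEvent(sd.SourceProfile.point(2.0), tau=1.0)
        target = sd.phi_continuous_point((0.5, 0.0), 0.8, pt_ev, self.MED)
        errs = []
        for rs in (0.1, 0.05, 0.025):
            ev = sd.SourceEvent(sd.SourceProfile(kind="circular_disc",
                                                 Q0=2.0, rs=rs), tau=1.0)
            v = sd.phi_circular_disc((0.5, 0.0), 0.8, ev, self.MED)
            errs.append(abs(v - target) / target)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_anisotropic_rejected(self):
        with pytest.raises(ValueError):
            sd.phi_circular_disc((0.1, 0.0), 0.5, self.EV,
                                 sd.DiffusionMedium((0.2, 0.3)))


# ---------------------------------------------------------------------------
# square disc source
# ---------------------------------------------------------------------------

class TestSquareDisc:
    EV = sd.SourceEvent(sd.SourceProfile(kind="square_disc", Q0=3.0,
                                         half_width=0.25), tau=0.6)
    MED = sd.DiffusionMedium((0.4, 0.4))

    def test_conservation_at_dwell_end(self):
        # Simpson quadrature on a grid wide enough to hold the spread mass;
        # 4-fold reflection symmetry lets one quadrant stand for the plane,
        # and the node spacing puts the square's edge exactly on a node
        L, n = 6.0, 49
        xs = np.linspace(0.0, L, n)
        X, Y = np.meshgrid(xs, xs)
        pts = np.stack([X, Y], axis=-1)
        vals = sd.phi_square_disc(pts, 0.6, self.EV, self.MED, rtol=1e-7)
        tot = 4.0 * integrate.simpson(integrate.simpson(vals, x=xs), x=xs)
        assert tot == pytest.approx(3.0 * 0.6, rel=1e-4)

    def test_reflection_symmetry(self):
        for t in (0.3, 1.0):
            ref = sd.phi_square_disc((0.31, 0.17), t, self.EV, self.MED)
            for p in [(-0.31, 0.17), (0.31, -0.17), (-0.31, -0.17),
                      (0.17, 0.31)]:
                assert sd.phi_square_disc(p, t, self.EV, self.MED) \
                    == pytest.approx(ref, rel=1e-10)

    def test_against_brute_force_superposition(self):
        for r in [(0.1, 0.05), (0.6, -0.3)]:
            closed = sd.phi_square_disc(r, 0.5, self.EV, self.MED)
            oracle = sd.superposition_oracle(r, 0.5, self.EV, self.MED)
            assert closed == pytest.approx(oracle, rel=1e-5)


# ---------------------------------------------------------------------------
# Gaussian probe
# ---------------------------------------------------------------------------

class TestGaussianProbe:
    def test_centre_log_value(self):
        # t−t0 = Ds/(2D) makes the log argument exactly 2
        Dv, Dsv = 0.7, 0.1
        ev = sd.SourceEvent(sd.SourceProfile.gaussian(4 * math.pi * Dv, Dsv),
                            tau=1.0)
        med = sd.DiffusionMedium((Dv, Dv))
        val = sd.phi_gaussian((0.0, 0.0), Dsv / (2 * Dv), ev, med)
        assert val == pytest.approx(math.log(2.0), rel=1e-12)

    def test_reference_probe_reaches_1e4(self, gaussian_event, medium):
        val = sd.phi_gaussian((0.0, 0.0), TAU, gaussian_event, medium)
        assert val == pytest.approx(1e4, rel=5e-4)
        assert val == pytest.approx(sd.abdd_max(Q0, D, DS, TAU), rel=1e-12)

    def test_small_width_limit_is_point_source(self):
        med = sd.DiffusionMedium((0.5, 0.5))
        pt = sd.SourceEvent(sd.SourceProfile.point(2.0), tau=0.4)
        target = sd.phi_continuous_point((0.4, 0.3), 0.9, pt, med)
        errs = []
        for Dsv in (1e-2, 1e-3, 1e-4):
            ev = sd.SourceEvent(sd.SourceProfile.gaussian(2.0, Dsv), tau=0.4)
            v = sd.phi_gaussian((0.4, 0.3), 0.9, ev, med)
            errs.append(abs(v - target) / target)
        assert errs[0] > errs[1] > errs[2] and errs[2] < 1e-3

    def test_branch_continuity_including_centre(self, gaussian_event, medium):
        eps = 1e-12
        for r in [(0.0, 0.0), (0.03, -0.02)]:
            lo = sd.phi_gaussian(r, TAU - eps, gaussian_event, medium)
            hi = sd.phi_gaussian(r, TAU + eps, gaussian_event, medium)
            assert lo == pytest.approx(hi, rel=1e-6)

    def test_conservation(self, gaussian_event, medium):
        for t in (TAU / 2, TAU, 3 * TAU):
            tot = plane_integral_radial(
                lambda u: float(sd.phi_gaussian((u, 0.0), t, gaussian_event,
                                                medium)))
            assert tot == pytest.approx(sd.total_species(gaussian_event, t),
                                        rel=1e-4)

    def test_anisotropic_quadrature_matches_isotropic_closed_form(self):
        # same parameters driven through the general integral path
        ev_iso = sd.SourceEvent(sd.SourceProfile.gaussian(5.0, 0.02), tau=0.3)
        ev_aniso = sd.SourceEvent(
            sd.SourceProfile(kind="gaussian", Q0=5.0, Ds=(0.02, 0.02 + 1e-15)),
            tau=0.3)
        med = sd.DiffusionMedium((0.6, 0.6))
        for r, t in [((0.2, 0.1), 0.2), ((0.5, -0.3), 0.8)]:
            a = sd.phi_gaussian(r, t, ev_iso, med)
            b = sd.phi_gaussian(r, t, ev_aniso, med)
            assert a == pytest.approx(b, rel=1e-8)

    def test_genuinely_anisotropic_matches_oracle(self):
        ev = sd.SourceEvent(
            sd.SourceProfile(kind="gaussian", Q0=1.0, Ds=(0.2, 0.05)),
            tau=1.0)
        med = sd.DiffusionMedium((0.25, 0.5))
        for r, t in [((0.3, 0.2), 0.7), ((0.5, -0.4), 1.5)]:
            closed = sd.phi_gaussian(r, t, ev, med)
            oracle = sd.superposition_oracle(r, t, ev, med)
            assert closed == pytest.approx(oracle, rel=1e-6)


# ---------------------------------------------------------------------------
# totals, bound and limits
# ---------------------------------------------------------------------------

class TestTotalsAndLimits:
    def test_total_species_piecewise(self):
        ev = sd.SourceEvent(sd.SourceProfile.point(3.0), t0=1.0, tau=2.0)
        assert sd.total_species(ev, 1.0) == 0.0
        assert sd.total_species(ev, 2.0) == pytest.approx(3.0)
        assert sd.total_species(ev, 10.0) == pytest.approx(6.0)

    def test_abdd_max_degenerate_cases(self):
        assert sd.abdd_max(1.0, 1.0, 1.0, 0.0) == 0.0
        # Q0 = 4πD and 2τ/ρ = 1 -> ln 2
        assert sd.abdd_max(4 * math.pi, 1.0, 2.0, 1.0) \
            == pytest.approx(math.log(2.0), rel=1e-14)

    def test_small_D_limit_matches_small_D_evaluation(self, gaussian_event):
        # D = 1e-6·Ds/τ is deep in the frozen-probe regime
        Dv = 1e-6 * DS / TAU
        med = sd.DiffusionMedium((Dv, Dv))
        xs = np.linspace(-0.3, 0.3, 13)
        pts = np.stack(np.meshgrid(xs, xs), axis=-1)
        for t in (TAU / 2, 5 * TAU):
            lim = sd.limit_distribution_small_D(pts, t, gaussian_event)
            full = sd.phi_gaussian(pts, t, gaussian_event, med)
            keep = lim > lim.max() * 1e-12
            np.testing.assert_allclose(full[keep], lim[keep], rtol=1e-3)

    def test_small_D_off_phase_mass(self, gaussian_event):
        f = lambda u: float(sd.limit_distribution_small_D(
            (u, 0.0), 10 * TAU, gaussian_event))
        assert plane_integral_radial(f) == pytest.approx(Q0 * TAU, rel=1e-6)

    def test_large_D_limit_vanishes(self, gaussian_event):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        assert np.all(sd.limit_distribution_large_D(pts, 1.0, gaussian_event)
                      == 0.0)


# ---------------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(0.1, 50.0), t=st.floats(0.05, 3.0),
       rho=st.floats(0.01, 2.0))
def test_linearity_in_rate(scale, t, rho):
    """Doubling (or scaling) Q0 scales the density exactly."""
    med = sd.DiffusionMedium((0.5, 0.5))
    base = sd.SourceEvent(sd.SourceProfile.gaussian(2.0, 0.05), tau=0.5)
    scaled = sd.SourceEvent(sd.SourceProfile.gaussian(2.0 * scale, 0.05),
                            tau=0.5)
    a = float(sd.phi_gaussian((rho, 0.0), t, base, med))
    b = float(sd.phi_gaussian((rho, 0.0), t, scaled, med))
    assert b == pytest.approx(scale * a, rel=1e-12)


def test_radial_monotonicity_and_centre_time_course(gaussian_event, medium):
    """On-phase: density falls with distance; at the centre it rises during
    the dwell and falls after."""
    rho = np.linspace(0.0, 0.5, 40)
    pts = np.stack([rho, np.zeros_like(rho)], axis=-1)
    on = sd.phi_gaussian(pts, 0.7 * TAU, gaussian_event, medium)
    assert np.all(np.diff(on) <= 0)

    ts_on = np.linspace(0.1 * TAU, TAU, 12)
    centre_on = [float(sd.phi_gaussian((0.0, 0.0), t, gaussian_event, medium))
                 for t in ts_on]
    assert np.all(np.diff(centre_on) > 0)
    ts_off = np.linspace(1.01 * TAU, 5 * TAU, 12)
    centre_off = [float(sd.phi_gaussian((0.0, 0.0), t, gaussian_event, medium))
                  for t in ts_off]
    assert np.all(np.diff(centre_off) < 0)


def test_single_probe_bound_attained_at_dwell_end(gaussian_event, medium):
    """The density never exceeds the centre value, and the centre never
    exceeds the dwell-end maximum, which is attained exactly."""
    bound = sd.abdd_max(Q0, D, DS, TAU)
    rng = np.random.default_rng(7)
    for _ in range(50):
        r = rng.normal(scale=0.2, size=2)
        t = float(rng.uniform(0.0, 4 * TAU))
        v = float(sd.phi_gaussian(r, t, gaussian_event, medium))
        c = float(sd.phi_gaussian((0.0, 0.0), t, gaussian_event, medium))
        assert v <= c * (1 + 1e-12) + 1e-30
        assert c <= bound * (1 + 1e-12)
    assert float(sd.phi_gaussian((0.0, 0.0), TAU, gaussian_event, medium)) \
        == pytest.approx(bound, rel=1e-12)
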