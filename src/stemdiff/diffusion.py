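"""Closed-form diffusion distributions for beam-activated sources.

A focused electron probe dwelling on a thin specimen seeds a population of
diffusing species (radicals, ions, heat — the mediator of radiolysis damage)
whose areal density ``phi(r, t)`` obeys Fick's second law in an infinite,
homogeneous 2-D medium.  This module evaluates ``phi`` for the standard
source shapes:

* instantaneous point source — the anisotropic heat kernel in ``d`` dimensions;
* continuous point source — exponential-integral (E1) closed form;
* continuous circular disc — radial quadrature with the modified Bessel I0;
* continuous square disc — separable error-function form, time quadrature;
* continuous Gaussian probe — E1 closed form (the STEM workhorse: an airy
  disc probe is well approximated by a Gaussian of shape parameter ``Ds``).

Units are fixed internally: species amount ``u``, length nm, time s, so the
2-D densities are in u·nm⁻².  ``Q0`` is the rate at which the beam seeds
species (u·s⁻¹) for continuous sources; for the instantaneous source it is
the total deposited amount (u) — the only dimensionally consistent reading.

All evaluators accept ``r`` as an array of points with trailing axis of
length ``d`` and broadcast over the leading axes.  The singular branch of
the point-source solutions (``r == r0``) is dispatched by exact coordinate
match: probe positions live on grid nodes, so no epsilon comparison is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import integrate
from scipy.special import erf, exp1, i0e

__all__ = [
    "DiffusionMedium",
    "SourceProfile",
    "SourceEvent",
    "ProbeEvent",
    "phi_instantaneous_point",
    "phi_continuous_point",
    "phi_circular_disc",
    "phi_square_disc",
    "phi_gaussian",
    "superposition_oracle",
    "total_species",
    "abdd_max",
    "limit_distribution_small_D",
    "limit_distribution_large_D",
]

SourceKind = Literal[
    "instantaneous_point",
    "continuous_point",
    "circular_disc",
    "square_disc",
    "gaussian",
]

#: default relative tolerance for adaptive quadrature
QUAD_RTOL = 1e-10
#: accepted relative tolerance before a quadrature result is considered converged
QUAD_RTOL_ACCEPT = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionMedium:
    """Homogeneous anisotropic medium: diagonal diffusion tensor diag(D1..Dd).

    Parameters
    ----------
    D : sequence of float
        Per-axis diffusion coefficients in nm²·s⁻¹, all strictly positive.
    """

    D: tuple[float, ...]

    def __init__(self, D: float | Sequence[float]):
        Dt = (float(D),) if np.isscalar(D) else tuple(float(x) for x in D)
        if len(Dt) < 1:
            raise ValueError("medium needs at least one diffusion coefficient")
        if any(x <= 0 for x in Dt):
            raise ValueError(f"diffusion coefficients must be > 0, got {Dt}")
        object.__setattr__(self, "D", Dt)

    @property
    def d(self) -> int:
        """Spatial dimensionality."""
        return len(self.D)

    @property
    def det(self) -> float:
        """Determinant |D| of the diffusion tensor."""
        return float(np.prod(self.D))

    @property
    def isotropic(self) -> bool:
        return len(set(self.D)) == 1

    @property
    def scalar(self) -> float:
        """The single coefficient of an isotropic medium."""
        if not self.isotropic:
            raise ValueError("medium is anisotropic; no scalar coefficient")
        return self.D[0]


@dataclass(frozen=True)
class SourceProfile:
    """Shape and strength of a diffusing-species source.

    ``Q0`` is in u·s⁻¹ (u for ``instantaneous_point``).  The spatial profile
    ``h_s`` always integrates to one over the plane, so the amount of species
    in the system does not depend on the source size (a fixed beam current
    deposits a fixed number of electrons regardless of probe defocus).
    """

    kind: SourceKind
    Q0: float
    rs: Optional[float] = None          # disc radius, nm
    half_width: Optional[float] = None  # square half-width, nm
    Ds: Optional[tuple[float, float]] = None  # Gaussian shape diag, nm²

    def __post_init__(self):
        if self.Q0 < 0:
            raise ValueError("Q0 must be non-negative")
        if self.kind == "circular_disc":
            if self.rs is None or self.rs <= 0:
                raise ValueError("circular_disc requires rs > 0")
        elif self.kind == "square_disc":
            if self.half_width is None or self.half_width <= 0:
                raise ValueError("square_disc requires half_width > 0")
        elif self.kind == "gaussian":
            Ds = self.Ds
            if np.isscalar(Ds):
                Ds = (float(Ds), float(Ds))
                object.__setattr__(self, "Ds", Ds)
            if Ds is None or any(x <= 0 for x in Ds):
                raise ValueError("gaussian requires positive Ds entries")

    @property
    def Ds_scalar(self) -> float:
        if self.Ds is None or self.Ds[0] != self.Ds[1]:
            raise ValueError("profile is not an isotropic Gaussian")
        return self.Ds[0]

    @staticmethod
    def gaussian(Q0: float, Ds: float | Sequence[float]) -> "SourceProfile":
        Dst = (float(Ds), float(Ds)) if np.isscalar(Ds) else tuple(map(float, Ds))
        return SourceProfile(kind="gaussian", Q0=Q0, Ds=Dst)

    @staticmethod
    def point(Q0: float, instantaneous: bool = False) -> "SourceProfile":
        kind = "instantaneous_point" if instantaneous else "continuous_point"
        return SourceProfile(kind=kind, Q0=Q0)


@dataclass(frozen=True)
class SourceEvent:
    """A source activated at ``r0`` from ``t0`` for a duration ``tau``."""

    profile: SourceProfile
    r0: tuple[float, ...] = (0.0, 0.0)
    t0: float = 0.0
    tau: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "r0", tuple(float(x) for x in self.r0))
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class ProbeEvent:
    """One scanned probe position: where and when the beam dwelt.

    ``node`` is the (row, col) index on the scan grid; ``r`` the position in
    nm.  Within a scan plan activation times are non-decreasing and dwells do
    not overlap.
    """

    index: int
    node: tuple[int, int]
    r: tuple[float, float]
    t: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("dwell time must be > 0")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _prep_r(r, r0, d):
    """Return (dr, q_mask) with dr shape (..., d)."""
    r = np.asarray(r, dtype=float)
    if r.shape[-1] != d:
        raise ValueError(f"points must have trailing axis of length {d}")
    return r - np.asarray(r0, dtype=float)


def _quadratic_form(dr: np.ndarray, D: Sequence[float]) -> np.ndarray:
    """(r−r0)ᵀ D⁻¹ (r−r0) for a diagonal tensor."""
    Dinv = 1.0 / np.asarray(D, dtype=float)
    return np.einsum("...l,l->...", dr * dr, Dinv)


def _E1(x):
    """E1 with the convention E1(0) = +inf, E1(inf) = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = exp1(x)
    out = np.where(x == 0.0, np.inf, out)
    out = np.where(np.isinf(x), 0.0, out)
    return out


# ---------------------------------------------------------------------------
# instantaneous point source (the heat kernel)
# ---------------------------------------------------------------------------

def phi_instantaneous_point(r, t: float, event: SourceEvent,
                            medium: DiffusionMedium) -> np.ndarray:
    """Heat-kernel density of an instantaneous point source.

    ``phi = Q0 (4π(t−t0))^{−d/2} |D|^{−1/2} exp(−¼ (t−t0)⁻¹ drᵀD⁻¹dr)``,
    strictly positive for t > t0.  ``Q0`` is the total deposited amount (u).
    """
    dt = t - event.t0
    if dt <= 0:
        raise ValueError("instantaneous source not yet active (t <= t0)")
    d = medium.d
    dr = _prep_r(r, event.r0, d)
    q = _quadratic_form(dr, medium.D)
    norm = event.profile.Q0 / math.sqrt((4.0 * math.pi * dt) ** d * medium.det)
    return norm * np.exp(-0.25 * q / dt)


# ---------------------------------------------------------------------------
# continuous point source
# ---------------------------------------------------------------------------

def phi_continuous_point(r, t: float, event: SourceEvent,
                         medium: DiffusionMedium) -> np.ndarray:
    """Density of a point source on for ``t ∈ [t0, t0+τ]`` (2-D only).

    On-phase: ``Q0/(4π√|D|) · E1(q/(4(t−t0)))`` with ``q = drᵀD⁻¹dr``;
    off-phase the difference of the two E1 terms.  At the activation point
    the on-phase value is +inf and the off-phase value the log form
    ``Q0/(4π√|D|) · ln((t−t0)/(t−t0−τ))``.  Returns 0 for ``t < t0``.
    """
    if medium.d != 2:
        raise ValueError("continuous point source closed form is 2-D only")
    Q0, t0, tau = event.profile.Q0, event.t0, event.tau
    dr = _prep_r(r, event.r0, 2)
    q = _quadratic_form(dr, medium.D)
    pref = Q0 / (4.0 * math.pi * math.sqrt(medium.det))
    dt = t - t0
    out = np.zeros_like(q)
    if dt < 0 or dt == 0:
        # at t == t0 nothing has diffused yet (E1 argument -> inf off-centre)
        if dt == 0:
            out = np.where(q == 0.0, np.inf if tau > 0 else 0.0, 0.0)
        return out
    at0 = q == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        if dt <= tau:  # on-phase
            out = pref * _E1(q / (4.0 * dt))
            out = np.where(at0, np.inf, out)
        else:  # off-phase
            out = pref * (_E1(q / (4.0 * dt)) - _E1(q / (4.0 * (dt - tau))))
            out = np.where(at0, pref * math.log(dt / (dt - tau)), out)
    return out


# ---------------------------------------------------------------------------
# circular disc source
# ---------------------------------------------------------------------------

def phi_circular_disc(r, t: float, event: SourceEvent,
                      medium: DiffusionMedium,
                      rtol: float = 1e-10) -> np.ndarray:
    """Density of a uniformly emitting disc of radius ``rs`` (isotropic 2-D).

    Evaluates the radial double integral (inner over the disc radius with the
    I0 kernel, outer over emission time) by adaptive quadrature.  The Bessel
    factor is computed in exponentially scaled form, ``I0(x) = i0e(x)·eˣ``,
    folded into the Gaussian exponent so large arguments never overflow:
    ``exp(−(ρ²+u²)/(4s))·I0(uρ/(2s)) = exp(−(ρ−u)²/(4s))·i0e(uρ/(2s))``.
    """
    if medium.d != 2:
        raise ValueError("disc source closed form is 2-D only")
    if not medium.isotropic:
        raise ValueError("disc source assumes an isotropic medium")
    D = medium.scalar
    Q0, t0, tau, rs = event.profile.Q0, event.t0, event.tau, event.profile.rs
    dr = _prep_r(r, event.r0, 2)
    rho = np.sqrt(np.sum(dr * dr, axis=-1))

    t_hi = min(t, t0 + tau)
    if t_hi <= t0 or Q0 == 0.0:
        return np.zeros_like(rho)

    def integrand_t(tp, rho_s):
        s = D * (t - tp)
        if s <= 0:  # endpoint tp == t: kernel collapses onto h_s
            if rho_s < rs:
                return 1.0 / (math.pi * rs**2)
            elif rho_s == rs:
                return 0.5 / (math.pi * rs**2)
            return 0.0

        def integrand_u(u):
            return u * math.exp(-((rho_s - u) ** 2) / (4.0 * s)) \
                * i0e(u * rho_s / (2.0 * s))

        inner, _ = integrate.quad(integrand_u, 0.0, rs,
                                  epsabs=0.0, epsrel=rtol, limit=200)
        return inner / (2.0 * math.pi * rs**2 * s)

    # absolute floor well below any resolvable density (the time integrand
    # never exceeds the source density 1/(π rs²)); avoids roundoff churn at
    # far-field points whose value is effectively zero
    floor = 1e-13 * (t_hi - t0) / (math.pi * rs**2)
    flat = np.atleast_1d(rho).ravel()
    vals = np.empty_like(flat)
    for i, rho_s in enumerate(flat):
        v, _ = integrate.quad(integrand_t, t0, t_hi, args=(rho_s,),
                              epsabs=floor, epsrel=rtol, limit=200,
                              points=[t_hi])
        vals[i] = Q0 * v
    return vals.reshape(np.shape(rho)) if np.ndim(rho) else float(vals[0])


# ---------------------------------------------------------------------------
# square disc source
# ---------------------------------------------------------------------------

def phi_square_disc(r, t: float, event: SourceEvent,
                    medium: DiffusionMedium,
                    rtol: float = 1e-10) -> np.ndarray:
    """Density of a uniformly emitting square of half-width ``a`` (isotropic 2-D).

    The spatial convolution of the uniform square with the heat kernel is
    separable into per-axis error-function differences; the remaining time
    integral is evaluated adaptively.
    """
    if medium.d != 2:
        raise ValueError("square source closed form is 2-D only")
    if not medium.isotropic:
        raise ValueError("square source assumes an isotropic medium")
    D = medium.scalar
    Q0, t0, tau = event.profile.Q0, event.t0, event.tau
    a = event.profile.half_width
    dr = _prep_r(r, event.r0, 2)

    t_hi = min(t, t0 + tau)
    if t_hi <= t0 or Q0 == 0.0:
        return np.zeros(dr.shape[:-1])

    def integrand_t(tp, x, y):
        s = D * (t - tp)
        if s <= 0:
            inside = (abs(x) < a) and (abs(y) < a)
            edge_x, edge_y = abs(x) == a, abs(y) == a
            if inside:
                return 1.0 / (2.0 * a) ** 2
            if (edge_x and abs(y) <= a) or (edge_y and abs(x) <= a):
                w = 0.25 if (edge_x and edge_y) else 0.5
                return w / (2.0 * a) ** 2
            return 0.0
        den = 2.0 * math.sqrt(s)
        fx = 0.5 * (erf((x + a) / den) - erf((x - a) / den))
        fy = 0.5 * (erf((y + a) / den) - erf((y - a) / den))
        return fx * fy / (2.0 * a) ** 2

    # time integrand is bounded by the source density 1/(2a)²; the floor
    # suppresses roundoff churn at far-field points of negligible value
    floor = 1e-13 * (t_hi - t0) / (2.0 * a) ** 2
    flat = np.atleast_2d(dr.reshape(-1, 2))
    vals = np.empty(flat.shape[0])
    for i, (x, y) in enumerate(flat):
        v, _ = integrate.quad(integrand_t, t0, t_hi, args=(x, y),
                              epsabs=floor, epsrel=rtol, limit=200,
                              points=[t_hi])
        vals[i] = Q0 * v
    out = vals.reshape(dr.shape[:-1])
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gaussian probe
# ---------------------------------------------------------------------------

def _phi_gaussian_isotropic(q2: np.ndarray, dt: float, tau: float,
                            Q0: float, D: float, Ds: float) -> np.ndarray:
    """Closed form at squared distance ``q2``, elapsed time ``dt = t − t0``."""
    pref = Q0 / (4.0 * math.pi * D)
    at0 = q2 == 0.0
    with np.errstate(invalid="ignore"):
        if dt <= tau:  # on-phase
            out = pref * (_E1(q2 / (2.0 * Ds + 4.0 * D * dt))
                          - _E1(q2 / (2.0 * Ds)))
            centre = pref * math.log((Ds + 2.0 * D * dt) / Ds)
        else:  # off-phase
            out = pref * (_E1(q2 / (2.0 * Ds + 4.0 * D * dt))
                          - _E1(q2 / (2.0 * Ds + 4.0 * D * (dt - tau))))
            centre = pref * math.log((Ds + 2.0 * D * dt)
                                     / (Ds + 2.0 * D * (dt - tau)))
    return np.where(at0, centre, out)


def phi_gaussian(r, t: float, event: SourceEvent,
                 medium: DiffusionMedium,
                 rtol: float = 1e-10) -> np.ndarray:
    """Density of a continuous Gaussian probe of shape matrix diag(Ds).

    For an isotropic probe in an isotropic medium the E1 closed form (with
    log branch at the activation point) is used; any anisotropic combination
    falls back to the effective-covariance time integral
    ``∫ Q0/(2π√|De|)·exp(−½ drᵀDe⁻¹dr) dt′`` with ``De = Ds + 2(t−t′)D``.
    Returns 0 for ``t < t0``.
    """
    Q0, t0, tau = event.profile.Q0, event.t0, event.tau
    Ds = event.profile.Ds
    dr = _prep_r(r, event.r0, 2)
    dt = t - t0
    if dt < 0 or Q0 == 0.0:
        return np.zeros(dr.shape[:-1])

    iso = medium.isotropic and Ds[0] == Ds[1]
    if iso:
        q2 = np.sum(dr * dr, axis=-1)
        return _phi_gaussian_isotropic(q2, dt, tau, Q0, medium.scalar, Ds[0])

    # anisotropic: quadrature of the effective-covariance integrand
    t_hi = min(t, t0 + tau)
    D = np.asarray(medium.D, dtype=float)
    Dsv = np.asarray(Ds, dtype=float)

    def integrand(tp, x, y):
        De = Dsv + 2.0 * (t - tp) * D
        return math.exp(-0.5 * (x * x / De[0] + y * y / De[1])) \
            / (2.0 * math.pi * math.sqrt(De[0] * De[1]))

    flat = np.atleast_2d(dr.reshape(-1, 2))
    vals = np.empty(flat.shape[0])
    for i, (x, y) in enumerate(flat):
        v, _ = integrate.quad(integrand, t0, t_hi, args=(x, y),
                              epsabs=0.0, epsrel=rtol, limit=200)
        vals[i] = Q0 * v
    out = vals.reshape(dr.shape[:-1])
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# superposition oracle: brute-force space-time quadrature
# ---------------------------------------------------------------------------

def superposition_oracle(r, t: float, event: SourceEvent,
                         medium: DiffusionMedium,
                         rtol: float = 1e-9) -> float:
    """Brute-force evaluation of the superposition integral for one point.

    Integrates ``h_s(r′) h_t(t′) Q0`` against the instantaneous heat kernel
    over space and time with adaptive quadrature; the spatial integral is
    taken over the source support (a ±10σ box for the Gaussian).  Used as an
    independent verification oracle for the closed forms — it shares none of
    their E1/erf/I0 reductions.
    """
    prof = event.profile
    Q0, t0, tau = prof.Q0, event.t0, event.tau
    if Q0 == 0.0:
        return 0.0
    r = np.asarray(r, dtype=float)
    if r.shape != (2,) or medium.d != 2:
        raise ValueError("oracle evaluates a single 2-D point")
    x, y = r - np.asarray(event.r0)
    D1, D2 = medium.D
    det = D1 * D2

    def kernel(xp, yp, s):
        # instantaneous unit kernel at lag s, offset (x−xp, y−yp)
        e = ((x - xp) ** 2 / D1 + (y - yp) ** 2 / D2) / (4.0 * s)
        return math.exp(-e) / (4.0 * math.pi * s * math.sqrt(det))

    if prof.kind == "instantaneous_point":
        if t <= t0:
            return 0.0
        return Q0 * kernel(0.0, 0.0, t - t0)

    t_hi = min(t, t0 + tau)
    if t_hi <= t0:
        return 0.0

    if prof.kind == "continuous_point":
        def f_t(tp):
            s = t - tp
            if s <= 0:
                return 0.0
            return kernel(0.0, 0.0, s)
    elif prof.kind == "gaussian":
        Dsv = prof.Ds
        sig = [math.sqrt(v) for v in Dsv]
        box = [10.0 * s for s in sig]

        def hs(xp, yp):
            return math.exp(-0.5 * (xp * xp / Dsv[0] + yp * yp / Dsv[1])) \
                / (2.0 * math.pi * sig[0] * sig[1])

        def f_t(tp):
            s = t - tp
            if s <= 0:
                return hs(x, y)
            v, _ = integrate.dblquad(
                lambda yp, xp: hs(xp, yp) * kernel(xp, yp, s),
                -box[0], box[0], -box[1], box[1],
                epsabs=0.0, epsrel=rtol)
            return v
    elif prof.kind == "circular_disc":
        rs = prof.rs
        area = math.pi * rs**2

        def f_t(tp):
            s = t - tp
            if s <= 0:
                return (1.0 if math.hypot(x, y) < rs else 0.0) / area
            v, _ = integrate.dblquad(
                lambda th, u: u * kernel(u * math.cos(th), u * math.sin(th), s),
                0.0, rs, 0.0, 2.0 * math.pi,
                epsabs=0.0, epsrel=rtol)
            return v / area
    elif prof.kind == "square_disc":
        a = prof.half_width
        area = (2.0 * a) ** 2

        def f_t(tp):
            s = t - tp
            if s <= 0:
                return (1.0 if max(abs(x), abs(y)) < a else 0.0) / area
            v, _ = integrate.dblquad(
                lambda yp, xp: kernel(xp, yp, s),
                -a, a, -a, a, epsabs=0.0, epsrel=rtol)
            return v / area
    else:
        raise ValueError(f"unknown source kind {prof.kind!r}")

    import warnings
    with warnings.catch_warnings():
        # convergence is judged from the returned error estimate instead
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(f_t, t0, t_hi, epsabs=0.0, epsrel=rtol,
                                  limit=300, points=[t_hi])
    if val != 0.0 and err / abs(val) > QUAD_RTOL_ACCEPT:
        warnings.warn(f"oracle quadrature reached rel. error {err/abs(val):.2e}")
    return Q0 * val


# ---------------------------------------------------------------------------
# totals, bounds and asymptotic limits
# ---------------------------------------------------------------------------

def total_species(event: SourceEvent, t: float) -> float:
    """Total amount in the system at time t: ``Q0·min(t−t0, τ)`` (u)."""
    if t < event.t0:
        raise ValueError("t must be >= activation time")
    if event.profile.kind == "instantaneous_point":
        return event.profile.Q0
    return event.profile.Q0 * min(t - event.t0, event.tau)


def abdd_max(Q0: float, D: float, Ds: float, tau: float) -> float:
    """Maximum beam diffusion distribution of a single Gaussian probe.

    ``Q0/(4πD)·ln(1 + 2τ/ρ)`` with ``ρ = Ds/D``: the largest density a probe
    ever produces, attained at its own position at the end of the dwell.
    """
    if tau == 0.0:
        return 0.0
    rho = Ds / D
    return Q0 / (4.0 * math.pi * D) * math.log1p(2.0 * tau / rho)


def limit_distribution_small_D(r, t: float, event: SourceEvent) -> np.ndarray:
    """D→0 limit of the Gaussian-probe density: the frozen probe shape.

    On-phase the amplitude grows linearly in elapsed time, off-phase it is
    pinned at ``Q0 τ/(2π Ds)``; the width stays at the probe width.
    """
    prof = event.profile
    Ds = prof.Ds_scalar
    dr = _prep_r(r, event.r0, 2)
    q2 = np.sum(dr * dr, axis=-1)
    dt = t - event.t0
    if dt < 0:
        return np.zeros_like(q2)
    amp = prof.Q0 * min(dt, event.tau) / (2.0 * math.pi * Ds)
    return amp * np.exp(-q2 / (2.0 * Ds))


def limit_distribution_large_D(r, t: float, event: SourceEvent) -> np.ndarray:
    """D→∞ limit: the species disperse instantly; the density vanishes."""
    dr = _prep_r(r, event.r0, 2)
    return np.zeros(dr.shape[:-1])
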