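"""Diffusion-induced damage (DID) from the time-resolved CDD.

Damage at a point accrues whenever the cumulative diffusion distribution
exceeds a threshold λ.  The irreversible DID profile is the time integral of
``p(r, t)·g(ψ(r, t) − λ)`` over the acquisition, with

* activation ``g``: ``sign`` (damage-event frequency; Λ in seconds) or
  ``relu`` (damage intensity; Λ in u·nm⁻²·s);
* pupil ``p``: ``offline`` — damage counts everywhere (observable only by
  re-scanning) — or ``online`` — damage counts at a point only while some
  *later* probe will still dwell within a radius ``rp`` of it (what the
  detector can witness during the scan).

The integral is discretised on the probe-slot grid: within each slot the CDD
is evaluated at the dwell end and weighted by the slot duration (``nt``
sub-rectangles per slot refine this).  A scan is DID-free — zero damage for
any non-negative activation — iff its GM-CDD is at most λ; and if a *single*
probe's maximum already reaches λ, no subsampling strategy can be DID-free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dfield
from typing import Literal, Optional

import numpy as np

from .accumulation import (FieldMap, SimulationGrid, _Engine, _resolved,
                           gmcdd)
from .diffusion import DiffusionMedium, abdd_max
from .scan import ScanPlan, SubsamplingMask

__all__ = [
    "DamageModel",
    "DamageMap",
    "did_profile",
    "overall_did",
    "is_did_free",
    "single_probe_condition",
]


@dataclass(frozen=True)
class DamageModel:
    """Threshold, activation and pupil defining one DID variant.

    ``rp`` (online pupil radius, nm) defaults to 3 scan steps when left None
    and resolved against a plan.
    """

    threshold: float
    activation: Literal["sign", "relu"] = "sign"
    pupil: Literal["offline", "online"] = "offline"
    rp: Optional[float] = None

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("DID threshold must be >= 0")
        if self.activation not in ("sign", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.pupil not in ("offline", "online"):
            raise ValueError(f"unknown pupil {self.pupil!r}")
        if self.pupil == "online" and self.rp is not None and self.rp <= 0:
            raise ValueError("online pupil radius must be > 0")

    def resolve_rp(self, plan: ScanPlan) -> float:
        return self.rp if self.rp is not None else 3.0 * plan.grid.step

    @property
    def units(self) -> str:
        return "s" if self.activation == "sign" else "u.nm^-2.s"


@dataclass
class DamageMap:
    """Accumulated point-wise DID Λ(r; λ) on the simulation grid."""

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float]
    units: str
    meta: dict = dfield(default_factory=dict)

    def to_field_map(self) -> FieldMap:
        return FieldMap(values=self.values, pixel_size=self.pixel_size,
                        origin=self.origin, units=self.units, meta=self.meta)


def _activation(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sign":
        return (x >= 0.0).astype(float)
    return np.maximum(x, 0.0)


def did_profile(plan: ScanPlan, medium: DiffusionMedium,
                sim_grid: SimulationGrid, model: DamageModel,
                mask: Optional[SubsamplingMask] = None) -> DamageMap:
    """Point-wise DID Λ(r; λ) accumulated over the whole acquisition.

    Rectangle rule on the probe-slot time grid: slot ``j`` spans from its
    activation to the next activation (the last slot ends at its dwell end),
    is subdivided into ``nt`` rectangles, and the CDD is sampled at each
    rectangle's end.  For the online pupil, a pixel contributes during slot
    ``j`` only if some selected probe with index > j dwells within ``rp``.
    """
    rplan = _resolved(plan, mask)
    if not rplan.events:
        raise ValueError("empty scan plan")
    eng = _Engine(rplan, medium, sim_grid)
    events = rplan.events
    n = len(events)

    online = model.pupil == "online"
    if online:
        rp = model.resolve_rp(plan)
        # last_cover[r] = largest slot index i whose probe covers pixel r
        rows = np.arange(eng.nrow)[:, None]
        cols = np.arange(eng.ncol)[None, :]
        last_cover = np.full((eng.nrow, eng.ncol), -1, dtype=np.int64)
        rp_pix2 = (rp / eng.pixel) ** 2
        for i, ev in enumerate(events):
            pr, pc = eng.node_pixel(ev.node)
            covered = (rows - pr) ** 2 + (cols - pc) ** 2 <= rp_pix2
            last_cover[covered] = i
        if not np.all(last_cover >= 0):
            warnings.warn(
                "online pupil never opens at some grid points; the DID-free "
                "equivalence (zero damage iff GM-CDD <= threshold) is not "
                "guaranteed there", stacklevel=2)

    lam = model.threshold
    out = eng.zeros()
    nt = sim_grid.nt
    for j, ev in enumerate(events):
        slot_end = events[j + 1].t if j + 1 < n else ev.t + ev.tau
        width = (slot_end - ev.t) / nt
        if online:
            pupil = (last_cover > j).astype(float)
        for k in range(1, nt + 1):
            ts = ev.t + (slot_end - ev.t) * k / nt
            psi = eng.cdd_at(events, ts)
            g = _activation(psi - lam, model.activation)
            if online:
                g *= pupil
            out += width * g
    dm = DamageMap(values=out, pixel_size=eng.pixel, origin=eng.origin,
                   units=model.units)
    dm.meta.update(activation=model.activation, pupil=model.pupil,
                   threshold=lam,
                   rp=model.resolve_rp(plan) if online else None)
    return dm


def overall_did(damage_map: DamageMap) -> float:
    """Spatial integral of the DID map (grid quadrature, pixel-area weight)."""
    return float(damage_map.values.sum()) * damage_map.pixel_size ** 2


def is_did_free(plan: ScanPlan, medium: DiffusionMedium,
                sim_grid: SimulationGrid, model: DamageModel,
                mask: Optional[SubsamplingMask] = None
                ) -> tuple[bool, float]:
    """Whether the scan produces zero DID, plus the margin λ − GM-CDD.

    By the threshold equivalence this needs only the GM-CDD: the scan is
    DID-free iff GM-CDD ≤ λ (boundary inclusive).  Valid for any
    non-negative activation and a pupil with positive time integral
    everywhere (the offline pupil always satisfies this; ``did_profile``
    warns when the online pupil does not).
    """
    g = gmcdd(plan, medium, sim_grid, mask)
    return g.value <= model.threshold, model.threshold - g.value


def single_probe_condition(Q0: float, D: float, Ds: float, tau_max: float,
                           threshold: float) -> bool:
    """True when damage is unavoidable for *any* subsampling strategy.

    If one probe's maximum beam diffusion distribution already reaches the
    threshold, even a single activated position damages the specimen, so no
    mask is DID-free.
    """
    return abdd_max(Q0, D, Ds, tau_max) >= threshold
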