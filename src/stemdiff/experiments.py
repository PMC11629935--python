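"""Experiment configuration, canned campaigns and result serialisation.

The baseline configuration matches the reference STEM setting used
throughout: a 20×20 raster scan with 0.05 nm step, 10 µs dwell, zero
settling time, a Gaussian probe of width parameter Ds = 0.01 nm² seeding
Q0 = 63.45 Mu·s⁻¹ of diffusing species into a medium with D = 10 nm²·s⁻¹.
That setting gives a single-probe maximum of ≈10⁴ u·nm⁻² and a total
deposit of ≈253.8 Ku.

Configurations round-trip through YAML with explicit unit suffixes in the
field names (``dwell_us``, ``D_nm2_per_s``, ``Q0_Mu_per_s``, ...);
internally everything is canonical u/nm/s.  Every artifact directory gets a
``summary.json`` carrying a provenance header (config hash, package
version, units).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .accumulation import (SimulationGrid, cdd, deposited_totals, gmcdd,
                           pmcdd)
from .damage import DamageModel, did_profile, overall_did
from .dcs import design, efficiency_curve
from .diffusion import DiffusionMedium, SourceProfile, abdd_max
from .scan import (ScanGrid, ScanPlan, build_plan, full_mask,
                   make_linehop_mask, make_uds_mask, schedule)

log = logging.getLogger("stemdiff")

__all__ = [
    "ExperimentConfig",
    "run_baseline",
    "run_sweep",
    "run_compressive",
    "run_dcs",
    "generate_fixture",
    "SWEEP_GRIDS",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one simulated acquisition."""

    # scan geometry
    nx: int = 20
    ny: int = 20
    step_nm: float = 0.05
    trajectory: str = "raster"
    kappa: int = 1
    # timing
    dwell_us: float = 10.0
    settle_us: float = 0.0
    # medium and probe
    D_nm2_per_s: float = 10.0
    Ds_nm2: float = 0.01
    Q0_Mu_per_s: float = 63.45
    # simulation grid
    subpixels_per_step: int = 10
    nt: int = 1
    margin_steps: int = 5
    eps_rel: float = 1e-9
    # bookkeeping
    seed: int = 0

    def __post_init__(self):
        for name in ("step_nm", "dwell_us", "D_nm2_per_s", "Ds_nm2",
                     "Q0_Mu_per_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be > 0")
        if self.settle_us < 0:
            raise ValueError("config field settle_us must be >= 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("config fields nx, ny must be >= 1")

    # -- canonical-unit views -------------------------------------------
    @property
    def dwell_s(self) -> float:
        return self.dwell_us * 1e-6

    @property
    def settle_s(self) -> float:
        return self.settle_us * 1e-6

    @property
    def Q0_u_per_s(self) -> float:
        return self.Q0_Mu_per_s * 1e6

    def medium(self) -> DiffusionMedium:
        return DiffusionMedium((self.D_nm2_per_s, self.D_nm2_per_s))

    def profile(self) -> SourceProfile:
        return SourceProfile.gaussian(self.Q0_u_per_s, self.Ds_nm2)

    def grid(self) -> ScanGrid:
        return ScanGrid(nx=self.nx, ny=self.ny, step=self.step_nm)

    def sim_grid(self) -> SimulationGrid:
        return SimulationGrid(subpixels_per_step=self.subpixels_per_step,
                              nt=self.nt, margin_steps=self.margin_steps,
                              eps_rel=self.eps_rel)

    def plan(self) -> ScanPlan:
        return build_plan(self.grid(), self.profile(), self.dwell_s,
                          settle=self.settle_s, trajectory=self.trajectory,
                          seed=self.seed, kappa=self.kappa)

    def abdd_max(self) -> float:
        return abdd_max(self.Q0_u_per_s, self.D_nm2_per_s, self.Ds_nm2,
                        self.dwell_s)

    # -- serialisation ---------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "ExperimentConfig":
        data = yaml.safe_load(text) or {}
        valid = set(ExperimentConfig.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        try:
            return ExperimentConfig(**data)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid configuration: {exc}") from exc

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "version": __version__,
                "units": {"density": "u.nm^-2", "amount": "u",
                          "length": "nm", "time": "s"}}


def _write_summary(outdir: Path, config: ExperimentConfig, summary: dict):
    payload = {"provenance": config.provenance(),
               "config": asdict(config), **summary}
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))
    (outdir / "config.yaml").write_text(config.to_yaml())


def _write_field(outdir: Path, name: str, fm) -> None:
    fm.to_csv(outdir / f"{name}.csv")
    fm.to_tiff(outdir / f"{name}.tiff")


# ---------------------------------------------------------------------------
# campaigns
# ---------------------------------------------------------------------------

def run_baseline(config: ExperimentConfig,
                 outdir: Optional[Path] = None) -> dict:
    """Full scan: PM-CDD field, GM-CDD, single-probe maximum and totals."""
    plan = config.plan()
    sim = config.sim_grid()
    log.info("baseline: %dx%d probes, %d px/step, nt=%d, eps_rel=%g",
             config.ny, config.nx, sim.subpixels_per_step, sim.nt,
             sim.eps_rel)
    fm = pmcdd(plan, config.medium(), sim)
    qstem, _ = deposited_totals(plan)
    a = config.abdd_max()
    summary = {
        "gmcdd": fm.meta["gmcdd"],
        "gmcdd_argmax_xy": list(fm.meta["argmax_xy"]),
        "gmcdd_time_index": fm.meta["time_index"],
        "abdd_max": a,
        "gmcdd_over_abdd_max": fm.meta["gmcdd"] / a,
        "qstem": qstem,
        "n_probes": plan.n_events,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_field(outdir, "pmcdd", fm)
        _write_summary(outdir, config, summary)
    return summary


#: parameter grids of the canned sweeps (values in config-field units)
SWEEP_GRIDS = {
    "D_nm2_per_s": [0.1, 1.0, 10.0, 100.0],
    "Ds_nm2": [1e-4, 1e-3, 1e-2, 1e-1],
    "step_nm": [5e-4, 5e-3, 5e-2, 5e-1],
    "dwell_us": [0.1, 1.0, 10.0, 100.0],
    "settle_over_dwell": [0.0, 0.1, 1.0, 10.0],
    "trajectory": ["raster", "snake", "random", "alternating"],
    "kappa": [1, 2, 4, 6, 8, 10, 12, 14],
}


def run_sweep(config: ExperimentConfig, parameter: str,
              values: Optional[Sequence] = None,
              outdir: Optional[Path] = None) -> list[dict]:
    """One baseline-style run per parameter value; returns the summaries."""
    if parameter not in SWEEP_GRIDS:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"choose from {sorted(SWEEP_GRIDS)}")
    values = list(SWEEP_GRIDS[parameter]) if values is None else list(values)
    results = []
    for v in values:
        if parameter == "settle_over_dwell":
            cfg = replace(config, settle_us=v * config.dwell_us)
        elif parameter == "kappa":
            cfg = replace(config, trajectory="alternating", kappa=int(v))
        else:
            cfg = replace(config, **{parameter: v})
        sub = None if outdir is None else Path(outdir) / f"{parameter}={v}"
        res = run_baseline(cfg, sub)
        res[parameter] = v
        results.append(res)
    return results


#: Monte-Carlo sampling ratios of the compressive campaign
UDS_RATIOS = [0.05, 0.10, 0.20, 0.30, 0.40, 0.50]
LINEHOP_RATIOS = [0.05, 0.10, 0.20, 0.25, 0.333, 0.50]


def run_compressive(config: ExperimentConfig, strategy: str = "uds",
                    hardware: str = "beam_blanker",
                    ratios: Optional[Sequence[float]] = None,
                    trials: int = 10,
                    gmcdd_full: Optional[float] = None,
                    outdir: Optional[Path] = None) -> list[dict]:
    """Seeded Monte-Carlo GM-CDD statistics per sampling ratio.

    For each ratio, ``trials`` masks are drawn (seeds spawned from
    ``config.seed``), the compressive GM-CDD computed for each, and the mean
    and variance of the ratio to the full scan's GM-CDD reported.
    """
    if strategy not in ("uds", "linehop"):
        raise ValueError("strategy must be 'uds' or 'linehop'")
    plan = config.plan()
    sim = config.sim_grid()
    medium = config.medium()
    if gmcdd_full is None:
        gmcdd_full = gmcdd(plan, medium, sim).value
    if ratios is None:
        ratios = UDS_RATIOS if strategy == "uds" else LINEHOP_RATIOS
    ss = np.random.SeedSequence(config.seed)
    rows = []
    for ratio in ratios:
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(trials)]
        vals = []
        for sd in seeds:
            if strategy == "uds":
                mask = make_uds_mask(plan.grid, ratio, seed=sd,
                                     hardware=hardware)
            else:
                mask = make_linehop_mask(plan.grid, ratio, seed=sd,
                                         hardware=hardware)
            vals.append(gmcdd(plan, medium, sim, mask).value)
        vals = np.array(vals)
        rows.append({
            "strategy": strategy, "hardware": hardware, "ratio": ratio,
            "trials": trials,
            "gmcdd_mean": float(vals.mean()),
            "gmcdd_var": float(vals.var()),
            "gmcdd_norm_mean": float((vals / gmcdd_full).mean()),
            "gmcdd_norm_var": float((vals / gmcdd_full).var()),
            "gmcdd_full": float(gmcdd_full),
        })
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd
        pd.DataFrame(rows).to_csv(outdir / "compressive.csv", index=False)
        _write_summary(outdir, config, {"rows": rows})
    return rows


def run_dcs(config: ExperimentConfig, lambda_over_ref: Sequence[float],
            hardware: str = "beam_blanker",
            outdir: Optional[Path] = None):
    """DCS efficiency curve over thresholds expressed as multiples of the
    single-probe maximum (the reference threshold)."""
    plan = config.plan()
    sim = config.sim_grid()
    medium = config.medium()
    lam_ref = config.abdd_max()
    gm_full = gmcdd(plan, medium, sim).value
    table = efficiency_curve(plan, [x * lam_ref for x in lambda_over_ref],
                             hardware, medium, sim,
                             gmcdd_full=gm_full, lambda_ref=lam_ref)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"dcs_{hardware}.csv", index=False)
        _write_summary(outdir, config, {"gmcdd_full": gm_full,
                                        "lambda_ref": lam_ref})
    return table


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    # sub-second scenes for tests and quick sanity runs
    "single_probe": dict(nx=1, ny=1, subpixels_per_step=10, margin_steps=3),
    "two_probe": dict(nx=2, ny=1, subpixels_per_step=5, margin_steps=2),
    "tiny_3x3": dict(nx=3, ny=3, subpixels_per_step=4, margin_steps=2),
    "baseline_mini": dict(nx=10, ny=10),
}


def generate_fixture(name: str) -> ExperimentConfig:
    """A fully specified small deterministic scene (baseline parameters
    otherwise)."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choose from {sorted(_FIXTURES)}")
    return ExperimentConfig(seed=12345, **_FIXTURES[name])
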