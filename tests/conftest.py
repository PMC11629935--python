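"""Shared fixtures: reference parameters and small deterministic scenes."""

import numpy as np
import pytest

import stemdiff as sd

# reference acquisition parameters (20x20 raster, 10 us dwell, 0.05 nm step,
# D = 10 nm^2/s, Ds = 0.01 nm^2, Q0 = 63.45e6 u/s)
Q0 = 63.45e6
D = 10.0
DS = 0.01
TAU = 10e-6
STEP = 0.05


@pytest.fixture(scope="session")
def medium():
    return sd.DiffusionMedium((D, D))


@pytest.fixture(scope="session")
def gaussian_event():
    """Single reference probe dwelling at the origin."""
    return sd.SourceEvent(sd.SourceProfile.gaussian(Q0, DS),
                          (0.0, 0.0), 0.0, TAU)


@pytest.fixture(scope="session")
def tiny_config():
    return sd.generate_fixture("tiny_3x3")


@pytest.fixture(scope="session")
def mini_config():
    return sd.generate_fixture("baseline_mini")


@pytest.fixture(scope="session")
def baseline_summary():
    """Full 20x20 reference scan, computed once per session.

    Used by the acceptance checks on the global maximum and its ratio to the
    single-probe maximum, and as the full-scan normaliser elsewhere.
    """
    return sd.run_baseline(sd.ExperimentConfig())


def random_tiny_plan(rng, nx=None, ny=None):
    """A randomized small scan for brute-force cross-checks."""
    nx = int(rng.integers(2, 4)) if nx is None else nx
    ny = int(rng.integers(2, 4)) if ny is None else ny
    grid = sd.ScanGrid(nx=nx, ny=ny, step=float(rng.uniform(0.03, 0.1)))
    profile = sd.SourceProfile.gaussian(float(rng.uniform(1e6, 1e8)),
                                        float(rng.uniform(0.005, 0.05)))
    traj = rng.choice(["raster", "snake", "random"])
    return sd.build_plan(grid, profile, dwell=float(rng.uniform(5e-6, 5e-5)),
                         settle=float(rng.choice([0.0, 1e-5])),
                         trajectory=str(traj), seed=int(rng.integers(1 << 16)))
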