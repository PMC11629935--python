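"""Scan trajectories, acquisition timing and subsampling masks.

A STEM acquisition visits an ``ny × nx`` array of probe positions spaced by
the scan step ``Δp``.  The trajectory fixes the visiting order (raster,
snake, seeded random, or an alternating scan of order κ that interleaves κ²
raster passes over a κ-decimated lattice); the timing model assigns each
visited position an activation time ``t_i`` with constant dwell ``τ`` and
inter-position settling/blanking time ``τ̄``, so ``t_{i+1} = t_i + τ + τ̄``.

Subsampling selects M of the N positions.  Two hardware models realise a
mask: a *beam blanker* keeps the full raster timeline and simply blanks the
unselected slots (time passes, nothing is deposited), while a *scan
generator* visits only the selected positions back-to-back, so the
acquisition shortens from ``N(τ+τ̄)`` to ``M(τ+τ̄)``.

Grid convention: probe (row r, col c) sits at ``origin + (c·Δp, −r·Δp)`` —
row index grows downward, matching image orientation.  Indices are 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .diffusion import ProbeEvent, SourceProfile

__all__ = [
    "ScanGrid",
    "ScanPlan",
    "SubsamplingMask",
    "make_trajectory",
    "make_uds_mask",
    "make_linehop_mask",
    "full_mask",
    "schedule",
]

Trajectory = Literal["raster", "snake", "alternating", "random", "custom"]
Hardware = Literal["beam_blanker", "scan_generator"]


@dataclass(frozen=True)
class ScanGrid:
    """Rectangular array of probe positions: ``ny`` rows × ``nx`` columns."""

    nx: int
    ny: int
    step: float          # Δp, nm
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid needs nx, ny >= 1")
        if self.step <= 0:
            raise ValueError("scan step must be > 0")

    @property
    def n(self) -> int:
        return self.nx * self.ny

    def position(self, node: tuple[int, int]) -> tuple[float, float]:
        """nm position of probe (row, col)."""
        r, c = node
        return (self.origin[0] + c * self.step, self.origin[1] - r * self.step)

    def node_of_flat(self, j: int) -> tuple[int, int]:
        """Row-major flat index -> (row, col)."""
        return divmod(j, self.nx)


@dataclass(frozen=True)
class SubsamplingMask:
    """Binary selection of probe positions, stored row-major over the grid.

    ``order``, when set, is the explicit visiting order of the selected
    nodes (flat row-major indices).  A mask with its own order *is* a scan
    trajectory — the probe path touches only selected nodes, so the beam is
    never blanked and the blanker/generator distinction disappears (the
    linehop pattern is the canonical example).
    """

    s: np.ndarray                  # shape (N,), dtype bool
    strategy: str = "custom"
    hardware: Hardware = "beam_blanker"
    seed: Optional[int] = None
    order: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "s", np.asarray(self.s, dtype=bool).ravel())
        if self.order is not None:
            order = tuple(int(j) for j in self.order)
            if sorted(order) != sorted(map(int, np.flatnonzero(self.s))):
                raise ValueError("order must visit exactly the selected nodes")
            object.__setattr__(self, "order", order)

    @property
    def m(self) -> int:
        return int(self.s.sum())

    @property
    def n(self) -> int:
        return int(self.s.size)

    @property
    def ratio(self) -> float:
        return self.m / self.n

    # -- plain-text / CSV round trips ------------------------------------
    def to_text(self) -> str:
        """One 0/1 per node, row-major, newline separated."""
        return "\n".join("1" if v else "0" for v in self.s) + "\n"

    @staticmethod
    def from_text(text: str, **kw) -> "SubsamplingMask":
        vals = [int(tok) for tok in text.split()]
        return SubsamplingMask(s=np.array(vals, dtype=bool), **kw)

    def to_coords_csv(self, grid: ScanGrid) -> str:
        lines = ["row,col,x_nm,y_nm"]
        for j in np.flatnonzero(self.s):
            node = grid.node_of_flat(int(j))
            x, y = grid.position(node)
            lines.append(f"{node[0]},{node[1]},{x:.6g},{y:.6g}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ScanPlan:
    """A fully resolved acquisition: ordered, timed probe events.

    ``events`` covers each visited grid node exactly once, with strictly
    increasing activation times (probe moves are instantaneous).  ``uniform``
    marks constant dwell and settle — the common case that downstream
    accumulation exploits for kernel caching.
    """

    grid: ScanGrid
    events: tuple[ProbeEvent, ...]
    profile: SourceProfile
    trajectory: str = "raster"
    dwell: float = 0.0
    settle: float = 0.0

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def end_time(self) -> float:
        """End of the last dwell, t_N + τ_N."""
        last = self.events[-1]
        return last.t + last.tau

    def validate(self) -> None:
        seen = set()
        prev_end = -np.inf
        for ev in self.events:
            if ev.node in seen:
                raise ValueError(f"node {ev.node} visited twice")
            seen.add(ev.node)
            if ev.t < prev_end:
                raise ValueError("overlapping probe events")
            prev_end = ev.t + ev.tau

    def order_csv(self) -> str:
        lines = ["order,row,col,t_s,tau_s"]
        for k, ev in enumerate(self.events):
            lines.append(f"{k},{ev.node[0]},{ev.node[1]},{ev.t:.9g},{ev.tau:.9g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_trajectory(grid: ScanGrid, trajectory: Trajectory = "raster",
                    seed: Optional[int] = None, kappa: int = 1,
                    order: Optional[Sequence[tuple[int, int]]] = None,
                    ) -> list[tuple[int, int]]:
    """Ordered list of (row, col) nodes covering the grid exactly once.

    * ``raster``: row-major, each row left→right.
    * ``snake``: row-major with alternating row direction.
    * ``random``: seeded uniform permutation of all nodes.
    * ``alternating``: order-κ interleave — for each offset (a, b) of the
      κ×κ offset grid in row-major order, visit nodes (a+κm, b+κn)
      raster-ordered.  κ=1 reduces to raster.
    * ``custom``: the caller-supplied ``order`` is validated and returned.
    """
    nx, ny = grid.nx, grid.ny
    if trajectory == "raster":
        return [(r, c) for r in range(ny) for c in range(nx)]
    if trajectory == "snake":
        out = []
        for r in range(ny):
            cols = range(nx) if r % 2 == 0 else range(nx - 1, -1, -1)
            out.extend((r, c) for c in cols)
        return out
    if trajectory == "random":
        rng = np.random.default_rng(seed)
        flat = rng.permutation(grid.n)
        return [grid.node_of_flat(int(j)) for j in flat]
    if trajectory == "alternating":
        if kappa < 1:
            raise ValueError("alternating order kappa must be >= 1")
        if kappa > nx or kappa > ny:
            raise ValueError("alternating order exceeds grid extent")
        out = []
        for a in range(kappa):
            for b in range(kappa):
                out.extend((r, c)
                           for r in range(a, ny, kappa)
                           for c in range(b, nx, kappa))
        return out
    if trajectory == "custom":
        if order is None:
            raise ValueError("custom trajectory requires an explicit order")
        order = [tuple(map(int, nd)) for nd in order]
        if sorted(order) != [(r, c) for r in range(ny) for c in range(nx)]:
            raise ValueError("custom order is not a permutation of grid nodes")
        return order
    raise ValueError(f"unknown trajectory {trajectory!r}")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def full_mask(grid: ScanGrid, hardware: Hardware = "beam_blanker",
              ) -> SubsamplingMask:
    return SubsamplingMask(s=np.ones(grid.n, dtype=bool), strategy="full",
                           hardware=hardware)


def make_uds_mask(grid: ScanGrid, ratio: float, seed: Optional[int] = None,
                  hardware: Hardware = "beam_blanker") -> SubsamplingMask:
    """Uniform density sampling: exactly round(ratio·N) nodes, seeded."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("sampling ratio must be in (0, 1]")
    n = grid.n
    m = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    sel = rng.choice(n, size=m, replace=False)
    s = np.zeros(n, dtype=bool)
    s[sel] = True
    return SubsamplingMask(s=s, strategy="UDS", hardware=hardware, seed=seed)


def make_linehop_mask(grid: ScanGrid, ratio: float, seed: Optional[int] = None,
                      hardware: Hardware = "scan_generator",
                      max_retries: int = 50) -> SubsamplingMask:
    """Linehop sampling: L lanes, one pixel per column, ±1-row hops.

    ``L = round(ratio·ny)`` lanes start at equally spaced rows; advancing
    column by column, each lane steps −1/0/+1 rows (seeded, clamped to the
    grid).  Two lanes never share a pixel: colliding steps are resampled up
    to ``max_retries`` times, then shifted deterministically to the nearest
    free row.  The lane paths are also returned (``.lane_rows`` attribute on
    the mask's ``s`` is not used; see :func:`linehop_lanes` for ordering).
    """
    lanes = linehop_lanes(grid, ratio, seed, max_retries)
    s = np.zeros((grid.ny, grid.nx), dtype=bool)
    order = []
    for lane in lanes:          # lane after lane, left to right
        for c, r in enumerate(lane):
            s[r, c] = True
            order.append(r * grid.nx + c)
    return SubsamplingMask(s=s.ravel(), strategy="linehop",
                           hardware=hardware, seed=seed, order=tuple(order))


def linehop_lanes(grid: ScanGrid, ratio: float, seed: Optional[int] = None,
                  max_retries: int = 50) -> list[list[int]]:
    """Row index per column for each linehop lane (lane-major)."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("sampling ratio must be in (0, 1]")
    L = int(round(ratio * grid.ny))
    if L == 0:
        raise ValueError("ratio too small: no lanes")
    if L == grid.ny:  # full sampling: every row is a flat lane
        return [[r] * grid.nx for r in range(grid.ny)]
    rng = np.random.default_rng(seed)
    starts = np.round(np.linspace(0, grid.ny - 1, L)).astype(int)
    # de-duplicate starting rows if rounding collides
    used = set()
    rows = []
    for r in starts:
        r = int(r)
        while r in used:
            r = (r + 1) % grid.ny
        used.add(r)
        rows.append(r)
    lanes = [[r] for r in rows]
    for c in range(1, grid.nx):
        taken: set[int] = set()
        for lane in lanes:
            prev = lane[-1]
            nxt = None
            for _ in range(max_retries):
                cand = int(np.clip(prev + rng.integers(-1, 2), 0, grid.ny - 1))
                if cand not in taken:
                    nxt = cand
                    break
            if nxt is None:  # deterministic shift to nearest free row
                for delta in range(grid.ny):
                    for cand in (prev - delta, prev + delta):
                        if 0 <= cand < grid.ny and cand not in taken:
                            nxt = cand
                            break
                    if nxt is not None:
                        break
            taken.add(nxt)
            lane.append(nxt)
    return lanes


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------

def build_plan(grid: ScanGrid, profile: SourceProfile, dwell: float,
               settle: float = 0.0, trajectory: Trajectory = "raster",
               seed: Optional[int] = None, kappa: int = 1,
               order: Optional[Sequence[tuple[int, int]]] = None) -> ScanPlan:
    """Full-scan plan: every node visited in trajectory order, slot spacing τ+τ̄."""
    if dwell <= 0:
        raise ValueError("dwell must be > 0")
    if settle < 0:
        raise ValueError("settle must be >= 0")
    nodes = make_trajectory(grid, trajectory, seed=seed, kappa=kappa, order=order)
    slot = dwell + settle
    events = tuple(
        ProbeEvent(index=i, node=nd, r=grid.position(nd), t=i * slot, tau=dwell)
        for i, nd in enumerate(nodes)
    )
    return ScanPlan(grid=grid, events=events, profile=profile,
                    trajectory=trajectory, dwell=dwell, settle=settle)


def schedule(plan: ScanPlan, mask: SubsamplingMask) -> ScanPlan:
    """Resolve a subsampled plan under the mask's hardware timing model.

    Beam blanker: the full timeline is retained; unselected slots elapse but
    deposit nothing, so the events keep their full-scan activation times.
    Scan generator: only selected slots exist; they run consecutively with
    spacing τ+τ̄ from t=0.  With a full mask both models coincide.  A mask
    carrying its own visiting order (e.g. linehop) is an explicit trajectory:
    its nodes run consecutively in that order under either hardware model.
    """
    if mask.n != plan.grid.n:
        raise ValueError("mask length does not match grid size")
    if mask.order is not None:
        slot = plan.dwell + plan.settle
        events = tuple(
            ProbeEvent(index=i, node=plan.grid.node_of_flat(j),
                       r=plan.grid.position(plan.grid.node_of_flat(j)),
                       t=i * slot, tau=plan.dwell)
            for i, j in enumerate(mask.order)
        )
        return ScanPlan(grid=plan.grid, events=events, profile=plan.profile,
                        trajectory=f"mask:{mask.strategy}", dwell=plan.dwell,
                        settle=plan.settle)
    selected = []
    for ev in plan.events:
        j = ev.node[0] * plan.grid.nx + ev.node[1]
        if mask.s[j]:
            selected.append(ev)
    if mask.hardware == "beam_blanker":
        events = tuple(replace(ev, index=i) for i, ev in enumerate(selected))
    elif mask.hardware == "scan_generator":
        slot = plan.dwell + plan.settle
        events = tuple(
            replace(ev, index=i, t=i * slot) for i, ev in enumerate(selected)
        )
    else:
        raise ValueError(f"unknown hardware {mask.hardware!r}")
    return ScanPlan(grid=plan.grid, events=events, profile=plan.profile,
                    trajectory=plan.trajectory, dwell=plan.dwell,
                    settle=plan.settle)
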