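"""2-D on-lattice volume-exclusion model of migration and multi-stage
proliferation (growth to confluence).

Cells occupy at most one site of a periodic ``Lx x Ly`` square lattice.
Each cell moves to a uniformly chosen von Neumann neighbour at rate
``Pm`` (aborted if the target is occupied) and undergoes a cell-cycle
stage change at rate ``Pp * k``.  A stage change increments the cell's
stage; a cell in the final stage instead attempts to place a daughter in
a uniform von Neumann neighbour — on success both parent and daughter
restart at stage 1, on failure one of two abort rules applies:

* ``reset`` — the parent's stage is reset to 1 (same average attempt
  rate as the original k = 1 model);
* ``hold`` — the parent stays in stage k, poised to re-attempt quickly
  (closer to a real cell held at a checkpoint).

The two rules coincide for k = 1 but diverge sharply at high density:
``reset`` colonies get *sparser* with more stages, ``hold`` colonies
denser.  Time is reported rescaled, ``tbar = Pp * t``, so runs at
different proliferation rates are comparable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np

from .ssa import spawn_seeds

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "DensityTrajectory",
    "initialise_lattice",
    "simulate_lattice",
    "ensemble_density",
]


@dataclass(frozen=True)
class LatticeConfig:
    Lx: int = 100
    Ly: int = 100
    Pm: float = 1.0  # movement rate (1/time)
    Pp: float = 1.0  # overall proliferation-attempt rate (1/time)
    k: int = 1  # cell-cycle stages
    abort_rule: str = "reset"  # {"reset", "hold"}
    initial_density: float = 0.01
    initial_stages: str = "first"  # {"first", "uniform"}
    h: float = 1.0  # site length; bookkeeping only, the dynamics are h-free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Lx < 2 or self.Ly < 2:
            raise ValueError("lattice must be at least 2x2")
        if not (0.0 < self.initial_density <= 1.0):
            raise ValueError("initial_density must lie in (0, 1]")
        if self.Pm < 0 or self.Pp < 0:
            raise ValueError("rates must be nonnegative")
        if int(self.k) != self.k or self.k < 1:
            raise ValueError("k must be a positive integer")
        object.__setattr__(self, "k", int(self.k))
        if self.abort_rule not in ("reset", "hold"):
            raise ValueError("abort_rule must be 'reset' or 'hold'")
        if self.initial_stages not in ("first", "uniform"):
            raise ValueError("initial_stages must be 'first' or 'uniform'")
        if round(self.initial_density * self.Lx * self.Ly) < 1:
            raise ValueError("initial density places no cells on the lattice")

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly

    @property
    def n_initial(self) -> int:
        return int(round(self.initial_density * self.n_sites))


@dataclass
class LatticeState:
    """Positions (flat site indices), per-cell stages, occupancy mask."""

    cfg: LatticeConfig
    sites: list[int]
    stages: list[int]
    occupied: bytearray
    t: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.sites)

    @property
    def density(self) -> float:
        return self.n_cells / self.cfg.n_sites

    def stage_grid(self) -> np.ndarray:
        """``(Ly, Lx)`` array of stage labels, 0 marking empty sites —
        the raw material for the usual grey-scale snapshot (later stages
        darker, white empty)."""
        grid = np.zeros((self.cfg.Ly, self.cfg.Lx), dtype=np.int32)
        for p, s in zip(self.sites, self.stages):
            grid[p // self.cfg.Lx, p % self.cfg.Lx] = s
        return grid


@dataclass
class DensityTrajectory:
    """Occupied fraction on the rescaled time grid ``tbar = Pp * t``."""

    tbar: np.ndarray
    densities: np.ndarray
    snapshots: list[np.ndarray] = field(default_factory=list)


def initialise_lattice(cfg: LatticeConfig, seed: int | None = None) -> LatticeState:
    """Place ``round(initial_density * Lx * Ly)`` cells uniformly at
    random on distinct sites.  By default every cell starts in stage 1;
    ``initial_stages='uniform'`` draws stages uniformly from 1..k
    instead (terminal densities at small times are sensitive to this)."""
    rng = random.Random(cfg.seed if seed is None else seed)
    n = cfg.n_initial
    sites = rng.sample(range(cfg.n_sites), n)
    if cfg.initial_stages == "first":
        stages = [1] * n
    else:
        stages = [rng.randint(1, cfg.k) for _ in range(n)]
    occupied = bytearray(cfg.n_sites)
    for p in sites:
        occupied[p] = 1
    return LatticeState(cfg=cfg, sites=sites, stages=stages, occupied=occupied)


def _tbar_to_t(cfg: LatticeConfig, tbar: np.ndarray) -> np.ndarray:
    # with Pp = 0 there is no proliferation clock to rescale by; the grid
    # is then interpreted in plain time units
    return tbar / cfg.Pp if cfg.Pp > 0 else tbar


def simulate_lattice(
    cfg: LatticeConfig,
    tbar_record,
    seed: int | None = None,
    snapshots: bool = False,
    state: LatticeState | None = None,
) -> DensityTrajectory:
    """One exact SSA realisation, recording density at the rescaled
    times ``tbar_record``.

    Every cell carries the same total rate ``Pm + Pp*k`` regardless of
    stage, so the direct method reduces to: exponential waiting time
    from the total rate ``N (Pm + Pp k)``, uniform choice of cell, then
    movement vs stage change by rate ratio.
    """
    tbar_record = np.asarray(tbar_record, dtype=float)
    record_times = _tbar_to_t(cfg, tbar_record)
    rng = random.Random(cfg.seed if seed is None else seed)
    if state is None:
        state = initialise_lattice(cfg, seed=rng.randrange(2**31))

    lx, ly = cfg.Lx, cfg.Ly
    n_sites = cfg.n_sites
    k, pm, ppk = cfg.k, cfg.Pm, cfg.Pp * cfg.k
    hold = cfg.abort_rule == "hold"
    per_cell = pm + ppk
    if per_cell == 0.0:
        dens = np.full(tbar_record.shape, state.density)
        snaps = [state.stage_grid() for _ in tbar_record] if snapshots else []
        return DensityTrajectory(tbar=tbar_record, densities=dens, snapshots=snaps)

    sites = state.sites
    stages = state.stages
    occ = state.occupied
    t = state.t
    uniform = rng.random
    log = np.log
    n_rec = record_times.size
    rec_i = 0
    dens = np.empty(n_rec)
    snaps: list[np.ndarray] = []

    while rec_i < n_rec:
        n = len(sites)
        t_next = t - log(uniform()) / (n * per_cell)
        while rec_i < n_rec and record_times[rec_i] < t_next:
            dens[rec_i] = n / n_sites
            if snapshots:
                snaps.append(state.stage_grid())
            rec_i += 1
        if rec_i >= n_rec:
            break
        t = t_next
        i = int(uniform() * n)
        p = sites[i]
        if uniform() * per_cell < pm:
            # movement into a uniform von Neumann neighbour, abort if full
            d = int(uniform() * 4)
            if d == 0:
                q = p - (lx - 1) if p % lx == lx - 1 else p + 1
            elif d == 1:
                q = p + (lx - 1) if p % lx == 0 else p - 1
            elif d == 2:
                q = p - lx * (ly - 1) if p >= lx * (ly - 1) else p + lx
            else:
                q = p + lx * (ly - 1) if p < lx else p - lx
            if not occ[q]:
                occ[p] = 0
                occ[q] = 1
                sites[i] = q
        else:
            s = stages[i]
            if s < k:
                stages[i] = s + 1
            else:
                # division attempt into a uniform von Neumann neighbour
                d = int(uniform() * 4)
                if d == 0:
                    q = p - (lx - 1) if p % lx == lx - 1 else p + 1
                elif d == 1:
                    q = p + (lx - 1) if p % lx == 0 else p - 1
                elif d == 2:
                    q = p - lx * (ly - 1) if p >= lx * (ly - 1) else p + lx
                else:
                    q = p + lx * (ly - 1) if p < lx else p - lx
                if not occ[q]:
                    occ[q] = 1
                    sites.append(q)
                    stages.append(1)
                    stages[i] = 1
                elif not hold:
                    stages[i] = 1
                # under "hold" the parent simply remains in stage k

    state.t = t
    return DensityTrajectory(tbar=tbar_record, densities=dens, snapshots=snaps)


def ensemble_density(
    cfg: LatticeConfig,
    tbar_record,
    reps: int,
    seed: int | None = None,
) -> tuple[DensityTrajectory, np.ndarray]:
    """Across-replicate mean density; returns ``(mean trajectory,
    per-replicate density matrix)`` so callers can attach their own error
    bars.  Per-replicate seeds derive from the root seed."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tbar_record = np.asarray(tbar_record, dtype=float)
    root = cfg.seed if seed is None else seed
    all_dens = np.empty((reps, tbar_record.size))
    for i, s in enumerate(spawn_seeds(root, reps)):
        traj = simulate_lattice(cfg, tbar_record, seed=int(s))
        all_dens[i] = traj.densities
    mean = DensityTrajectory(tbar=tbar_record, densities=all_dens.mean(axis=0))
    return mean, all_dens
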