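"""Basin-hopping global optimisation and basin-hopping parallel tempering.

Basin-hopping proposes a structural perturbation, quenches the perturbed
coordinates to the nearest local minimum, and accepts or rejects on the
quenched energies with a Metropolis rule.  Every converged quench is
recorded in a capacity-bounded :class:`MinimaPool` holding the lowest-energy
distinct minima found, which can afterwards be re-converged to a tight
gradient tolerance with :func:`tight_converge`.

The move set mirrors common peptide-landscape practice: plain Cartesian
displacements, torsional group rotations for chains, and rigid-body moves
for two-monomer (dimer) systems -- radial expansion of the monomer
centroids, angle-axis rotation about each monomer centroid, and random
translation -- interleaved with the Cartesian moves at a configurable
cadence (default: one rigid-body move per 111 Cartesian moves).

:func:`bhpt` runs several basin-hopping replicas at temperatures spaced
geometrically between ``t_min`` and ``t_max`` (default 16 replicas,
300-575) with Metropolis replica-exchange swaps between adjacent
temperatures, and merges the per-replica pools.

All runs are reproducible bit-for-bit from the configured seed.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import _fastmin
from .geometry import aligned_rmsd
from .minimize import MinimizeResult, minimize
from .potentials import LJCluster, Potential, PotentialError

logger = logging.getLogger(__name__)

__all__ = [
    "BHConfig",
    "BHPTConfig",
    "MoveSchedule",
    "MinimaPool",
    "temperature_schedule",
    "basin_hop",
    "bhpt",
    "dimer_move",
    "group_rotation_move",
    "tight_converge",
    "quench",
]

# deduplication tolerances: identical iff both are satisfied
ENERGY_DEDUP_TOL = 1e-6
RMSD_DEDUP_TOL = 1e-3


@dataclass(frozen=True)
class BHConfig:
    """Single-replica basin-hopping parameters.

    ``temperature`` is kBT in the potential's energy units.  ``keep_lowest``
    defaults to the production value of 1000 saved structures;
    ``tight_rms_tol`` to the production RMS-gradient criterion of 1e-7.
    """

    n_steps: int = 1000
    temperature: float = 1.0
    max_step_size: float = 0.4
    seed: int = 0
    keep_lowest: int = 1000
    loose_rms_tol: float = 1e-4
    tight_rms_tol: float = 1e-7
    adapt_step: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise PotentialError("n_steps must be >= 1")
        if self.temperature <= 0:
            raise PotentialError("temperature must be positive")
        if self.keep_lowest < 1:
            raise PotentialError("keep_lowest must be >= 1")
        if self.tight_rms_tol >= self.loose_rms_tol:
            raise PotentialError("tight_rms_tol must be below loose_rms_tol")


@dataclass(frozen=True)
class BHPTConfig:
    """Basin-hopping parallel tempering parameters.

    Defaults follow the production protocol: 16 replicas at temperatures
    geometrically distributed between 300 and 575 (Kelvin-scale numbers are
    only meaningful for potentials in matching units; toy runs pass reduced
    temperatures).
    """

    n_replicas: int = 16
    t_min: float = 300.0
    t_max: float = 575.0
    exchange_interval: int = 10
    base: BHConfig = field(default_factory=BHConfig)

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise PotentialError("need at least 2 replicas")
        if not (0 < self.t_min < self.t_max):
            raise PotentialError("require 0 < t_min < t_max")
        if self.exchange_interval < 1:
            raise PotentialError("exchange_interval must be >= 1")


@dataclass(frozen=True)
class MoveSchedule:
    """Move-set parameters; a rigid-body dimer move replaces every
    ``cartesian_per_rigid``-th Cartesian move when a monomer partition is set."""

    cartesian_per_rigid: int = 111
    rigid_translation_size: float = 0.5
    rigid_rotation_size: float = 1.0
    radial_expansion_factor: float = 1.05
    group_rotation_probability: float = 0.0
    group_rotation_max_angle: float = np.pi
    monomer_partition: tuple[tuple[int, ...], tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if self.cartesian_per_rigid < 1:
            raise PotentialError("cartesian_per_rigid must be >= 1")
        if min(self.rigid_translation_size, self.rigid_rotation_size) < 0:
            raise PotentialError("move sizes must be non-negative")
        if not 0.0 <= self.group_rotation_probability <= 1.0:
            raise PotentialError("group_rotation_probability must be in [0, 1]")


def temperature_schedule(t_min: float, t_max: float, n: int) -> np.ndarray:
    """``n`` temperatures in geometric progression from ``t_min`` to ``t_max``."""
    if n < 2:
        raise PotentialError("schedule needs n >= 2")
    if not (0 < t_min < t_max):
        raise PotentialError("require 0 < t_min < t_max")
    return t_min * (t_max / t_min) ** (np.arange(n) / (n - 1))


class MinimaPool:
    """Capacity-bounded, energy-sorted, deduplicated store of minima.

    Two entries are duplicates iff their energies differ by less than
    ``ENERGY_DEDUP_TOL`` *and* their best-aligned RMSD is below
    ``RMSD_DEDUP_TOL``.
    """

    def __init__(self, capacity: int, ndim: int = 3):
        if capacity < 1:
            raise PotentialError("capacity must be >= 1")
        self.capacity = capacity
        self.ndim = ndim
        self.energies: list[float] = []
        self.coords: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self.energies)

    def __iter__(self):
        return iter(zip(self.energies, self.coords))

    @property
    def lowest_energy(self) -> float:
        if not self.energies:
            raise PotentialError("pool is empty")
        return self.energies[0]

    def _is_duplicate(self, energy: float, x: np.ndarray) -> bool:
        lo = bisect.bisect_left(self.energies, energy - ENERGY_DEDUP_TOL)
        hi = bisect.bisect_right(self.energies, energy + ENERGY_DEDUP_TOL)
        for i in range(lo, hi):
            if aligned_rmsd(self.coords[i], x, self.ndim) < RMSD_DEDUP_TOL:
                return True
        return False

    def insert(self, energy: float, x: np.ndarray) -> bool:
        """Insert a minimum; returns True if stored (new and low enough)."""
        energy = float(energy)
        if len(self.energies) >= self.capacity and energy >= self.energies[-1]:
            return False
        if self._is_duplicate(energy, x):
            return False
        idx = bisect.bisect_left(self.energies, energy)
        self.energies.insert(idx, energy)
        self.coords.insert(idx, np.array(x, dtype=float, copy=True))
        if len(self.energies) > self.capacity:
            self.energies.pop()
            self.coords.pop()
        return True

    def merge(self, other: "MinimaPool") -> None:
        for energy, x in other:
            self.insert(energy, x)


def quench(pot: Potential, x: np.ndarray, rms_tol: float) -> MinimizeResult:
    """Local minimisation with a compiled fast path for LJ clusters."""
    if isinstance(pot, LJCluster) and _fastmin.HAVE_NUMBA:
        xq, e, rms, conv = _fastmin.lj_quench(
            np.asarray(x, dtype=float).ravel(), pot.n_particles, pot.ndim, rms_tol
        )
        if conv:
            return MinimizeResult(xq, e, np.array([]), rms, conv, -1)
        # rare pathological starts (deep in the repulsive wall) can stall the
        # compiled line search; the generic path is slower but robust
    return minimize(pot, x, rms_tol=rms_tol)


def _propose(
    x: np.ndarray,
    pot: Potential,
    moveset: MoveSchedule,
    step_size: float,
    step_index: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if (
        moveset.monomer_partition is not None
        and (step_index + 1) % moveset.cartesian_per_rigid == 0
    ):
        return dimer_move(x, moveset, rng)
    if (
        moveset.group_rotation_probability > 0
        and rng.random() < moveset.group_rotation_probability
    ):
        return group_rotation_move(
            x.reshape(-1, 3), rng, max_angle=moveset.group_rotation_max_angle
        ).ravel()
    return x + rng.uniform(-step_size, step_size, size=x.size)


def basin_hop(
    pot: Potential,
    start: np.ndarray,
    moveset: MoveSchedule,
    cfg: BHConfig,
    rng: np.random.Generator | None = None,
    pool: MinimaPool | None = None,
) -> tuple[MinimaPool, dict]:
    """Run basin-hopping from ``start``; returns the pool and acceptance stats."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if pool is None:
        pool = MinimaPool(cfg.keep_lowest, ndim=pot.ndim)
    x = np.asarray(start, dtype=float).ravel()
    res = quench(pot, x, cfg.loose_rms_tol)
    if not res.converged:
        raise PotentialError("starting configuration failed to quench")
    x, energy = res.x, res.energy
    pool.insert(energy, x)
    n_accept = n_reject = n_fail = 0
    step_size = cfg.max_step_size
    for step in range(cfg.n_steps):
        x_prop = _propose(x, pot, moveset, step_size, step, rng)
        try:
            res = quench(pot, x_prop, cfg.loose_rms_tol)
        except PotentialError:
            res = None
        u = rng.random()  # drawn unconditionally to keep the stream aligned
        if res is None or not res.converged:
            n_fail += 1
            logger.debug("step %d: quench failed, step rejected", step)
            continue
        pool.insert(res.energy, res.x)
        if res.energy <= energy or u < np.exp(-(res.energy - energy) / cfg.temperature):
            x, energy = res.x, res.energy
            n_accept += 1
        else:
            n_reject += 1
        if cfg.adapt_step and (step + 1) % 50 == 0:
            rate = n_accept / max(1, n_accept + n_reject)
            step_size *= 1.05 if rate > 0.5 else 0.95
        if (step + 1) % 1000 == 0:
            logger.info(
                "step %d: E=%.6f best=%.6f pool=%d acc=%.2f",
                step + 1, energy, pool.lowest_energy, len(pool),
                n_accept / max(1, n_accept + n_reject),
            )
    stats = {
        "n_accepted": n_accept,
        "n_rejected": n_reject,
        "n_quench_failures": n_fail,
        "acceptance_rate": n_accept / max(1, n_accept + n_reject),
        "final_step_size": step_size,
        "final_x": x,
        "final_energy": energy,
    }
    return pool, stats


def bhpt(
    pot: Potential,
    starts: Sequence[np.ndarray] | np.ndarray,
    moveset: MoveSchedule,
    cfg: BHPTConfig,
) -> tuple[MinimaPool, dict]:
    """Basin-hopping parallel tempering; replicas run sequentially.

    ``starts`` is one configuration per replica or a single shared one.
    Swaps between adjacent temperatures use the Metropolis criterion on the
    replicas' current quenched energies.
    """
    temps = temperature_schedule(cfg.t_min, cfg.t_max, cfg.n_replicas)
    starts = np.asarray(starts, dtype=float)
    if starts.ndim == 1:
        starts = np.tile(starts, (cfg.n_replicas, 1))
    if starts.shape[0] != cfg.n_replicas:
        raise PotentialError("need one start per replica or a single shared start")

    seeds = np.random.SeedSequence(cfg.base.seed).spawn(cfg.n_replicas + 1)
    rngs = [np.random.default_rng(s) for s in seeds[:-1]]
    swap_rng = np.random.default_rng(seeds[-1])

    states = []
    pools = []
    for i in range(cfg.n_replicas):
        res = quench(pot, starts[i].ravel(), cfg.base.loose_rms_tol)
        states.append((res.x, res.energy))
        pools.append(MinimaPool(cfg.base.keep_lowest, ndim=pot.ndim))
        pools[-1].insert(res.energy, res.x)

    n_swap_accept = n_swap_try = 0
    steps_done = 0
    while steps_done < cfg.base.n_steps:
        chunk = min(cfg.exchange_interval, cfg.base.n_steps - steps_done)
        for i in range(cfg.n_replicas):
            sub = replace(cfg.base, n_steps=chunk, temperature=float(temps[i]))
            x, _ = states[i]
            _, st = basin_hop(pot, x, moveset, sub, rng=rngs[i], pool=pools[i])
            states[i] = (st["final_x"], st["final_energy"])
        steps_done += chunk
        for i in range(cfg.n_replicas - 1):
            n_swap_try += 1
            (xi, ei), (xj, ej) = states[i], states[i + 1]
            delta = (1.0 / temps[i] - 1.0 / temps[i + 1]) * (ei - ej)
            if delta >= 0 or swap_rng.random() < np.exp(delta):
                states[i], states[i + 1] = (xj, ej), (xi, ei)
                n_swap_accept += 1
    merged = MinimaPool(cfg.base.keep_lowest, ndim=pot.ndim)
    for p in pools:
        merged.merge(p)
    stats = {
        "swap_attempts": n_swap_try,
        "swap_acceptance": n_swap_accept / max(1, n_swap_try),
        "temperatures": temps,
    }
    return merged, stats


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * radius * rng.random() ** (1.0 / 3.0)


def dimer_move(x: np.ndarray, schedule: MoveSchedule, rng: np.random.Generator) -> np.ndarray:
    """Rigid-body move for a two-monomer system.

    Each monomer's centroid is displaced radially from the overall centroid
    by ``radial_expansion_factor``; the monomer is then rotated about its
    centroid by a random angle-axis vector of magnitude at most
    ``rigid_rotation_size`` and translated by a random vector of length at
    most ``rigid_translation_size``.  Internal monomer geometry is preserved
    exactly.
    """
    if schedule.monomer_partition is None:
        raise PotentialError("dimer_move requires a monomer partition")
    idx_a, idx_b = (np.asarray(ix, dtype=int) for ix in schedule.monomer_partition)
    pos = np.array(x, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    combined = np.concatenate([idx_a, idx_b])
    if (
        len(combined) != n
        or len(np.unique(combined)) != n
        or combined.min() < 0
        or combined.max() >= n
    ):
        raise PotentialError("monomer index sets must partition the particles")
    overall = pos.mean(axis=0)
    for idx in (idx_a, idx_b):
        mono = pos[idx]
        centroid = mono.mean(axis=0)
        new_centroid = overall + schedule.radial_expansion_factor * (centroid - overall)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.random() * schedule.rigid_rotation_size
        rot = Rotation.from_rotvec(axis * angle)
        translation = _random_in_ball(rng, schedule.rigid_translation_size)
        pos[idx] = rot.apply(mono - centroid) + new_centroid + translation
    return pos.ravel()


def group_rotation_move(
    pos: np.ndarray, rng: np.random.Generator, max_angle: float = np.pi
) -> np.ndarray:
    """Rotate a random contiguous tail segment about its preceding bond axis.

    For a chain of beads 0..n-1 a segment start s in [2, n-1] is drawn; beads
    s..n-1 are rotated about the axis of bond (s-2, s-1), through bead s-1,
    by a uniform angle in [-max_angle, max_angle].
    """
    pos = np.array(pos, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    if n < 4:
        raise PotentialError("group rotation needs a chain of at least 4 beads")
    s = int(rng.integers(2, n))
    angle = rng.uniform(-max_angle, max_angle)
    axis = pos[s - 1] - pos[s - 2]
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return pos
    rot = Rotation.from_rotvec(axis / norm * angle)
    pos[s:] = rot.apply(pos[s:] - pos[s - 1]) + pos[s - 1]
    return pos


def tight_converge(pool: MinimaPool, pot: Potential, tol: float = 1e-7) -> MinimaPool:
    """Re-converge every pool entry to RMS gradient <= ``tol``.

    Entries that fail to converge within the iteration budget are dropped
    with a warning; the refined pool is re-deduplicated (entries that merge
    under refinement collapse to one).
    """
    refined = MinimaPool(pool.capacity, ndim=pool.ndim)
    for energy, x in pool:
        res = quench(pot, x, tol)
        if not res.converged:
            logger.warning("tight convergence failed for minimum at E=%.6f; dropped", energy)
            continue
        refined.insert(res.energy, res.x)
    return refined
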