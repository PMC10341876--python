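"""The stationary-point database: minima, transition states, connectivity.

A landscape is catalogued as a set of local minima and the index-1 saddles
(transition states) that connect them.  Each record carries the quantities
the harmonic superposition approximation needs: the energy, the log product
of positive normal-mode frequencies, and a degeneracy order (a single
multiplicative weight for permutation-inversion isomers divided by the
point-group order).  The number of vibrational degrees of freedom ``kappa``
is a property of the whole database and must be identical for every
minimum.

Internal minimum and transition-state ids are 0-based and dense; the flat
file formats in :mod:`hexscape.io_formats` use 1-based ids on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import aligned_rmsd

__all__ = [
    "DatabaseError",
    "MinimumRecord",
    "TransitionStateRecord",
    "StationaryPointDatabase",
    "BARRIER_TOL",
]

#: tolerance for the barrier-positivity invariant E_ts >= E_min - BARRIER_TOL
BARRIER_TOL = 1e-8

# deduplication: records identical iff both tolerances are met
ENERGY_DEDUP_TOL = 1e-6
RMSD_DEDUP_TOL = 1e-3


class DatabaseError(ValueError):
    """Invalid stationary-point database content."""


@dataclass
class MinimumRecord:
    """One local minimum.

    ``log_freq_product`` is the sum of log positive normal-mode frequencies
    (kappa terms); ``degeneracy`` the multiplicative permutation-inversion /
    point-group weight n_a > 0.
    """

    id: int
    energy: float
    log_freq_product: float = 0.0
    degeneracy: float = 1.0
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise DatabaseError(f"minimum {self.id}: energy not finite")
        if self.degeneracy <= 0:
            raise DatabaseError(f"minimum {self.id}: degeneracy must be positive")


@dataclass
class TransitionStateRecord:
    """One index-1 saddle and the two minima its descents reach.

    ``log_freq_product`` sums the log positive frequencies only (the single
    negative mode and zero modes are excluded).
    """

    id: int
    energy: float
    min1_id: int
    min2_id: int
    log_freq_product: float = 0.0
    degeneracy: float = 1.0
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise DatabaseError(f"ts {self.id}: energy not finite")


class StationaryPointDatabase:
    """Minima + transition states + optional coordinates for one landscape."""

    def __init__(
        self,
        kappa: int | None = None,
        ndim: int = 3,
        metadata: dict | None = None,
    ):
        self.kappa = kappa
        self.ndim = ndim
        self.metadata: dict = metadata or {}
        self.minima: list[MinimumRecord] = []
        self.transition_states: list[TransitionStateRecord] = []

    # -- construction -----------------------------------------------------

    def add_minimum(
        self,
        energy: float,
        log_freq_product: float = 0.0,
        degeneracy: float = 1.0,
        coordinates: np.ndarray | None = None,
    ) -> int:
        mid = len(self.minima)
        self.minima.append(
            MinimumRecord(
                mid, float(energy), float(log_freq_product), float(degeneracy),
                None if coordinates is None else np.array(coordinates, dtype=float).ravel(),
            )
        )
        return mid

    def add_transition_state(
        self,
        energy: float,
        min1_id: int,
        min2_id: int,
        log_freq_product: float = 0.0,
        degeneracy: float = 1.0,
        coordinates: np.ndarray | None = None,
    ) -> int:
        tid = len(self.transition_states)
        self.transition_states.append(
            TransitionStateRecord(
                tid, float(energy), int(min1_id), int(min2_id),
                float(log_freq_product), float(degeneracy),
                None if coordinates is None else np.array(coordinates, dtype=float).ravel(),
            )
        )
        return tid

    def find_minimum(self, energy: float, coordinates: np.ndarray) -> int | None:
        """Return the id of a stored duplicate of this minimum, if any."""
        for m in self.minima:
            if abs(m.energy - energy) < ENERGY_DEDUP_TOL and m.coordinates is not None:
                if aligned_rmsd(m.coordinates, coordinates, self.ndim) < RMSD_DEDUP_TOL:
                    return m.id
        return None

    def add_minimum_checked(self, energy: float, coordinates: np.ndarray, modes) -> int:
        """Insert a minimum with normal-mode data, deduplicating."""
        existing = self.find_minimum(energy, coordinates)
        if existing is not None:
            return existing
        if self.kappa is None:
            self.kappa = modes.kappa
        elif modes.kappa != self.kappa:
            raise DatabaseError(
                f"kappa mismatch: database has {self.kappa}, new minimum {modes.kappa}"
            )
        return self.add_minimum(
            energy, log_freq_product=modes.log_freq_product, coordinates=coordinates
        )

    def add_transition_state_checked(
        self, energy: float, coordinates: np.ndarray, min1_id: int, min2_id: int, modes
    ) -> int | None:
        """Insert a TS, deduplicating against stored TS; returns id or None."""
        for ts in self.transition_states:
            if abs(ts.energy - energy) < ENERGY_DEDUP_TOL and ts.coordinates is not None:
                if aligned_rmsd(ts.coordinates, coordinates, self.ndim) < RMSD_DEDUP_TOL:
                    return None
        for mid in (min1_id, min2_id):
            if not 0 <= mid < len(self.minima):
                raise DatabaseError(f"ts references unknown minimum {mid}")
        e1 = self.minima[min1_id].energy
        e2 = self.minima[min2_id].energy
        if energy < max(e1, e2) - BARRIER_TOL:
            raise DatabaseError(
                f"ts energy {energy} below connected minimum max({e1}, {e2})"
            )
        return self.add_transition_state(
            energy, min1_id, min2_id,
            log_freq_product=modes.log_freq_product, coordinates=coordinates,
        )

    # -- access -----------------------------------------------------------

    @property
    def n_minima(self) -> int:
        return len(self.minima)

    @property
    def minima_ids(self) -> list[int]:
        return [m.id for m in self.minima]

    @property
    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.minima])

    def coordinates_of(self, mid: int) -> np.ndarray:
        m = self.minima[mid]
        if m.coordinates is None:
            raise DatabaseError(f"minimum {mid} has no coordinates")
        return m.coordinates

    @property
    def global_minimum(self) -> MinimumRecord:
        if not self.minima:
            raise DatabaseError("empty database")
        return min(self.minima, key=lambda m: m.energy)

    def graph(self) -> nx.MultiGraph:
        """Connectivity graph: nodes are minima, edges transition states."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.minima_ids)
        for ts in self.transition_states:
            g.add_edge(ts.min1_id, ts.min2_id, ts_id=ts.id, energy=ts.energy)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph()) if self.minima else False

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Check every database invariant; returns a list of violations."""
        report: list[str] = []
        ids = self.minima_ids
        if len(set(ids)) != len(ids):
            report.append("duplicate minimum ids")
        if ids != list(range(len(ids))):
            report.append("minimum ids are not dense 0..n-1")
        for ts in self.transition_states:
            for mid in (ts.min1_id, ts.min2_id):
                if not 0 <= mid < len(self.minima):
                    report.append(f"ts {ts.id}: dangling minimum reference {mid}")
            if 0 <= ts.min1_id < len(self.minima) and 0 <= ts.min2_id < len(self.minima):
                top = max(self.minima[ts.min1_id].energy, self.minima[ts.min2_id].energy)
                if ts.energy < top - BARRIER_TOL:
                    report.append(
                        f"ts {ts.id}: energy {ts.energy:.8f} below connected minima"
                    )
        ts_ids = [ts.id for ts in self.transition_states]
        if len(set(ts_ids)) != len(ts_ids):
            report.append("duplicate transition-state ids")
        if self.kappa is not None and self.kappa < 1:
            report.append("kappa must be >= 1")
        return report
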