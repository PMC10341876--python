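"""Shared fixtures: the grid+Newton stationary-point oracle for the
Mueller-Brown surface, and small database factories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from hexscape.database import StationaryPointDatabase
from hexscape.minimize import hessian
from hexscape.potentials import MullerBrown


@dataclass(frozen=True)
class StationaryPoint:
    position: np.ndarray
    energy: float
    index: int  # 0 = minimum, 1 = saddle


def _newton_refine(pot, x0, max_iter=100):
    x = np.array(x0, dtype=float)
    for _ in range(max_iter):
        g = pot.gradient(x)
        if np.linalg.norm(g) < 1e-12:
            break
        x = x - np.linalg.solve(hessian(pot, x), g)
    return x


@pytest.fixture(scope="session")
def mb_inventory() -> list[StationaryPoint]:
    """All stationary points of the Mueller-Brown surface in the standard
    region, located independently by a dense grid scan + Newton refinement."""
    pot = MullerBrown()
    found: list[StationaryPoint] = []
    with np.errstate(over="ignore", invalid="ignore"):
        for x0 in np.linspace(-1.8, 1.2, 14):
            for y0 in np.linspace(-0.5, 2.2, 14):
                try:
                    p = _newton_refine(pot, [x0, y0])
                except np.linalg.LinAlgError:
                    continue
                if not (-2 < p[0] < 1.5 and -0.7 < p[1] < 2.5):
                    continue
                if not np.all(np.isfinite(p)) or np.linalg.norm(pot.gradient(p)) > 1e-8:
                    continue
                if any(np.linalg.norm(p - q.position) < 1e-4 for q in found):
                    continue
                vals = np.linalg.eigvalsh(hessian(pot, p))
                found.append(StationaryPoint(p, pot.energy(p), int(np.sum(vals < 0))))
    return sorted(found, key=lambda s: s.energy)


@pytest.fixture(scope="session")
def mb_minima(mb_inventory):
    return [s for s in mb_inventory if s.index == 0]


@pytest.fixture(scope="session")
def mb_saddles(mb_inventory):
    return [s for s in mb_inventory if s.index == 1]


def make_random_db(rng: np.random.Generator, n_minima: int | None = None,
                   kappa: int | None = None) -> StationaryPointDatabase:
    """A random (unconnected) database for thermodynamic property tests."""
    if n_minima is None:
        n_minima = int(rng.integers(2, 40))
    if kappa is None:
        kappa = int(rng.integers(1, 15))
    db = StationaryPointDatabase(kappa=kappa)
    for _ in range(n_minima):
        db.add_minimum(
            float(rng.normal() * 2),
            log_freq_product=float(rng.normal()),
            degeneracy=float(rng.uniform(0.5, 4.0)),
        )
    return db


@pytest.fixture
def two_state_db() -> StationaryPointDatabase:
    """Two minima, energy gap 0.3, identical entropy: the Schottky reference."""
    db = StationaryPointDatabase(kappa=5)
    db.add_minimum(0.0)
    db.add_minimum(0.3)
    return db
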