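"""Differentiable toy potentials used to exercise the landscape machinery.

Three surfaces are provided, all in reduced units (energy and length
dimensionless):

* :class:`MullerBrown` -- the standard two-dimensional four-Gaussian test
  surface with three minima and two index-1 saddles; the workhorse for
  verifying transition-state searches.
* :class:`LJCluster` -- N identical Lennard-Jones particles
  (epsilon = sigma = 1), the canonical benchmark for basin-hopping global
  optimisation.
* :class:`BeadChain` -- a coarse-grained polymer: harmonic bonds, harmonic
  angle bends, a cosine-series dihedral potential with trans and gauche
  wells, and attractive Lennard-Jones interactions between beads at least
  three bonds apart.  The gauche wells plus the nonbonded attraction create
  compact basins that compete with the extended all-trans basin, mimicking
  the hairpin-versus-helix competition seen in short peptides.

Each potential evaluates the energy and the analytic gradient of a flat
coordinate vector; :func:`numerical_gradient` is the central-difference
oracle used to validate the analytic forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PotentialError",
    "CoincidentParticlesError",
    "Configuration",
    "PotentialSpec",
    "Potential",
    "MullerBrown",
    "LJCluster",
    "BeadChain",
    "make_potential",
    "evaluate",
    "numerical_gradient",
]

#: minimum allowed pair distance (in sigma) before a configuration is rejected
COINCIDENCE_TOL = 1e-6


class PotentialError(ValueError):
    """Invalid input to a potential evaluation."""


class CoincidentParticlesError(PotentialError):
    """Two particles closer than the coincidence guard; energy undefined."""


@dataclass(frozen=True)
class Configuration:
    """A flat coordinate vector plus its shape metadata.

    ``coordinates`` has length ``particle_count * dimensionality``; the
    layout is particle-major (x1, y1, [z1], x2, ...).
    """

    coordinates: np.ndarray
    particle_count: int
    dimensionality: int

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).ravel()
        object.__setattr__(self, "coordinates", coords)
        if self.dimensionality not in (2, 3):
            raise PotentialError(f"dimensionality must be 2 or 3, got {self.dimensionality}")
        if coords.size != self.particle_count * self.dimensionality:
            raise PotentialError(
                f"coordinate length {coords.size} inconsistent with "
                f"{self.particle_count} particles x {self.dimensionality}D"
            )
        if not np.all(np.isfinite(coords)):
            raise PotentialError("coordinates must be finite")

    @property
    def positions(self) -> np.ndarray:
        """Coordinates reshaped to (particle_count, dimensionality)."""
        return self.coordinates.reshape(self.particle_count, self.dimensionality)


@dataclass(frozen=True)
class PotentialSpec:
    """Declarative description of a toy potential (name + parameters)."""

    name: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("mueller_brown_2d", "lj_cluster", "bead_chain"):
            raise PotentialError(f"unknown potential {self.name!r}")
        for key, value in self.parameters.items():
            if not np.isfinite(value):
                raise PotentialError(f"parameter {key!r} is not finite")


class Potential:
    """Base class: a differentiable energy on flat coordinate vectors."""

    #: spatial dimensionality of one particle
    ndim: int
    #: number of particles
    n_particles: int

    @property
    def dof(self) -> int:
        return self.ndim * self.n_particles

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def energy(self, x: np.ndarray) -> float:
        return self.energy_gradient(x)[0]

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.energy_gradient(x)[1]

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.dof:
            raise PotentialError(f"expected {self.dof} coordinates, got {x.size}")
        return x

    def check_configuration(self, config: Configuration) -> None:
        if config.particle_count != self.n_particles or config.dimensionality != self.ndim:
            raise PotentialError(
                f"configuration ({config.particle_count} x {config.dimensionality}D) "
                f"does not match potential ({self.n_particles} x {self.ndim}D)"
            )


class MullerBrown(Potential):
    """The standard four-Gaussian two-dimensional test surface."""

    ndim = 2
    n_particles = 1

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self._check(x)
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        terms = self.A * np.exp(self.a * dx * dx + self.b * dx * dy + self.c * dy * dy)
        energy = float(terms.sum())
        gx = float(np.sum(terms * (2.0 * self.a * dx + self.b * dy)))
        gy = float(np.sum(terms * (self.b * dx + 2.0 * self.c * dy)))
        return energy, np.array([gx, gy])


class LJCluster(Potential):
    """N identical Lennard-Jones particles, epsilon = sigma = 1."""

    def __init__(self, n_particles: int, ndim: int = 3):
        if n_particles < 2:
            raise PotentialError("LJ cluster needs at least 2 particles")
        if ndim not in (2, 3):
            raise PotentialError("ndim must be 2 or 3")
        self.n_particles = int(n_particles)
        self.ndim = int(ndim)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self._check(x)
        pos = x.reshape(self.n_particles, self.ndim)
        diff = pos[:, None, :] - pos[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        iu = np.triu_indices(self.n_particles, k=1)
        r2_pairs = r2[iu]
        if np.any(r2_pairs < COINCIDENCE_TOL**2):
            raise CoincidentParticlesError(
                f"pair distance below coincidence guard {COINCIDENCE_TOL}"
            )
        inv_r2 = 1.0 / r2_pairs
        inv_r6 = inv_r2**3
        inv_r12 = inv_r6**2
        energy = float(4.0 * np.sum(inv_r12 - inv_r6))
        # dU/dr2 summed back onto particles
        coeff = np.zeros_like(r2)
        coeff[iu] = 4.0 * (-12.0 * inv_r12 + 6.0 * inv_r6) * inv_r2
        coeff = coeff + coeff.T
        grad = np.einsum("ij,ijk->ik", coeff, diff)
        return energy, grad.ravel()


def _dihedral_energy_gradient(p: np.ndarray, coeffs: tuple[float, ...]) -> tuple[float, np.ndarray]:
    """Energy and 12-component gradient of a cosine-series torsion on 4 points.

    V(phi) = sum_n c_n * (1 + cos(n * phi)), coeffs = (c1, c2, c3).
    Uses the standard atan2 torsion and analytic derivatives.
    """
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    xx = float(n1 @ n2)
    yy = b2n * float(b1 @ n2)
    phi = np.arctan2(yy, xx)

    c1, c2, c3 = coeffs
    energy = (
        c1 * (1.0 + np.cos(phi))
        + c2 * (1.0 + np.cos(2.0 * phi))
        + c3 * (1.0 + np.cos(3.0 * phi))
    )
    dV_dphi = -(c1 * np.sin(phi) + 2.0 * c2 * np.sin(2.0 * phi) + 3.0 * c3 * np.sin(3.0 * phi))

    # dphi/dx via the standard formulas (e.g. classical MD force derivations)
    n1_sq = float(n1 @ n1)
    n2_sq = float(n2 @ n2)
    dphi_dp0 = -(b2n / n1_sq) * n1
    dphi_dp3 = (b2n / n2_sq) * n2
    f1 = float(b1 @ b2) / (b2n * b2n)
    f2 = float(b3 @ b2) / (b2n * b2n)
    dphi_dp1 = -(1.0 + f1) * dphi_dp0 + f2 * dphi_dp3
    dphi_dp2 = f1 * dphi_dp0 - (1.0 + f2) * dphi_dp3

    grad = dV_dphi * np.concatenate([dphi_dp0, dphi_dp1, dphi_dp2, dphi_dp3])
    return float(energy), grad


class BeadChain(Potential):
    """Coarse-grained bead polymer with competing compact/extended basins.

    Terms: harmonic bonds, harmonic angle bends, a (c1, c2, c3) cosine-series
    dihedral with trans and gauche wells, and truncation-free attractive LJ
    between beads separated by three or more bonds.
    """

    ndim = 3

    def __init__(
        self,
        n_beads: int,
        bond_k: float = 100.0,
        bond_r0: float = 1.0,
        angle_k: float = 10.0,
        angle_theta0: float = 1.8849555921538759,  # 108 degrees
        dihedral_coeffs: tuple[float, float, float] = (0.8, 0.0, 1.2),
        nb_epsilon: float = 0.6,
        nb_sigma: float = 1.1,
    ):
        if n_beads < 4:
            raise PotentialError("bead chain needs at least 4 beads (dihedral defined)")
        params = (bond_k, bond_r0, angle_k, angle_theta0, nb_epsilon, nb_sigma, *dihedral_coeffs)
        if not all(np.isfinite(p) for p in params):
            raise PotentialError("bead-chain parameters must be finite")
        self.n_particles = int(n_beads)
        self.bond_k = float(bond_k)
        self.bond_r0 = float(bond_r0)
        self.angle_k = float(angle_k)
        self.angle_theta0 = float(angle_theta0)
        self.dihedral_coeffs = tuple(float(c) for c in dihedral_coeffs)
        self.nb_epsilon = float(nb_epsilon)
        self.nb_sigma = float(nb_sigma)

    @property
    def n_beads(self) -> int:
        return self.n_particles

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self._check(x)
        pos = x.reshape(self.n_particles, 3)
        grad = np.zeros_like(pos)
        energy = 0.0

        # bonds
        bond_vec = pos[1:] - pos[:-1]
        bond_len = np.linalg.norm(bond_vec, axis=1)
        if np.any(bond_len < COINCIDENCE_TOL):
            raise CoincidentParticlesError("bonded beads coincide")
        stretch = bond_len - self.bond_r0
        energy += float(self.bond_k * np.sum(stretch**2))
        f = (2.0 * self.bond_k * stretch / bond_len)[:, None] * bond_vec
        grad[1:] += f
        grad[:-1] -= f

        # angle bends
        for i in range(self.n_particles - 2):
            u = pos[i] - pos[i + 1]
            v = pos[i + 2] - pos[i + 1]
            nu = np.linalg.norm(u)
            nv = np.linalg.norm(v)
            cos_t = float(u @ v) / (nu * nv)
            cos_t = min(1.0, max(-1.0, cos_t))
            theta = np.arccos(cos_t)
            dtheta = theta - self.angle_theta0
            energy += self.angle_k * dtheta * dtheta
            sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
            dE_dtheta = 2.0 * self.angle_k * dtheta
            dcos_du = v / (nu * nv) - cos_t * u / (nu * nu)
            dcos_dv = u / (nu * nv) - cos_t * v / (nv * nv)
            pref = -dE_dtheta / sin_t
            grad[i] += pref * dcos_du
            grad[i + 2] += pref * dcos_dv
            grad[i + 1] -= pref * (dcos_du + dcos_dv)

        # dihedrals
        for i in range(self.n_particles - 3):
            e, g = _dihedral_energy_gradient(pos[i : i + 4], self.dihedral_coeffs)
            energy += e
            grad[i : i + 4] += g.reshape(4, 3)

        # nonbonded LJ, |i - j| >= 3
        n = self.n_particles
        if n >= 4:
            ii, jj = np.triu_indices(n, k=3)
            diff = pos[ii] - pos[jj]
            r2 = np.einsum("ij,ij->i", diff, diff)
            if np.any(r2 < (COINCIDENCE_TOL * self.nb_sigma) ** 2):
                raise CoincidentParticlesError("nonbonded beads coincide")
            s2 = self.nb_sigma**2 / r2
            s6 = s2**3
            s12 = s6**2
            energy += float(4.0 * self.nb_epsilon * np.sum(s12 - s6))
            coeff = (4.0 * self.nb_epsilon * (-12.0 * s12 + 6.0 * s6) / r2)[:, None] * diff
            np.add.at(grad, ii, coeff)
            np.add.at(grad, jj, -coeff)

        return float(energy), grad.ravel()


def make_potential(spec: PotentialSpec) -> Potential:
    """Instantiate a :class:`Potential` from a :class:`PotentialSpec`."""
    p = dict(spec.parameters)
    if spec.name == "mueller_brown_2d":
        return MullerBrown()
    if spec.name == "lj_cluster":
        return LJCluster(int(p.pop("n_particles", 7)), int(p.pop("ndim", 3)))
    if spec.name == "bead_chain":
        n = int(p.pop("n_beads", 8))
        return BeadChain(n, **p)
    raise PotentialError(f"unknown potential {spec.name!r}")


def evaluate(spec: PotentialSpec | Potential, config: Configuration) -> tuple[float, np.ndarray]:
    """Energy and gradient of ``config`` under ``spec``.

    Raises :class:`PotentialError` on shape mismatch and
    :class:`CoincidentParticlesError` when particles overlap under an LJ term.
    """
    pot = make_potential(spec) if isinstance(spec, PotentialSpec) else spec
    pot.check_configuration(config)
    return pot.energy_gradient(config.coordinates)


def numerical_gradient(pot: Potential, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-finite-difference gradient, one coordinate at a time."""
    if step <= 0:
        raise PotentialError("step must be positive")
    x = np.asarray(x, dtype=float).ravel()
    grad = np.empty_like(x)
    for i in range(x.size):
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        grad[i] = (pot.energy(xp) - pot.energy(xm)) / (2.0 * step)
    return grad
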