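"""Local minimisation and normal-mode analysis for toy potentials.

Minimisation is limited-memory quasi-Newton (L-BFGS) with convergence
declared when the root-mean-square gradient falls below a tolerance, the
criterion used throughout basin-hopping and database refinement.  Hessians
are central finite differences of the analytic gradient; eigenvalues with
magnitude below ``ZERO_MODE_TOL`` are treated as zero modes (overall
translation/rotation) and excluded from vibrational analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .potentials import Potential

ZERO_MODE_TOL = 1e-6

__all__ = ["MinimizeResult", "minimize", "hessian", "NormalModes", "normal_modes"]


@dataclass
class MinimizeResult:
    x: np.ndarray
    energy: float
    gradient: np.ndarray
    rms_grad: float
    converged: bool
    n_iter: int


def rms(g: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(g))))


def minimize(
    pot: Potential,
    x0: np.ndarray,
    rms_tol: float = 1e-4,
    max_iter: int = 10_000,
) -> MinimizeResult:
    """Quench ``x0`` to the nearest local minimum.

    Convergence requires RMS gradient <= ``rms_tol``; the L-BFGS stopping
    test uses the max-component gradient, which bounds the RMS from above,
    so an extra polish loop is rarely needed but is applied when the history
    stalls just short of the tolerance.
    """
    res = scipy.optimize.minimize(
        pot.energy_gradient,
        np.asarray(x0, dtype=float).ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": rms_tol, "ftol": 1e-16, "maxcor": 20},
    )
    x = res.x
    energy, grad = pot.energy_gradient(x)
    r = rms(grad)
    n_iter = int(res.nit)
    if r > rms_tol:
        # Newton polish with zero-mode filtering: L-BFGS stalls once energy
        # differences reach roundoff, but curvature information still drives
        # the gradient to tight tolerances near a minimum
        for _ in range(50):
            H = hessian(pot, x)
            vals, vecs = np.linalg.eigh(H)
            proj = vecs.T @ grad
            keep = np.abs(vals) > ZERO_MODE_TOL
            step = -(vecs[:, keep] @ (proj[keep] / np.abs(vals[keep])))
            norm = np.linalg.norm(step)
            if norm > 0.1:
                step *= 0.1 / norm
            x_new = x + step
            e_new, g_new = pot.energy_gradient(x_new)
            r_new = rms(g_new)
            if not np.isfinite(e_new) or r_new >= r:
                break
            x, energy, grad, r = x_new, e_new, g_new, r_new
            n_iter += 1
            if r <= rms_tol:
                break
    return MinimizeResult(x, float(energy), grad, r, r <= rms_tol, n_iter)


def hessian(pot: Potential, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Symmetrised central-difference Hessian of the analytic gradient."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        H[i] = (pot.gradient(xp) - pot.gradient(xm)) / (2.0 * step)
    return 0.5 * (H + H.T)


@dataclass
class NormalModes:
    """Eigenvalue classification of a stationary point (unit masses)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    n_negative: int
    n_zero: int

    @property
    def index(self) -> int:
        """Saddle index: number of negative (non-zero-mode) eigenvalues."""
        return self.n_negative

    @property
    def positive_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > ZERO_MODE_TOL]

    @property
    def log_freq_product(self) -> float:
        """Sum of log angular frequencies over positive modes (unit mass)."""
        return float(0.5 * np.sum(np.log(self.positive_eigenvalues)))

    @property
    def kappa(self) -> int:
        """Number of vibrational (positive-eigenvalue) degrees of freedom."""
        return int(np.sum(self.eigenvalues > ZERO_MODE_TOL))

    @property
    def lowest_vector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def normal_modes(pot: Potential, x: np.ndarray, step: float = 1e-5) -> NormalModes:
    H = hessian(pot, x, step)
    vals, vecs = np.linalg.eigh(H)
    n_neg = int(np.sum(vals < -ZERO_MODE_TOL))
    n_zero = int(np.sum(np.abs(vals) <= ZERO_MODE_TOL))
    return NormalModes(vals, vecs, n_neg, n_zero)
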