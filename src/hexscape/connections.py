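"""Transition-state searches and stationary-point database growth.

The pipeline mirrors discrete path sampling practice: candidate saddles
between a pair of minima are generated with a doubly nudged elastic band
(:func:`dneb`), refined to true index-1 saddles with hybrid
eigenvector-following (:func:`hybrid_ef_refine`), and each refined saddle
is connected to its two minima by steepest-descent quenches started either
side of the reaction mode (:func:`descend_both_sides`), giving a
minimum-transition state-minimum triple.  :func:`select_next_pair` picks
which unconnected pair to attempt next from a Dijkstra shortest-gap
analysis, and :func:`grow_database` drives the whole loop.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .database import MinimumRecord, StationaryPointDatabase, TransitionStateRecord
from .minimize import ZERO_MODE_TOL, minimize, normal_modes, rms
from .geometry import aligned_rmsd
from .potentials import Potential, PotentialError

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectionError_",
    "SaddleClassificationError",
    "ConnectionAttempt",
    "dneb",
    "hybrid_ef_refine",
    "descend_both_sides",
    "select_next_pair",
    "grow_database",
    "FullyConnected",
    "PairsExhausted",
]


class ConnectionError_(RuntimeError):
    """A connection-pipeline step failed."""


class SaddleClassificationError(ConnectionError_):
    """Refinement converged to something other than an index-1 saddle."""


class FullyConnected(Exception):
    """Source and sink already lie in the same connected component."""


class PairsExhausted(Exception):
    """No remaining candidate pair with finite weight."""


@dataclass
class ConnectionAttempt:
    pair: tuple[int, int]
    status: str = "pending"  # pending -> connected | failed
    n_images: int = 0
    ts_ids: list[int] = field(default_factory=list)

    def mark(self, status: str) -> None:
        if self.status != "pending":
            raise ConnectionError_("attempt status transitions are monotone")
        if status not in ("connected", "failed"):
            raise ConnectionError_(f"bad status {status!r}")
        self.status = status


def _upwind_tangent(e_prev: float, e_i: float, e_next: float,
                    d_prev: np.ndarray, d_next: np.ndarray) -> np.ndarray:
    """Henkelman-Jonsson upwind tangent estimate for band image i."""
    if e_next > e_i > e_prev:
        tau = d_next
    elif e_next < e_i < e_prev:
        tau = d_prev
    else:
        dmax = max(abs(e_next - e_i), abs(e_prev - e_i))
        dmin = min(abs(e_next - e_i), abs(e_prev - e_i))
        if e_next >= e_prev:
            tau = dmax * d_next + dmin * d_prev
        else:
            tau = dmin * d_next + dmax * d_prev
    norm = np.linalg.norm(tau)
    return tau / norm if norm > 0 else tau


def dneb(
    pot: Potential,
    min_a: np.ndarray,
    min_b: np.ndarray,
    n_images: int = 11,
    k_spring: float = 1.0,
    max_iter: int = 2000,
    rms_tol: float = 1e-3,
) -> list[np.ndarray]:
    """Relax a doubly nudged elastic band between two minima.

    Returns the interior images that are local maxima of energy along the
    relaxed band, ordered along the path -- the candidate transition states.
    A band that fails to relax within ``max_iter`` still returns its current
    maxima (best-effort, logged as low-confidence).
    """
    if n_images < 3:
        raise PotentialError("need at least 3 images")
    a = np.asarray(min_a, dtype=float).ravel()
    b = np.asarray(min_b, dtype=float).ravel()
    if np.linalg.norm(a - b) < 1e-8:
        return []
    # interior images by linear interpolation
    ts = np.linspace(0.0, 1.0, n_images)
    band = np.array([a + t * (b - a) for t in ts])

    n_int = n_images - 2
    # FIRE relaxation of the band under the doubly nudged force
    v = np.zeros((n_int, a.size))
    dt, dt_max, alpha, n_pos = 0.002, 0.01, 0.1, 0
    converged = False
    for _ in range(max_iter):
        energies = np.array([pot.energy(im) for im in band])
        forces = np.zeros((n_int, a.size))
        for k in range(n_int):
            i = k + 1
            d_prev = band[i] - band[i - 1]
            d_next = band[i + 1] - band[i]
            tau = _upwind_tangent(energies[i - 1], energies[i], energies[i + 1],
                                  d_prev, d_next)
            g = pot.gradient(band[i])
            g_perp = g - (g @ tau) * tau
            # spring force: parallel part plus the doubly nudged perpendicular
            # portion projected off the true-gradient direction
            f_spring = k_spring * (d_next - d_prev)
            f_par = (f_spring @ tau) * tau
            f_sp_perp = f_spring - f_par
            g_perp_norm = np.linalg.norm(g_perp)
            if g_perp_norm > 1e-12:
                g_hat = g_perp / g_perp_norm
                f_dneb = f_sp_perp - (f_sp_perp @ g_hat) * g_hat
            else:
                f_dneb = f_sp_perp
            forces[k] = -g_perp + f_par + f_dneb
        if rms(forces) <= rms_tol:
            converged = True
            break
        p = float(np.vdot(forces, v))
        if p > 0:
            n_pos += 1
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(forces)
            if fn > 0:
                v = (1 - alpha) * v + alpha * (forces / fn) * vn
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha, n_pos = 0.1, 0
        v = v + dt * forces
        step = dt * v
        biggest = np.max(np.abs(step))
        if biggest > 0.05:
            step *= 0.05 / biggest
        band[1:-1] += step
    if not converged:
        logger.warning("DNEB band did not converge; candidates are low-confidence")

    energies = np.array([pot.energy(im) for im in band])
    candidates = [
        band[i].copy()
        for i in range(1, n_images - 1)
        if energies[i] > energies[i - 1] and energies[i] > energies[i + 1]
    ]
    return candidates


def hybrid_ef_refine(
    pot: Potential,
    candidate: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 200,
    trust_radius: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Refine a candidate to an index-1 saddle by hybrid eigenvector-following.

    Steps uphill along the lowest Hessian eigenvector while minimising in the
    orthogonal complement (via a Newton step with the reaction-mode component
    sign-reversed).  Returns ``(coordinates, energy)``.

    Raises :class:`SaddleClassificationError` when the walk converges to a
    minimum or a higher-index saddle.
    """
    x = np.asarray(candidate, dtype=float).ravel()
    for _ in range(max_iter):
        g = pot.gradient(x)
        modes = normal_modes(pot, x)
        vals, vecs = modes.eigenvalues, modes.eigenvectors
        if rms(g) <= tol:
            if modes.index == 1:
                return x, pot.energy(x)
            kind = "minimum" if modes.index == 0 else f"index-{modes.index} saddle"
            raise SaddleClassificationError(f"converged to a {kind}")
        proj = vecs.T @ g
        step_vec = np.zeros_like(x)
        lowest = None
        for i, lam in enumerate(vals):
            if abs(lam) <= ZERO_MODE_TOL:
                continue
            if lowest is None:
                lowest = i
                # uphill along the softest non-zero mode
                denom = abs(lam) if abs(lam) > 1e-4 else 1e-4
                step_vec += (proj[i] / denom) * vecs[:, i]
            else:
                step_vec -= (proj[i] / lam) * vecs[:, i]
        norm = np.linalg.norm(step_vec)
        if norm > trust_radius:
            step_vec *= trust_radius / norm
        x = x + step_vec
    raise SaddleClassificationError("hybrid EF walk did not converge")


def descend_both_sides(
    pot: Potential,
    ts_coords: np.ndarray,
    displacement: float = 1e-3,
    rms_tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Quench from +/- ``displacement`` along the reaction mode of a saddle.

    Returns the two connected minima (which may coincide for a degenerate
    rearrangement; callers compare them).
    """
    if displacement == 0:
        raise PotentialError("displacement must be nonzero to break symmetry")
    x = np.asarray(ts_coords, dtype=float).ravel()
    modes = normal_modes(pot, x)
    if modes.index != 1:
        raise SaddleClassificationError(
            f"descend_both_sides requires an index-1 saddle, got index {modes.index}"
        )
    v = modes.lowest_vector
    minima = []
    for sign in (+1.0, -1.0):
        res = minimize(pot, x + sign * displacement * v, rms_tol=rms_tol)
        if not res.converged:
            raise ConnectionError_("descent from saddle failed to converge")
        minima.append(res.x)
    return minima[0], minima[1]


def _pair_weight(db: StationaryPointDatabase, i: int, j: int) -> float:
    """Dijkstra edge weight: 0 for TS-connected pairs, else squared
    best-aligned RMSD of the minima's coordinates."""
    xi = db.coordinates_of(i)
    xj = db.coordinates_of(j)
    d = aligned_rmsd(xi, xj, db.ndim)
    return d * d


def select_next_pair(
    db: StationaryPointDatabase,
    source_id: int,
    sink_id: int,
    attempt_history: list[ConnectionAttempt] | None = None,
) -> tuple[int, int]:
    """Choose the next unconnected pair to attempt.

    Builds the complete graph on minima where TS-connected pairs have weight
    zero and unconnected pairs a weight growing with structural distance
    (squared best-aligned RMSD), finds the minimum-weight source-sink path,
    and returns its first unconnected pair.  Pairs that already failed get
    infinite weight.

    Raises :class:`FullyConnected` if source and sink are connected, and
    :class:`PairsExhausted` if no finite-weight path remains.
    """
    if source_id not in db.minima_ids or sink_id not in db.minima_ids:
        raise PotentialError("source and sink must be database minima")
    failed = {
        frozenset(a.pair) for a in (attempt_history or []) if a.status == "failed"
    }
    connected = {
        frozenset((ts.min1_id, ts.min2_id))
        for ts in db.transition_states
        if ts.min1_id != ts.min2_id
    }
    g = nx.Graph()
    g.add_nodes_from(db.minima_ids)
    for i, j in itertools.combinations(db.minima_ids, 2):
        key = frozenset((i, j))
        if key in connected:
            g.add_edge(i, j, weight=0.0, gap=False)
        elif key not in failed:
            g.add_edge(i, j, weight=_pair_weight(db, i, j), gap=True)
    try:
        path = nx.dijkstra_path(g, source_id, sink_id)
    except nx.NetworkXNoPath:
        raise PairsExhausted("no finite-weight path between source and sink")
    gaps = [
        (a, b) for a, b in zip(path[:-1], path[1:]) if g.edges[a, b]["gap"]
    ]
    if not gaps:
        raise FullyConnected(f"{source_id} and {sink_id} are already connected")
    return gaps[0]


def grow_database(
    pot: Potential,
    initial_minima: list[np.ndarray],
    budget: int = 50,
    source: int = 0,
    sink: int = 1,
    n_images: int = 11,
    k_spring: float = 1.0,
    ts_tol: float = 1e-7,
    min_tol: float = 1e-7,
) -> StationaryPointDatabase:
    """Grow a connected stationary-point database from initial minima.

    Iterates select-pair -> DNEB -> hybrid EF -> two-sided descent until the
    source-sink pair is connected or the attempt budget is spent.  Individual
    attempt failures are logged and the loop continues.
    """
    if len(initial_minima) < 2:
        raise PotentialError("need at least 2 initial minima")
    db = StationaryPointDatabase(ndim=pot.ndim)
    for x in initial_minima:
        res = minimize(pot, x, rms_tol=min_tol)
        if not res.converged:
            raise ConnectionError_("initial minimum failed to converge")
        modes = normal_modes(pot, res.x)
        db.add_minimum_checked(res.energy, res.x, modes)
    history: list[ConnectionAttempt] = []
    for _ in range(budget):
        try:
            pair = select_next_pair(db, source, sink, history)
        except FullyConnected:
            break
        except PairsExhausted:
            logger.warning("candidate pairs exhausted before connection")
            break
        attempt = ConnectionAttempt(pair)
        history.append(attempt)
        found_any = False
        try:
            candidates = dneb(
                pot, db.coordinates_of(pair[0]), db.coordinates_of(pair[1]),
                n_images=n_images, k_spring=k_spring,
            )
            for cand in candidates:
                try:
                    x_ts, e_ts = hybrid_ef_refine(pot, cand, tol=ts_tol)
                    x1, x2 = descend_both_sides(pot, x_ts, rms_tol=min_tol)
                except (SaddleClassificationError, ConnectionError_) as exc:
                    logger.info("candidate discarded: %s", exc)
                    continue
                m1 = db.add_minimum_checked(
                    pot.energy(x1), x1, normal_modes(pot, x1)
                )
                m2 = db.add_minimum_checked(
                    pot.energy(x2), x2, normal_modes(pot, x2)
                )
                modes_ts = normal_modes(pot, x_ts)
                ts_id = db.add_transition_state_checked(e_ts, x_ts, m1, m2, modes_ts)
                if ts_id is not None:
                    attempt.ts_ids.append(ts_id)
                    found_any = True
        except PotentialError as exc:
            logger.info("attempt on pair %s failed: %s", pair, exc)
        attempt.mark("connected" if found_any else "failed")
    return db
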