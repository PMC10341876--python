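"""Harmonic superposition thermodynamics and heat-capacity feature analysis.

The total partition function is approximated as the sum of classical
harmonic partition functions of all catalogued minima.  With kBT written as
``T`` (the temperature axis is always an energy), minimum ``a`` with energy
``E_a``, degeneracy ``n_a``, log-frequency-product ``L_a`` and ``kappa``
vibrational degrees of freedom contributes

    ln w_a(T) = ln n_a - E_a / T + kappa * ln T - L_a

up to additive constants common to all minima.  Occupation probabilities
are ``p_a = w_a / sum_b w_b`` (evaluated in the log domain), the mean energy
is ``<E> = kappa * T + sum_a p_a E_a`` and the heat capacity in units of kB
is

    CV / kB = kappa + (<E^2> - <E>^2) / T^2

with the variance taken over the minima energies under ``p_a``.  The
low-temperature features of CV(T) -- peaks and inflection points -- signal
competition between structurally distinct low-energy minima; the analysis
here locates them, applies the first-feature-above-threshold rule, and
decomposes each feature into the minima whose occupation probabilities grow
(positive ``dp_a/dT``) or drain (negative) across it, keeping the smallest
sets that cover a configured fraction (default 98%) of each sign group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .database import DatabaseError, StationaryPointDatabase

__all__ = [
    "TemperatureGrid",
    "ThermoCurve",
    "FeatureConfig",
    "FeatureReport",
    "ContributionSet",
    "log_weight",
    "log_weights",
    "occupation_probabilities",
    "occupation_derivatives",
    "heat_capacity_curve",
    "detect_features",
    "feature_contributions",
    "first_feature_temperature",
]


def temperature_grid(kbt_min: float, kbt_max: float, n: int, log_spaced: bool = True) -> np.ndarray:
    """Strictly increasing grid of kBT values (log-spaced by default)."""
    if not (0 < kbt_min < kbt_max) or n < 2:
        raise DatabaseError("grid needs 0 < kbt_min < kbt_max and n >= 2")
    if log_spaced:
        return np.geomspace(kbt_min, kbt_max, n)
    return np.linspace(kbt_min, kbt_max, n)


#: alias kept for symmetry with the container types
TemperatureGrid = temperature_grid


@dataclass
class ThermoCurve:
    """CV(T), mean energy and occupation probabilities on a kBT grid."""

    grid: np.ndarray
    cv: np.ndarray  # units of kB, includes the kinetic kappa offset
    mean_energy: np.ndarray
    occupations: np.ndarray  # shape (n_T, n_minima)
    kappa: int
    minima_ids: list[int]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-selection thresholds.

    ``threshold_low`` and ``threshold_high`` bound the kBT window of
    interest (protocol values 0.086 and 0.300; the alternative low cut
    0.076 is used for propensity correlations); ``coverage`` is the
    per-sign-group fraction of |dp/dT| a contribution set must cover.
    """

    threshold_low: float = 0.086
    threshold_high: float = 0.300
    coverage: float = 0.98
    exclude_melting: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold_low < self.threshold_high:
            raise DatabaseError("require 0 < threshold_low < threshold_high")
        if not 0 < self.coverage <= 1:
            raise DatabaseError("coverage must be in (0, 1]")


@dataclass
class ContributionSet:
    members: list[tuple[int, float]]  # (minimum id, dp_a/dT)
    achieved_coverage: float


@dataclass
class FeatureReport:
    kind: str  # "peak" | "inflection"
    kbt_location: float
    grid_index: int
    is_melting: bool = False
    positive_set: ContributionSet | None = None
    negative_set: ContributionSet | None = None


def _db_arrays(db: StationaryPointDatabase) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    if not db.minima:
        raise DatabaseError("empty database")
    if db.kappa is None or db.kappa < 1:
        raise DatabaseError("database kappa must be set and >= 1")
    e = np.array([m.energy for m in db.minima])
    lfp = np.array([m.log_freq_product for m in db.minima])
    ln_n = np.log(np.array([m.degeneracy for m in db.minima]))
    return e, lfp, ln_n, int(db.kappa)


def log_weight(energy: float, log_freq_product: float, degeneracy: float,
               kappa: int, kbt: float) -> float:
    """ln w_a for one minimum at one temperature (additive constants dropped)."""
    if kbt <= 0:
        raise DatabaseError("kBT must be positive")
    return float(np.log(degeneracy) - energy / kbt + kappa * np.log(kbt) - log_freq_product)


def log_weights(db: StationaryPointDatabase, kbt: np.ndarray | float) -> np.ndarray:
    """Matrix of ln w_a: shape (n_T, n_minima) (or (n_minima,) for scalar kbt)."""
    e, lfp, ln_n, kappa = _db_arrays(db)
    t = np.atleast_1d(np.asarray(kbt, dtype=float))
    if np.any(t <= 0):
        raise DatabaseError("kBT must be positive")
    lw = ln_n[None, :] - e[None, :] / t[:, None] + kappa * np.log(t)[:, None] - lfp[None, :]
    return lw[0] if np.isscalar(kbt) or np.ndim(kbt) == 0 else lw


def occupation_probabilities(db: StationaryPointDatabase, kbt: float | np.ndarray) -> np.ndarray:
    """p_a = w_a / sum_b w_b via log-sum-exp; rows sum to one."""
    lw = np.atleast_2d(log_weights(db, np.atleast_1d(kbt)))
    p = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    return p[0] if np.ndim(kbt) == 0 else p


def occupation_derivatives(db: StationaryPointDatabase, kbt: float) -> np.ndarray:
    """dp_a/dT at one temperature (T = kBT in energy units).

    Only the configurational energies enter: dp_a/dT = p_a (E_a - <E>_c) / T^2
    with <E>_c = sum p_a E_a; the derivatives sum to zero exactly.
    """
    e, *_ = _db_arrays(db)
    p = occupation_probabilities(db, float(kbt))
    # twice-compensated mean so the derivatives sum to zero to ~1e-16
    # even after the 1/T^2 amplification at low temperature
    resid = e - float(p @ e)
    resid -= float(p @ resid)
    return p * resid / float(kbt) ** 2


def heat_capacity_curve(db: StationaryPointDatabase, grid: np.ndarray) -> ThermoCurve:
    """Heat capacity, mean energy and occupations on a kBT grid.

    CV/kB = kappa + Var_p(E) / T^2; the mean energy includes the harmonic
    kinetic-plus-vibrational term kappa * T.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
        raise DatabaseError("grid must be strictly increasing and positive")
    e, _, _, kappa = _db_arrays(db)
    p = np.atleast_2d(occupation_probabilities(db, grid))
    mean_e_conf = p @ e
    var_e = p @ (e**2) - mean_e_conf**2
    cv = kappa + var_e / grid**2
    mean_energy = kappa * grid + mean_e_conf
    return ThermoCurve(grid, cv, mean_energy, p, kappa, db.minima_ids)


def log_partition_function(db: StationaryPointDatabase, kbt: np.ndarray) -> np.ndarray:
    """ln Z(T) up to additive constants; the finite-difference oracle target."""
    lw = np.atleast_2d(log_weights(db, np.atleast_1d(kbt)))
    return logsumexp(lw, axis=1)


def _peak_indices(y: np.ndarray, prominence_floor: float) -> list[int]:
    idx = [
        i for i in range(1, len(y) - 1)
        if y[i] > y[i - 1] and y[i] >= y[i + 1]
    ]
    if not idx:
        return idx
    # suppress numerical ripple: require the local maximum to stand above the
    # higher of the two flanking local minima by the prominence floor
    kept = []
    for i in idx:
        j = i
        while j > 0 and y[j - 1] < y[j]:
            j -= 1
        k = i
        while k < len(y) - 1 and y[k + 1] < y[k]:
            k += 1
        prom = y[i] - max(y[j], y[k])
        if prom >= prominence_floor:
            kept.append(i)
    return kept


def detect_features(curve: ThermoCurve, cfg: FeatureConfig) -> list[FeatureReport]:
    """Locate CV features (peaks and inflection points), apply the
    first-above-threshold rule, and optionally drop the melting peak.

    Peaks are interior local maxima of CV; inflections interior local maxima
    of dCV/d(kBT) not adjacent to a detected peak.  Features below
    ``threshold_low`` are discarded.  With ``exclude_melting`` the
    highest-kBT peak (the global unfolding maximum; the grid must extend
    beyond it) is removed.  Features are returned in ascending kBT.
    """
    t = curve.grid
    cv = curve.cv
    if len(t) < 3:
        return []
    floor = 1e-3 * float(np.max(cv))
    peak_idx = _peak_indices(cv, floor)
    slope = np.gradient(cv, t)
    infl_idx = [
        i for i in _peak_indices(slope, 1e-3 * float(np.max(np.abs(slope))))
        if not any(abs(i - j) <= 1 for j in peak_idx)
    ]
    features = [FeatureReport("peak", float(t[i]), i) for i in peak_idx]
    features += [FeatureReport("inflection", float(t[i]), i) for i in infl_idx]
    features.sort(key=lambda f: f.kbt_location)
    if cfg.exclude_melting:
        peaks = [f for f in features if f.kind == "peak"]
        if peaks:
            melting = peaks[-1]
            melting.is_melting = True
            features = [f for f in features if f is not melting]
    return [f for f in features if f.kbt_location > cfg.threshold_low]


def feature_contributions(
    db: StationaryPointDatabase, feature: FeatureReport, cfg: FeatureConfig
) -> FeatureReport:
    """Populate a feature's positive and negative contribution sets.

    At the feature temperature the minima are split by the sign of dp_a/dT;
    within each group, sorted by |dp_a/dT| descending (ties to the lower id),
    the shortest prefix whose summed magnitude reaches ``coverage`` times the
    group total is kept.
    """
    dp = occupation_derivatives(db, feature.kbt_location)
    ids = np.array(db.minima_ids)
    sets = {}
    for sign in (+1, -1):
        mask = (dp > 0) if sign > 0 else (dp < 0)
        group_ids = ids[mask]
        group_dp = dp[mask]
        order = np.lexsort((group_ids, -np.abs(group_dp)))
        total = float(np.sum(np.abs(group_dp)))
        members: list[tuple[int, float]] = []
        run = 0.0
        for k in order:
            if total > 0 and run >= cfg.coverage * total:
                break
            members.append((int(group_ids[k]), float(group_dp[k])))
            run += abs(float(group_dp[k]))
        sets[sign] = ContributionSet(members, run / total if total > 0 else 1.0)
    feature.positive_set = sets[+1]
    feature.negative_set = sets[-1]
    return feature


def first_feature_temperature(
    db: StationaryPointDatabase, grid: np.ndarray, cfg: FeatureConfig
) -> float | None:
    """kBT of the first non-melting feature inside the configured window,
    or None when no such feature exists (e.g. a melting-only landscape)."""
    curve = heat_capacity_curve(db, grid)
    for f in detect_features(curve, cfg):
        if cfg.threshold_low < f.kbt_location < cfg.threshold_high:
            return f.kbt_location
    return None
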