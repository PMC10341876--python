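"""Synthetic landscapes and conformers with designed statistical structure.

Real hexapeptide landscapes are multi-funnel: groups of low-lying minima
(funnels) whose bottoms differ in energy and vibrational entropy, separated
by barriers much larger than the intra-funnel ones.  The competition
between two such funnels produces a low-temperature heat-capacity peak at a
temperature set by the energy gap and the entropy difference.  The
generators here build stationary-point databases with exactly that
structure -- including solving for the inter-funnel gap that places the
low-temperature peak at a requested kBT -- plus toy conformer coordinate
sets spanning the hairpin / helical / extended families, so the entire
downstream analysis is testable without any external data.

All outputs are reproducible bit-for-bit from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .database import DatabaseError, StationaryPointDatabase
from .descriptors import SiteSelection, dihedral, end_to_end, interstrand_separation
from .hsa import heat_capacity_curve, temperature_grid

__all__ = [
    "FunnelSpec",
    "ConformerFamilySpec",
    "generate_funnel_db",
    "generate_conformers",
    "generate_dimer_configs",
    "CONFORMER_FAMILIES",
]

CONFORMER_FAMILIES = ("hairpin", "helical", "extended")


@dataclass(frozen=True)
class FunnelSpec:
    """Design parameters of a multi-funnel stationary-point database.

    Per-funnel sequences (one entry per funnel): ``bottom_energies``,
    ``spreads`` (scale of the exponential intra-funnel energy ladder),
    ``minima_counts`` and ``lfp_offsets`` (a constant added to every
    log-frequency-product in the funnel; a *negative* offset makes the
    funnel vibrationally entropic, favouring it at high temperature).

    ``barrier`` is the inter-funnel barrier height above the higher of the
    two connected bottoms; intra-funnel barriers are a fixed fraction of it.
    When ``target_feature_kbt`` is set the bottom energy of every funnel
    after the first is shifted by a common offset solved so that the first
    low-temperature CV peak of the assembled database lands on the target;
    the manifest records the solved gap.
    """

    n_funnels: int = 2
    bottom_energies: tuple[float, ...] = (0.0, 0.3)
    spreads: tuple[float, ...] = (0.05, 0.05)
    minima_counts: tuple[int, ...] = (10, 10)
    lfp_offsets: tuple[float, ...] = (0.0, -3.0)
    barrier: float = 6.0
    kappa: int = 12
    seed: int = 0
    target_feature_kbt: float | None = None
    # the high-energy, vibrationally entropic band that produces the
    # high-temperature melting peak (attached to the first funnel)
    melting_band: bool = True
    band_energy: float = 3.0
    band_count: int = 5
    band_lfp_offset: float = -5.0
    # toy conformer coordinates per minimum: funnel f draws jittered samples
    # of conformer family f mod 3 (hairpin, helical, extended); the melting
    # band is extended.  Lets the descriptor stage run on generated databases.
    attach_conformers: bool = True
    chain_length: int = 12
    conformer_jitter: float = 0.05

    def __post_init__(self) -> None:
        seqs = (self.bottom_energies, self.spreads, self.minima_counts, self.lfp_offsets)
        if any(len(s) != self.n_funnels for s in seqs):
            raise DatabaseError("per-funnel sequences must have n_funnels entries")
        if any(c < 1 for c in self.minima_counts):
            raise DatabaseError("each funnel needs at least one minimum")
        if self.kappa < 1:
            raise DatabaseError("kappa must be >= 1")
        if self.barrier <= 0:
            raise DatabaseError("inter-funnel barrier must be positive")
        if any(s < 0 for s in self.spreads):
            raise DatabaseError("spreads must be non-negative")


def _assemble(spec: FunnelSpec, ladders: list[np.ndarray], gap_shift: float) -> StationaryPointDatabase:
    """Build the database from pre-drawn intra-funnel ladders."""
    db = StationaryPointDatabase(kappa=spec.kappa)
    db.metadata["generator"] = "funnels"
    bottoms = []
    funnel_first_id = []
    for f in range(spec.n_funnels):
        bottom = spec.bottom_energies[f] + (gap_shift if f > 0 else 0.0)
        bottoms.append(bottom)
        ids = []
        for de in ladders[f]:
            ids.append(
                db.add_minimum(bottom + de, log_freq_product=spec.lfp_offsets[f])
            )
        funnel_first_id.append(ids[0])
        # intra-funnel connectivity: every minimum to the funnel bottom, with
        # barriers well below the inter-funnel one
        intra_barrier = 0.25 * spec.barrier
        for mid in ids[1:]:
            e_ts = max(db.minima[mid].energy, db.minima[ids[0]].energy) + intra_barrier
            lfp = 0.5 * (
                db.minima[mid].log_freq_product + db.minima[ids[0]].log_freq_product
            ) - 0.5
            db.add_transition_state(e_ts, ids[0], mid, log_freq_product=lfp)
    # inter-funnel connectivity through the funnel bottoms
    for f in range(spec.n_funnels - 1):
        a, b = funnel_first_id[f], funnel_first_id[f + 1]
        e_ts = max(bottoms[f], bottoms[f + 1]) + spec.barrier
        if e_ts <= max(db.minima[a].energy, db.minima[b].energy):
            raise DatabaseError("inter-funnel barrier below a connected minimum")
        lfp = 0.5 * (db.minima[a].log_freq_product + db.minima[b].log_freq_product) - 0.5
        db.add_transition_state(e_ts, a, b, log_freq_product=lfp)
    # melting band: high-energy, very entropic minima above the first funnel
    if spec.melting_band:
        root = funnel_first_id[0]
        e_band = bottoms[0] + spec.band_energy
        for _ in range(spec.band_count):
            mid = db.add_minimum(
                e_band, log_freq_product=spec.lfp_offsets[0] + spec.band_lfp_offset
            )
            db.add_transition_state(
                e_band + 0.25 * spec.barrier, root, mid,
                log_freq_product=spec.lfp_offsets[0] - 0.5,
            )
    return db


def _funnel_slices(spec: FunnelSpec) -> list[slice]:
    first = np.cumsum([0] + list(spec.minima_counts))
    return [slice(int(first[f]), int(first[f + 1])) for f in range(spec.n_funnels)]


def _peak_near(db: StationaryPointDatabase, target: float) -> float | None:
    """Dense-scan CV peak inside the window [0.4, 2.5] x target, if any."""
    grid = temperature_grid(0.4 * target, 2.5 * target, 3000)
    cv = heat_capacity_curve(db, grid).cv
    floor = 1e-4 * float(np.max(cv))
    best = None
    for i in range(1, len(cv) - 1):
        if cv[i] > cv[i - 1] and cv[i] >= cv[i + 1] and cv[i] - cv[: i + 1].min() >= floor:
            if best is None or abs(grid[i] - target) < abs(best - target):
                best = float(grid[i])
    return best


def _crossover_kbt(db: StationaryPointDatabase, spec: FunnelSpec) -> float | None:
    """Temperature at which the two lowest funnels' total weights cross."""
    from scipy.special import logsumexp

    from .hsa import log_weights

    sl = _funnel_slices(spec)

    def imbalance(t: float) -> float:
        lw = log_weights(db, np.array([t]))[0]
        return float(logsumexp(lw[sl[1]]) - logsumexp(lw[sl[0]]))

    lo, hi = 1e-3, 5.0
    if imbalance(lo) * imbalance(hi) > 0:
        return None
    return float(scipy.optimize.brentq(imbalance, lo, hi, xtol=1e-8))


def generate_funnel_db(spec: FunnelSpec) -> tuple[StationaryPointDatabase, dict]:
    """Generate a multi-funnel database plus a manifest of design truth.

    With ``target_feature_kbt`` set, the bottoms of all funnels after the
    first are shifted by a common solved offset so the funnel-competition CV
    peak lands on the target; the melting band guarantees a separate
    higher-temperature peak so the designed one is not the melting maximum.
    """
    rng = np.random.default_rng(spec.seed)
    ladders = []
    for f in range(spec.n_funnels):
        count = spec.minima_counts[f]
        de = np.zeros(count)
        if count > 1 and spec.spreads[f] > 0:
            de[1:] = np.sort(rng.exponential(spec.spreads[f], size=count - 1))
        ladders.append(de)

    gap_shift = 0.0
    if spec.target_feature_kbt is not None:
        if spec.n_funnels < 2:
            raise DatabaseError("a target feature temperature needs >= 2 funnels")
        target = spec.target_feature_kbt

        def objective(shift: float) -> float:
            db = _assemble(spec, ladders, shift)
            peak = _peak_near(db, target)
            if peak is None:
                # peak not resolved in the window; fall back to the funnel
                # weight crossover, which tracks the peak monotonically
                peak = _crossover_kbt(db, spec)
            if peak is None:
                return -target  # no crossover yet: gap clearly too small
            return peak - target

        shifts = np.geomspace(1e-3, 8.0, 30)
        values = [objective(s) for s in shifts]
        bracket = None
        for k in range(len(shifts) - 1):
            if values[k] == 0.0:
                bracket = (shifts[k], shifts[k])
                break
            if values[k] * values[k + 1] < 0:
                bracket = (shifts[k], shifts[k + 1])
                break
        if bracket is None:
            raise DatabaseError(
                "cannot bracket the requested feature temperature; "
                "adjust spreads, entropy offsets or the target"
            )
        if bracket[0] == bracket[1]:
            gap_shift = float(bracket[0])
        else:
            gap_shift = float(scipy.optimize.brentq(objective, *bracket, xtol=1e-7))

    db = _assemble(spec, ladders, gap_shift)
    families = None
    if spec.attach_conformers:
        families = [CONFORMER_FAMILIES[f % 3] for f in range(spec.n_funnels)]
        cursor = 0
        for f in range(spec.n_funnels):
            template = _template(families[f], spec.chain_length, 1.0)
            for _ in range(spec.minima_counts[f]):
                db.minima[cursor].coordinates = (
                    template + rng.normal(0.0, spec.conformer_jitter, size=template.shape)
                ).ravel()
                cursor += 1
        band_template = _template("extended", spec.chain_length, 1.0)
        while cursor < db.n_minima:
            db.minima[cursor].coordinates = (
                band_template + rng.normal(0.0, spec.conformer_jitter, size=band_template.shape)
            ).ravel()
            cursor += 1
    violations = db.validate()
    if violations:
        raise DatabaseError(f"generated database invalid: {violations}")
    gap = (
        (spec.bottom_energies[1] + gap_shift - spec.bottom_energies[0])
        if spec.n_funnels > 1
        else None
    )
    manifest = {
        "designed_gap": gap,
        "gap_shift": gap_shift,
        "lfp_offsets": list(spec.lfp_offsets),
        "target_feature_kbt": spec.target_feature_kbt,
        "realised_first_peak_kbt": (
            _peak_near(db, spec.target_feature_kbt) if spec.target_feature_kbt else None
        ),
        "n_minima": db.n_minima,
        "n_ts": len(db.transition_states),
        "kappa": spec.kappa,
        "seed": spec.seed,
        "conformer_families": families,
    }
    return db, manifest


# ---------------------------------------------------------------------------
# conformer generators


@dataclass(frozen=True)
class ConformerFamilySpec:
    """One conformer family: a geometric template plus Gaussian site jitter.

    ``jitter`` is the per-coordinate standard deviation; the manifest's
    design descriptor values are those of the unjittered template.
    """

    family: str = "hairpin"
    n_samples: int = 100
    chain_length: int = 12
    jitter: float = 0.05
    bond_length: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CONFORMER_FAMILIES:
            raise DatabaseError(f"unknown family {self.family!r}")
        if self.chain_length < 6:
            raise DatabaseError("chain length must be >= 6 sites")
        if self.jitter < 0 or self.n_samples < 1:
            raise DatabaseError("jitter must be >= 0 and n_samples >= 1")


def _template(family: str, n: int, b: float) -> np.ndarray:
    """Unjittered template coordinates for one family, (n, 3)."""
    if family == "extended":
        # planar zigzag, all-trans: dihedral exactly 180, maximal end-to-end
        pos = np.zeros((n, 3))
        half = 0.25 * b
        for i in range(n):
            pos[i] = (i * b * 0.93, half * (-1) ** i, 0.0)
        return pos
    if family == "helical":
        # right-handed helix: ~3.6 sites/turn, positive twist
        omega = 2 * np.pi / 3.6
        radius = 0.95 * b
        rise = 0.55 * b
        i = np.arange(n)
        return np.stack(
            [radius * np.cos(omega * i), radius * np.sin(omega * i), rise * i], axis=1
        )
    # hairpin: two antiparallel arms joined by a turn, slight out-of-plane
    # pucker so the torsion is small but well defined
    half = n // 2
    pos = np.zeros((n, 3))
    for i in range(half):
        pos[i] = (i * b, 0.0, 0.02 * b * i)
    sep = 1.1 * b
    for j in range(n - half):
        i = half + j
        pos[i] = ((half - 1 - j) * b, sep, 0.02 * b * (half - 1 - j) + 0.15 * b)
    return pos


def generate_conformers(spec: ConformerFamilySpec) -> tuple[list[np.ndarray], pd.DataFrame, dict]:
    """Sample jittered conformers; returns (coords list, truth table, manifest).

    The truth table lists each sample's exact end-to-end distance and
    dihedral under the standard chain site mapping; the manifest records the
    template's design values.
    """
    rng = np.random.default_rng(spec.seed)
    template = _template(spec.family, spec.chain_length, spec.bond_length)
    sel = SiteSelection.for_chain(spec.chain_length)
    coords = []
    rows = []
    for k in range(spec.n_samples):
        sample = template + rng.normal(0.0, spec.jitter, size=template.shape)
        coords.append(sample)
        rows.append(
            {
                "sample": k,
                "family": spec.family,
                "end_to_end": end_to_end(sample, sel),
                "dihedral": dihedral(sample, sel),
            }
        )
    truth = pd.DataFrame(rows)
    manifest = {
        "family": spec.family,
        "design_end_to_end": end_to_end(template, sel),
        "design_dihedral": dihedral(template, sel),
        "jitter": spec.jitter,
        "chain_length": spec.chain_length,
        "seed": spec.seed,
    }
    return coords, truth, manifest


def generate_dimer_configs(
    spec_a: ConformerFamilySpec,
    spec_b: ConformerFamilySpec,
    separation: float,
    n_samples: int = 10,
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame, dict]:
    """Place two jittered monomers at a given centroid separation.

    Each sample draws one conformer per family, rotates each monomer by a
    uniformly random orientation, and separates the centroids by
    ``separation`` along a random direction.  The truth table carries the
    per-monomer descriptors plus the realised interstrand separation.
    """
    from scipy.spatial.transform import Rotation

    if separation <= 0:
        raise DatabaseError("separation must be positive")
    if spec_a.chain_length != spec_b.chain_length:
        raise DatabaseError("monomers must have equal chain length")
    rng = np.random.default_rng(seed)
    n = spec_a.chain_length
    sel = SiteSelection.for_chain(n)
    partition = (tuple(range(n)), tuple(range(n, 2 * n)))
    coords_a, _, _ = generate_conformers(
        ConformerFamilySpec(**{**spec_a.__dict__, "n_samples": n_samples})
    )
    coords_b, _, _ = generate_conformers(
        ConformerFamilySpec(**{**spec_b.__dict__, "n_samples": n_samples})
    )
    configs = []
    rows = []
    for k in range(n_samples):
        placed = []
        for mono, sign in ((coords_a[k], -0.5), (coords_b[k], +0.5)):
            centred = mono - mono.mean(axis=0)
            rot = Rotation.random(random_state=rng)
            placed.append(rot.apply(centred))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dimer = np.vstack(
            [placed[0] - 0.5 * separation * direction, placed[1] + 0.5 * separation * direction]
        )
        configs.append(dimer)
        rows.append(
            {
                "sample": k,
                "end_to_end_a": end_to_end(dimer[:n], sel),
                "dihedral_a": dihedral(dimer[:n], sel),
                "end_to_end_b": end_to_end(dimer[n:], sel),
                "dihedral_b": dihedral(dimer[n:], sel),
                "interstrand": interstrand_separation(dimer, partition),
            }
        )
    truth = pd.DataFrame(rows)
    manifest = {
        "families": (spec_a.family, spec_b.family),
        "separation": separation,
        "chain_length": n,
        "seed": seed,
    }
    return configs, truth, manifest
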