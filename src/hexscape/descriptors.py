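"""Conformational descriptors: end-to-end distance and four-site dihedral.

Hexapeptide conformations separate cleanly in the plane spanned by two
order parameters: the end-to-end distance (N atom of the first residue to
the C atom of the sixth) and a signed torsion over four backbone sites
(the C-alpha atoms of residues 1, 3, 4 and 6).  Small distance and small
dihedral mark hairpin-like structures, large values of both mark helical
ones, and still larger distances extended chains.  For coarse-grained
bead-chain toys the equivalent sites are mapped by fractional chain
position.  This module computes the descriptors, extracts the
correlation-plot records for feature-contributing minima, classifies
conformations by distance bins, and correlates feature temperatures with
externally supplied aggregation-propensity scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .database import DatabaseError, StationaryPointDatabase
from .hsa import FeatureReport

__all__ = [
    "SiteSelection",
    "DescriptorRecord",
    "DescriptorConfig",
    "CONFORMATION_CLASSES",
    "end_to_end",
    "dihedral",
    "correlation_data",
    "spread_statistics",
    "classify_conformation",
    "interstrand_separation",
    "feature_vs_propensity",
]

CONFORMATION_CLASSES = ("hairpin", "S_shaped", "question_mark", "W_shaped", "extended")


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSelection:
    """Atom indices for the two order parameters.

    ``end_a``/``end_b`` are the end-to-end sites; ``dihedral_sites`` the
    four ordered torsion sites.
    """

    end_a: int
    end_b: int
    dihedral_sites: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        sites = set(self.dihedral_sites)
        if len(sites) != 4:
            raise DescriptorError("dihedral sites must be four distinct indices")
        if self.end_a == self.end_b:
            raise DescriptorError("end sites must be distinct")

    @classmethod
    def for_chain(cls, n_sites: int) -> "SiteSelection":
        """Convenience mapping for bead chains: ends at beads 0 and n-1,
        torsion sites at fractional positions 0, 2/5, 3/5, 1 of the chain
        (the bead-chain analogue of residues 1, 3, 4, 6 of a hexapeptide)."""
        if n_sites < 6:
            raise DescriptorError("chain mapping needs at least 6 sites")
        last = n_sites - 1
        sites = (0, round(2 * last / 5), round(3 * last / 5), last)
        return cls(0, last, sites)


@dataclass
class DescriptorRecord:
    minimum_id: int
    end_to_end: float
    dihedral: float  # degrees, (-180, 180]
    relative_energy: float
    contributes_to_feature: bool


@dataclass(frozen=True)
class DescriptorConfig:
    """``energy_window`` restricts records to minima within that energy of
    the global minimum (protocol value 2.6 for dimers); ``None`` disables."""

    energy_window: float | None = 2.6
    restrict_to_contributors: bool = True

    def __post_init__(self) -> None:
        if self.energy_window is not None and self.energy_window <= 0:
            raise DescriptorError("energy_window must be positive")


def _positions(coords: np.ndarray) -> np.ndarray:
    pos = np.asarray(coords, dtype=float)
    if pos.ndim == 1:
        pos = pos.reshape(-1, 3)
    if pos.shape[1] != 3:
        raise DescriptorError("descriptors require 3D coordinates")
    return pos


def end_to_end(coords: np.ndarray, sel: SiteSelection) -> float:
    """Euclidean distance between the two selected end sites."""
    pos = _positions(coords)
    n = pos.shape[0]
    if not (0 <= sel.end_a < n and 0 <= sel.end_b < n):
        raise DescriptorError("end site index out of range")
    return float(np.linalg.norm(pos[sel.end_a] - pos[sel.end_b]))


def dihedral(coords: np.ndarray, sel: SiteSelection) -> float:
    """Signed torsion over the four selected sites, in degrees in (-180, 180].

    Follows the IUPAC convention: looking along the middle bond, a clockwise
    rotation of the far bond relative to the near one is positive.
    """
    pos = _positions(coords)
    n = pos.shape[0]
    if any(not 0 <= i < n for i in sel.dihedral_sites):
        raise DescriptorError("dihedral site index out of range")
    p = pos[list(sel.dihedral_sites)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    b2n = np.linalg.norm(b2)
    if b2n < 1e-10:
        raise DescriptorError("middle bond has zero length; dihedral undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DescriptorError("three consecutive sites collinear; dihedral undefined")
    phi = np.degrees(np.arctan2(b2n * float(b1 @ n2), float(n1 @ n2)))
    if phi <= -180.0:
        phi += 360.0
    return float(phi)


def correlation_data(
    db: StationaryPointDatabase,
    feature: FeatureReport,
    cfg: DescriptorConfig,
    sel: SiteSelection,
    coordinates: dict[int, np.ndarray] | None = None,
) -> list[DescriptorRecord]:
    """Descriptor records for the minima behind one heat-capacity feature.

    One record per minimum in the union of the feature's positive and
    negative contribution sets (or per database minimum when
    ``restrict_to_contributors`` is off), optionally restricted to the
    energy window above the global minimum.
    """
    if feature.positive_set is None or feature.negative_set is None:
        raise DescriptorError("feature contribution sets are not populated")
    contributors = {mid for mid, _ in feature.positive_set.members}
    contributors |= {mid for mid, _ in feature.negative_set.members}
    ids = sorted(contributors) if cfg.restrict_to_contributors else db.minima_ids
    e_gm = db.global_minimum.energy if db.minima else 0.0
    records = []
    for mid in ids:
        if coordinates is not None and mid in coordinates:
            coords = coordinates[mid]
        else:
            m = db.minima[mid] if 0 <= mid < db.n_minima else None
            if m is None or m.coordinates is None:
                raise DescriptorError(f"missing coordinates for minimum {mid}")
            coords = m.coordinates
        rel = db.minima[mid].energy - e_gm
        if cfg.energy_window is not None and rel > cfg.energy_window:
            continue
        records.append(
            DescriptorRecord(
                mid,
                end_to_end(coords, sel),
                dihedral(coords, sel),
                rel,
                mid in contributors,
            )
        )
    return records


def spread_statistics(records: list[DescriptorRecord]) -> dict[str, float]:
    """Ranges and standard deviations of both descriptors -- the package's
    quantitative proxy for the visual spread of a correlation plot."""
    if not records:
        raise DescriptorError("spread statistics need at least one record")
    d = np.array([r.end_to_end for r in records])
    phi = np.array([r.dihedral for r in records])
    return {
        "distance_range": float(d.max() - d.min()),
        "dihedral_range": float(phi.max() - phi.min()),
        "distance_std": float(d.std()),
        "dihedral_std": float(phi.std()),
        "n": len(records),
    }


def classify_conformation(
    record: DescriptorRecord | float, boundaries: tuple[float, float, float, float]
) -> str:
    """Conformation class by end-to-end distance bin.

    Classes in order of increasing distance: hairpin (U-shaped), S-shaped
    (partially helical), question-mark-shaped, W-shaped (almost helical),
    extended (Z-shaped).  Bins are half-open: a distance exactly at a cut
    belongs to the upper class.
    """
    if list(boundaries) != sorted(boundaries) or len(set(boundaries)) != 4:
        raise DescriptorError("boundaries must be 4 strictly increasing cut points")
    d = record.end_to_end if isinstance(record, DescriptorRecord) else float(record)
    idx = int(np.searchsorted(np.asarray(boundaries), d, side="right"))
    return CONFORMATION_CLASSES[idx]


def interstrand_separation(
    coords: np.ndarray, partition: tuple[tuple[int, ...], tuple[int, ...]]
) -> float:
    """Minimum site-site distance between the two monomers of a dimer --
    the auxiliary descriptor separating closely packed from loosely
    associated dimers."""
    pos = _positions(coords)
    a = pos[list(partition[0])]
    b = pos[list(partition[1])]
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.min(np.einsum("ijk,ijk->ij", diff, diff))))


def feature_vs_propensity(table: pd.DataFrame) -> dict:
    """Rank-correlate first-feature temperatures with propensity scores.

    ``table`` needs columns ``sequence``, ``feature_kbt`` (NaN/None = no
    feature, excluded), ``propensity``; an optional ``group`` column (e.g.
    source protein) and boolean ``is_amyloid`` column enable the per-group
    check of whether the amyloid member shows the lowest feature
    temperature in its group.
    """
    df = pd.DataFrame(table).copy()
    for col in ("sequence", "feature_kbt", "propensity"):
        if col not in df.columns:
            raise DescriptorError(f"table must have a {col!r} column")
    excluded = df[df["feature_kbt"].isna()]["sequence"].tolist()
    usable = df.dropna(subset=["feature_kbt"])
    if len(usable) < 2:
        raise DescriptorError("need at least 2 rows with a feature temperature")
    rho, pval = scipy.stats.spearmanr(usable["feature_kbt"], usable["propensity"])
    result = {
        "rank_correlation": float(rho),
        "p_value": float(pval),
        "n_used": int(len(usable)),
        "excluded": excluded,
    }
    if "group" in df.columns and "is_amyloid" in df.columns:
        per_group = {}
        for name, sub in usable.groupby("group"):
            amy = sub[sub["is_amyloid"].astype(bool)]
            if len(amy) == 0 or len(sub) < 2:
                continue
            per_group[name] = bool(
                amy["feature_kbt"].min() <= sub["feature_kbt"].min() + 1e-12
            )
        result["amyloid_lowest_in_group"] = per_group
    return result
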