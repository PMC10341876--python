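"""Small geometric helpers shared across modules."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["aligned_rmsd"]


def aligned_rmsd(a: np.ndarray, b: np.ndarray, ndim: int) -> float:
    """Best RMSD between two flat coordinate sets after centroid shift and,
    in 3D, optimal rotation (Kabsch; no permutation matching)."""
    pa = np.asarray(a, dtype=float).reshape(-1, ndim)
    pb = np.asarray(b, dtype=float).reshape(-1, ndim)
    if pa.shape[0] > 1:
        # multi-particle systems are translation(/rotation) invariant;
        # single-particle surfaces live in an external potential, so their
        # absolute position is meaningful and must not be aligned away
        pa = pa - pa.mean(axis=0)
        pb = pb - pb.mean(axis=0)
        if ndim == 3:
            with warnings.catch_warnings():
                # near-planar/collinear structures make the optimal rotation
                # non-unique; any optimum gives the same RMSD
                warnings.simplefilter("ignore", UserWarning)
                rot, _ = Rotation.align_vectors(pa, pb)
            pb = rot.apply(pb)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
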