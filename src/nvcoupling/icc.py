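"""Intrinsic connectivity contrast: per-voxel mean squared correlation with
every other analysis voxel (a voxel-wise global-connectivity/degree measure).

Two computation paths are provided: a brute-force pairwise-correlation
reference for small instances, and a factorization-based path that never
materializes the N x N correlation matrix and must agree with the reference
to 1e-8. Self-correlation is excluded; the divisor is the number of other
valid voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import BoldImage

__all__ = ["IccResult", "compute_icc_bruteforce", "compute_icc_fast"]


@dataclass
class IccResult:
    """Per-voxel ICC values in [0, 1]; NaN outside analysis voxels."""

    icc_map: np.ndarray
    n_voxels: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _extract(bold: BoldImage, analysis_mask: np.ndarray):
    mask = np.asarray(analysis_mask) > 0
    if mask.shape != bold.shape3d:
        raise ValueError("analysis mask grid does not match BOLD grid")
    V = bold.data[mask]
    if V.shape[0] < 2:
        raise ValueError("need at least 2 analysis voxels")
    valid = V.std(axis=1) > 0  # constant series are excluded pairwise
    return mask, V, valid


def compute_icc_bruteforce(bold: BoldImage, analysis_mask: np.ndarray) -> IccResult:
    """Reference implementation via the full pairwise Pearson matrix."""
    mask, V, valid = _extract(bold, analysis_mask)
    vals = np.full(V.shape[0], np.nan)
    Vv = V[valid]
    nv = Vv.shape[0]
    if nv >= 2:
        R = np.corrcoef(Vv)
        vals[valid] = ((R * R).sum(axis=1) - 1.0) / (nv - 1)
    out = np.full(bold.shape3d, np.nan)
    out[mask] = np.clip(vals, 0.0, 1.0)
    return IccResult(out, n_voxels=int(valid.sum()), affine=bold.affine)


def compute_icc_fast(bold: BoldImage, analysis_mask: np.ndarray) -> IccResult:
    """Factorization path: with unit-norm standardized series z_i and Gram
    matrix G = Z Z', ICC_i = (||G e_i||^2 - 1)/(N - 1) = (z_i' M z_i - 1)/(N - 1)
    where M = Z'Z is only T x T — no N x N structure is ever allocated."""
    mask, V, valid = _extract(bold, analysis_mask)
    vals = np.full(V.shape[0], np.nan)
    Vv = V[valid]
    nv = Vv.shape[0]
    if nv >= 2:
        Z = Vv - Vv.mean(axis=1, keepdims=True)
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        M = Z.T @ Z  # (T, T)
        row_sq = ((Z @ M) * Z).sum(axis=1)  # z_i' M z_i = ||G e_i||^2
        vals[valid] = (row_sq - 1.0) / (nv - 1)
    out = np.full(bold.shape3d, np.nan)
    out[mask] = np.clip(vals, 0.0, 1.0)
    return IccResult(out, n_voxels=int(valid.sum()), affine=bold.affine)
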