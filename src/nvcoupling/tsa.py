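"""Per-voxel time-shift (hemodynamic lag/lead) maps against a venous reference.

Each analysis voxel is assigned the integer shift, on a +-max_lag TR grid,
at which its series best correlates with the reference. Positive shifts mean
the voxel is delayed relative to the reference (hemodynamic lag), negative
shifts that it leads. Overlap truncation is used for shifted correlations:
no circular wrapping, no zero padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import BoldImage

__all__ = ["LagResult", "lagged_pearson", "compute_lag_map", "shift_order"]


@dataclass
class LagResult:
    """Integer lag map (TR units) and the peak correlation achieved.

    Both maps are float volumes that are NaN outside the analysis voxels
    (and for voxels whose correlation is undefined at some shift).
    """

    lag_map: np.ndarray
    peak_corr: np.ndarray
    max_lag: int = 3
    tr_seconds: float = 2.32
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def lag_seconds(self) -> np.ndarray:
        return self.lag_map * self.tr_seconds

    @property
    def window_seconds(self) -> float:
        """Magnitude, in seconds, of the lag-window bound (max_lag TRs)."""
        return self.max_lag * self.tr_seconds


def lagged_pearson(x: np.ndarray, y: np.ndarray, shift: int) -> float:
    """Pearson correlation of x advanced by `shift` samples against y.

    Sign convention: if x(t) = y(t - d), i.e. x is a copy of y delayed by d
    samples, then lagged_pearson(x, y, d) == 1. Only the T - |shift|
    overlapping samples enter the correlation. Returns NaN when either
    overlap segment has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    T = x.size
    shift = int(shift)
    if abs(shift) >= T - 2:
        raise ValueError(f"|shift|={abs(shift)} too large for series of length {T}")
    if shift > 0:
        xs, ys = x[shift:], y[: T - shift]
    elif shift < 0:
        xs, ys = x[: T + shift], y[-shift:]
    else:
        xs, ys = x, y
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def shift_order(max_lag: int) -> list[int]:
    """Shift candidates ordered by the tie-break rule: smallest |lag| first,
    negative before positive at equal magnitude."""
    return sorted(range(-max_lag, max_lag + 1), key=lambda s: (abs(s), s))


def _rowwise_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector y; NaN on zero variance."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.sqrt((Xc * Xc).sum(axis=1))
    ynorm = np.sqrt((yc * yc).sum())
    denom = xnorm * ynorm
    num = Xc @ yc
    out = np.full(X.shape[0], np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0, out=out)


def compute_lag_map(
    bold: BoldImage,
    reference: np.ndarray,
    analysis_mask: np.ndarray,
    max_lag: int = 3,
) -> LagResult:
    """Assign each analysis voxel the shift maximizing its lagged correlation.

    Maximization is over the signed correlation on the 2*max_lag+1 integer
    shifts; ties break toward the smallest |lag|, then toward the negative
    lag. Voxels with an undefined correlation at any shift come out NaN in
    both maps.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 1 or reference.size != bold.n_timepoints:
        raise ValueError("reference must be a 1D series of length T")
    if np.ptp(reference) == 0:
        raise ValueError("reference series is constant")
    if max_lag < 1 or bold.n_timepoints < 2 * max_lag + 2:
        raise ValueError("need n_timepoints >= 2*max_lag + 2")

    mask = np.asarray(analysis_mask) > 0
    if mask.shape != bold.shape3d:
        raise ValueError("analysis mask grid does not match BOLD grid")
    V = bold.data[mask]  # (N, T)
    T = bold.n_timepoints

    shifts = shift_order(max_lag)
    best_r = np.full(V.shape[0], -np.inf)
    best_lag = np.zeros(V.shape[0])
    undefined = np.zeros(V.shape[0], dtype=bool)
    for s in shifts:
        if s > 0:
            r = _rowwise_corr(V[:, s:], reference[: T - s])
        elif s < 0:
            r = _rowwise_corr(V[:, : T + s], reference[-s:])
        else:
            r = _rowwise_corr(V, reference)
        undefined |= np.isnan(r)
        better = r > best_r  # strict: earlier (preferred) shifts win ties
        best_r[better] = r[better]
        best_lag[better] = s
    best_lag[undefined] = np.nan
    best_r[undefined] = np.nan

    lag_map = np.full(bold.shape3d, np.nan)
    peak_map = np.full(bold.shape3d, np.nan)
    lag_map[mask] = best_lag
    peak_map[mask] = best_r
    return LagResult(lag_map, peak_map, max_lag=max_lag,
                     tr_seconds=bold.tr_seconds, affine=bold.affine)
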