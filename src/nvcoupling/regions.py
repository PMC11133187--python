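"""Region-level dependent variables: lag/lead summaries, ICC quartile
percentages, and the four lag-connectivity conjunction indices.

All percentages are per region over the region's analysis voxels. The ICC
quartile thresholds are per subject (computed across all analysis voxels),
not per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .icc import IccResult
from .imaging import LabelAtlas
from .tsa import LagResult

__all__ = [
    "ConjunctionMasks",
    "summarize_lags",
    "icc_percentile_thresholds",
    "summarize_icc",
    "conjunction_masks",
    "summarize_conjunctions",
    "build_region_table",
    "REGION_COLUMNS",
]

REGION_COLUMNS = [
    "region",
    "mean_pos_lag",
    "mean_neg_lag",
    "pct_lag",
    "pct_lead",
    "pct_high_icc",
    "pct_low_icc",
    "pct_coupling_lowFC",
    "pct_coupling_highFC",
    "pct_uncoupling_lowFC",
    "pct_uncoupling_highFC",
    "n_voxels",
]


@dataclass
class ConjunctionMasks:
    """Four pairwise-disjoint boolean voxel masks.

    coupling_lowFC    (i)   lag > 0 and ICC below the 25th percentile
    coupling_highFC   (ii)  lag < 0 and ICC above the 75th percentile
    uncoupling_lowFC  (iii) lag < 0 and ICC below the 25th percentile
    uncoupling_highFC (iv)  lag > 0 and ICC above the 75th percentile
    """

    coupling_lowFC: np.ndarray
    coupling_highFC: np.ndarray
    uncoupling_lowFC: np.ndarray
    uncoupling_highFC: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "pct_coupling_lowFC": self.coupling_lowFC,
            "pct_coupling_highFC": self.coupling_highFC,
            "pct_uncoupling_lowFC": self.uncoupling_lowFC,
            "pct_uncoupling_highFC": self.uncoupling_highFC,
        }

    def labelled(self) -> np.ndarray:
        """Single int volume with values 1-4 for masks (i)-(iv), 0 elsewhere."""
        out = np.zeros(self.coupling_lowFC.shape, dtype=np.int16)
        for k, m in enumerate(
            [self.coupling_lowFC, self.coupling_highFC,
             self.uncoupling_lowFC, self.uncoupling_highFC], start=1
        ):
            out[m] = k
        return out


def _region_voxels(atlas: LabelAtlas):
    for label in atlas.labels:
        yield int(label), atlas.data == label


def summarize_lags(
    lag: LagResult, atlas: LabelAtlas, lag_threshold_inclusive: bool = False
) -> pd.DataFrame:
    """Per-region mean positive/negative lag and lag/lead voxel percentages.

    pct_lag counts voxels strictly beyond +1 TR (lag >= +1 TR when
    `lag_threshold_inclusive`), pct_lead symmetrically below -1 TR. Mean
    positive (negative) lag averages strictly positive (negative) voxels
    only and is NaN when the region has none.
    """
    rows = []
    for label, vox in _region_voxels(atlas):
        lags = lag.lag_map[vox]
        lags = lags[~np.isnan(lags)]
        n = lags.size
        if n == 0:
            rows.append({"region": label, "mean_pos_lag": np.nan,
                         "mean_neg_lag": np.nan, "pct_lag": np.nan,
                         "pct_lead": np.nan, "n_voxels": 0})
            continue
        pos = lags[lags > 0]
        neg = lags[lags < 0]
        if lag_threshold_inclusive:
            n_lag = (lags >= 1).sum()
            n_lead = (lags <= -1).sum()
        else:
            n_lag = (lags > 1).sum()
            n_lead = (lags < -1).sum()
        rows.append({
            "region": label,
            "mean_pos_lag": pos.mean() if pos.size else np.nan,
            "mean_neg_lag": neg.mean() if neg.size else np.nan,
            "pct_lag": 100.0 * n_lag / n,
            "pct_lead": 100.0 * n_lead / n,
            "n_voxels": n,
        })
    return pd.DataFrame(rows)


def icc_percentile_thresholds(icc: IccResult) -> tuple[float, float]:
    """25th and 75th percentiles of the subject's ICC values across all
    analysis voxels (linear interpolation between order statistics)."""
    vals = icc.icc_map[~np.isnan(icc.icc_map)]
    if vals.size < 4:
        raise ValueError(f"need >= 4 defined ICC values, got {vals.size}")
    p25, p75 = np.percentile(vals, [25, 75], method="linear")
    return float(p25), float(p75)


def summarize_icc(
    icc: IccResult, atlas: LabelAtlas, p25: float, p75: float
) -> pd.DataFrame:
    """Per-region percentage of voxels strictly above p75 / below p25."""
    rows = []
    for label, vox in _region_voxels(atlas):
        vals = icc.icc_map[vox]
        vals = vals[~np.isnan(vals)]
        n = vals.size
        rows.append({
            "region": label,
            "pct_high_icc": 100.0 * (vals > p75).sum() / n if n else np.nan,
            "pct_low_icc": 100.0 * (vals < p25).sum() / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def conjunction_masks(
    lag: LagResult, icc: IccResult, p25: float, p75: float
) -> ConjunctionMasks:
    """Overlay binary lag-sign and ICC-quartile masks into the four
    coupling/uncoupling conjunctions. Voxels with lag 0, mid-quartile ICC,
    or undefined values belong to no mask."""
    if lag.lag_map.shape != icc.icc_map.shape:
        raise GeometryError(
            f"lag grid {lag.lag_map.shape} != ICC grid {icc.icc_map.shape}"
        )
    defined_lag = ~np.isnan(lag.lag_map)
    defined_icc = ~np.isnan(icc.icc_map)
    if not np.array_equal(defined_lag, defined_icc):
        raise GeometryError("lag and ICC maps are defined on different voxel sets")
    with np.errstate(invalid="ignore"):
        pos = defined_lag & (lag.lag_map > 0)
        neg = defined_lag & (lag.lag_map < 0)
        low = defined_icc & (icc.icc_map < p25)
        high = defined_icc & (icc.icc_map > p75)
    return ConjunctionMasks(
        coupling_lowFC=pos & low,
        coupling_highFC=neg & high,
        uncoupling_lowFC=neg & low,
        uncoupling_highFC=pos & high,
    )


def summarize_conjunctions(masks: ConjunctionMasks, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-region percentage of voxels falling in each conjunction mask."""
    rows = []
    for label, vox in _region_voxels(atlas):
        n = int(vox.sum())
        row = {"region": label}
        for col, m in masks.as_dict().items():
            row[col] = 100.0 * int((m & vox).sum()) / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_region_table(
    lag: LagResult,
    icc: IccResult,
    atlas: LabelAtlas,
    lag_threshold_inclusive: bool = False,
) -> pd.DataFrame:
    """Full per-region table: lag summaries, ICC quartile percentages, and
    conjunction percentages, in the canonical column order."""
    p25, p75 = icc_percentile_thresholds(icc)
    masks = conjunction_masks(lag, icc, p25, p75)
    df = summarize_lags(lag, atlas, lag_threshold_inclusive)
    df = df.merge(summarize_icc(icc, atlas, p25, p75), on="region")
    df = df.merge(summarize_conjunctions(masks, atlas), on="region")
    return df[REGION_COLUMNS]
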