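"""Membrane-normalised ratiometric statistics at nanostructures.

Implements the end/side ratio on bars (with and without membrane
normalisation), gradient-bar grouping, pillar/membrane ratios with per-cell
normalisation, enriched-pillar classification, and the Spearman correlation
of a protein of interest with integrin enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NanocurveError
from .registration import ROISet, WindowSet

log = logging.getLogger(__name__)

__all__ = [
    "EndSideResult",
    "PillarRatioResult",
    "SpearmanResult",
    "background_level",
    "end_side_ratios",
    "direct_end_side",
    "gradient_group",
    "pillar_ratios",
    "classify_enriched",
    "spearman",
    "spearman_at_pillars",
]


@dataclass
class EndSideResult:
    """Per-bar end/side ratios and the per-cell mean (one point per cell)."""

    per_bar: pd.DataFrame
    per_cell_mean: float
    cell_id: int = 0
    excluded: list[int] = field(default_factory=list)


@dataclass
class PillarRatioResult:
    """Per-ROI integrin/membrane ratios normalised by the cell-wide mean."""

    per_roi: pd.DataFrame  # columns: window, roi_type, ratio, norm_ratio
    cell_id: int = 0
    excluded: list[int] = field(default_factory=list)

    @property
    def pillar_norm_ratios(self) -> np.ndarray:
        df = self.per_roi
        return df.loc[df.roi_type == "pillar", "norm_ratio"].to_numpy()


@dataclass
class SpearmanResult:
    rho: float | None
    n: int
    cell_id: int = 0


def background_level(image: np.ndarray, cell_mask: np.ndarray) -> float:
    """Median intensity of the cell-free image region."""
    outside = ~np.asarray(cell_mask).astype(bool)
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(image)[outside]))


def _roi_means(
    image: np.ndarray, windows: WindowSet, mask: np.ndarray, background: float
) -> np.ndarray:
    out = np.empty(len(windows.in_cell_indices()))
    for j, k in enumerate(windows.in_cell_indices()):
        win = windows.extract(image, k)
        out[j] = win[mask].mean() - background
    return out


def end_side_ratios(
    integrin: np.ndarray,
    membrane: np.ndarray,
    windows: WindowSet,
    rois: ROISet,
    cell_id: int = 0,
    background: tuple[float, float] = (0.0, 0.0),
) -> EndSideResult:
    """Membrane-normalised end/side ratios, one per bar, averaged per cell.

    ``ratio_norm = (integrin end/side) / (membrane end/side)``; the membrane
    division cancels per-bar wrapping factors.  Bars with a non-positive
    side mean after background correction are excluded and logged.
    """
    idx = windows.in_cell_indices()
    if len(idx) == 0:
        raise NanocurveError("no in-cell windows")
    bi, bm = background
    rows, excluded = [], []
    for k in idx:
        wi = windows.extract(integrin, k)
        wm = windows.extract(membrane, k)
        ie = wi[rois["end"]].mean() - bi
        is_ = wi[rois["side"]].mean() - bi
        me = wm[rois["end"]].mean() - bm
        ms = wm[rois["side"]].mean() - bm
        if is_ <= 0 or ms <= 0 or me <= 0:
            excluded.append(int(k))
            log.info("bar %d excluded: non-positive mean after background correction", k)
            continue
        rows.append(
            {
                "window": int(k),
                "end_mean_integrin": ie,
                "side_mean_integrin": is_,
                "end_mean_membrane": me,
                "side_mean_membrane": ms,
                "ratio_raw_integrin": ie / is_,
                "ratio_raw_membrane": me / ms,
                "ratio_norm": (ie / is_) / (me / ms),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise NanocurveError("all bars excluded; cannot form a per-cell mean")
    return EndSideResult(
        per_bar=df,
        per_cell_mean=float(df.ratio_norm.mean()),
        cell_id=cell_id,
        excluded=excluded,
    )


def direct_end_side(
    channel: np.ndarray,
    windows: WindowSet,
    rois: ROISet,
    cell_id: int = 0,
    background: float = 0.0,
) -> EndSideResult:
    """End/side ratio without membrane normalisation (unlabelled-membrane mode)."""
    idx = windows.in_cell_indices()
    if len(idx) == 0:
        raise NanocurveError("no in-cell windows")
    rows, excluded = [], []
    for k in idx:
        win = windows.extract(channel, k)
        e = win[rois["end"]].mean() - background
        s = win[rois["side"]].mean() - background
        if s <= 0:
            excluded.append(int(k))
            log.info("bar %d excluded: non-positive side mean", k)
            continue
        rows.append({"window": int(k), "end_mean": e, "side_mean": s, "ratio_raw": e / s})
    df = pd.DataFrame(rows)
    if df.empty:
        raise NanocurveError("all bars excluded")
    df["ratio_norm"] = df.ratio_raw
    return EndSideResult(
        per_bar=df, per_cell_mean=float(df.ratio_raw.mean()), cell_id=cell_id, excluded=excluded
    )


def gradient_group(per_bar: pd.DataFrame, value_col: str = "ratio_norm") -> pd.DataFrame:
    """Average same-diameter bars within each imaging field.

    ``per_bar`` needs ``field`` and ``diameter_um`` columns; returns one row
    per (field, diameter).  Diameters with zero bars are simply absent (and
    logged relative to the full diameter set of the table).
    """
    if per_bar.empty:
        raise NanocurveError("empty per-bar table")
    grouped = (
        per_bar.groupby(["field", "diameter_um"], sort=True)[value_col]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": value_col, "count": "n_bars"})
    )
    return grouped


def pillar_ratios(
    integrin: np.ndarray,
    membrane: np.ndarray,
    windows: WindowSet,
    rois: ROISet,
    cell_id: int = 0,
    background: tuple[float, float] = (0.0, 0.0),
    min_pillars: int = 10,
) -> PillarRatioResult:
    """Integrin/membrane ratio per pillar and flat-annulus ROI.

    Every ROI ratio is normalised by the mean ratio over all ROIs of the
    cell, so the per-cell mean of ``norm_ratio`` is exactly 1.
    """
    idx = windows.in_cell_indices()
    if len(idx) < min_pillars:
        raise NanocurveError(f"need >= {min_pillars} in-cell pillars, found {len(idx)}")
    bi, bm = background
    rows, excluded = [], []
    for k in idx:
        wi = windows.extract(integrin, k)
        wm = windows.extract(membrane, k)
        for roi_type in ("pillar", "annulus"):
            mi = wi[rois[roi_type]].mean() - bi
            mm = wm[rois[roi_type]].mean() - bm
            if mm <= 0:
                excluded.append(int(k))
                log.info("ROI (%s, window %d) excluded: membrane mean <= 0", roi_type, k)
                continue
            rows.append({"window": int(k), "roi_type": roi_type, "ratio": mi / mm})
    df = pd.DataFrame(rows)
    if df.empty:
        raise NanocurveError("all ROIs excluded")
    df["norm_ratio"] = df.ratio / df.ratio.mean()
    return PillarRatioResult(per_roi=df, cell_id=cell_id, excluded=excluded)


def classify_enriched(
    norm_ratios: np.ndarray, threshold: float = 1.5, min_pillars: int = 10
) -> tuple[np.ndarray, float]:
    """Flag pillars with ``norm_ratio > threshold``; return flags and fraction."""
    r = np.asarray(norm_ratios, dtype=float)
    if len(r) < min_pillars:
        raise NanocurveError(f"need >= {min_pillars} pillars to classify")
    flags = r > threshold
    return flags, float(flags.mean())


def spearman(x: np.ndarray, y: np.ndarray) -> float | None:
    """Spearman rank correlation with midranks for ties; None if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("spearman undefined: constant input array")
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_at_pillars(
    poi: np.ndarray,
    integrin: np.ndarray,
    membrane: np.ndarray,
    windows: WindowSet,
    rois: ROISet,
    cell_id: int = 0,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    min_pillars: int = 5,
) -> SpearmanResult:
    """Per-cell Spearman correlation of POI intensity with the normalised
    integrin/membrane ratio at individual pillars (pillar disc ROI only)."""
    idx = windows.in_cell_indices()
    if len(idx) < min_pillars:
        raise NanocurveError(f"need >= {min_pillars} pillars, found {len(idx)}")
    bp, bi, bm = background
    pm = rois["pillar"]
    poi_means, ratios = [], []
    for k in idx:
        mp = windows.extract(poi, k)[pm].mean() - bp
        mi = windows.extract(integrin, k)[pm].mean() - bi
        mm = windows.extract(membrane, k)[pm].mean() - bm
        if mm <= 0:
            log.info("pillar %d excluded from correlation: membrane mean <= 0", k)
            continue
        poi_means.append(mp)
        ratios.append(mi / mm)
    ratios = np.asarray(ratios)
    ratios = ratios / ratios.mean() if ratios.mean() != 0 else ratios
    rho = spearman(np.asarray(poi_means), ratios)
    return SpearmanResult(rho=rho, n=len(ratios), cell_id=cell_id)
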