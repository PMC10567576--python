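"""Ratiometric FRET tension analysis with moment-preserving thresholding.

Adhesions are segmented on the donor channel with Tsai's moment-preserving
("Moments") auto-threshold, split into curved (on-pillar) and focal
(off-pillar) classes via the pillar location map, and each class is scored
by its acceptor/donor ratio normalised to the cell-wide mean ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, NanocurveError, NoAdhesionsError
from .registration import NanostructureLattice

log = logging.getLogger(__name__)

__all__ = [
    "AdhesionMaskPair",
    "FretResult",
    "moments_threshold_hist",
    "moments_threshold",
    "moments_binarize",
    "pillar_disc_map",
    "segment_and_classify",
    "fret_ratios",
]


@dataclass
class AdhesionMaskPair:
    curved_mask: np.ndarray
    focal_mask: np.ndarray
    donor_threshold: float  # provenance: threshold in donor intensity units

    @property
    def all_mask(self) -> np.ndarray:
        return self.curved_mask | self.focal_mask


@dataclass
class FretResult:
    curved_ratio: float
    focal_ratio: float
    cellwide_ratio: float
    n_curved_px: int
    n_focal_px: int
    mode: str


def moments_threshold_hist(hist: np.ndarray) -> int:
    """Tsai's moment-preserving threshold on a 256-bin histogram.

    Finds the fraction ``p0`` such that a two-level image preserves the first
    three gray-level moments, then returns the first bin where the cumulative
    normalised histogram exceeds ``p0`` (the 256-bin GUI dialect).
    """
    h = np.asarray(hist, dtype=float)
    if h.sum() <= 0 or np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("histogram has no spread")
    p = h / h.sum()
    i = np.arange(len(p), dtype=float)
    m1 = float(np.sum(i * p))
    m2 = float(np.sum(i**2 * p))
    m3 = float(np.sum(i**3 * p))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("zero-variance histogram")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateHistogramError("complex moment roots; degenerate histogram")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    csum = np.cumsum(p)
    # first bin whose cumulative mass reaches p0 (>=, so a pure two-level
    # histogram thresholds at its lower level and keeps a foreground)
    above = np.flatnonzero(csum >= p0 - 1e-12)
    return int(above[0]) if len(above) else len(p) - 1


def _to_bins(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    img = np.asarray(image, dtype=float)
    mn, mx = float(img.min()), float(img.max())
    if mx == mn:
        raise DegenerateHistogramError("constant image")
    bins = np.round((img - mn) / (mx - mn) * 255.0).astype(int)
    return bins, mn, mx


def moments_threshold(image: np.ndarray) -> float:
    """Moments threshold of an image, returned in original intensity units.

    The image is rescaled to a 256-bin integer histogram first; pixels with
    a rescaled level strictly above the returned threshold are foreground.
    """
    bins, mn, mx = _to_bins(image)
    t_bin = moments_threshold_hist(np.bincount(bins.ravel(), minlength=256))
    return mn + t_bin * (mx - mn) / 255.0


def moments_binarize(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Binary foreground mask by the Moments threshold (and the threshold)."""
    bins, mn, mx = _to_bins(image)
    t_bin = moments_threshold_hist(np.bincount(bins.ravel(), minlength=256))
    return bins > t_bin, mn + t_bin * (mx - mn) / 255.0


def pillar_disc_map(
    lattice: NanostructureLattice, shape: tuple[int, int], r_in: int = 9
) -> np.ndarray:
    """Binary map of pillar discs (distance <= r_in px from each centre)."""
    out = np.zeros(shape, dtype=bool)
    for x, y in lattice.nodes(shape):
        x0, x1 = max(0, int(x) - r_in - 1), min(shape[1], int(x) + r_in + 2)
        y0, y1 = max(0, int(y) - r_in - 1), min(shape[0], int(y) + r_in + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] |= np.hypot(yy - y, xx - x) <= r_in
    return out


def segment_and_classify(
    donor: np.ndarray,
    lattice: NanostructureLattice,
    r_in: int = 9,
) -> AdhesionMaskPair:
    """Threshold the donor channel and split adhesions by pillar location.

    All-adhesions mask = Moments threshold of the donor; curved = its
    intersection with the pillar-disc map; focal = the remainder.
    """
    adh, thr = moments_binarize(donor)
    if not adh.any():
        raise NoAdhesionsError("no adhesions: empty mask after thresholding")
    pillars = pillar_disc_map(lattice, donor.shape, r_in=r_in)
    return AdhesionMaskPair(
        curved_mask=adh & pillars, focal_mask=adh & ~pillars, donor_threshold=thr
    )


def fret_ratios(
    acceptor: np.ndarray,
    donor: np.ndarray,
    masks: AdhesionMaskPair,
    cell_mask: np.ndarray | None = None,
    mode: str = "mean_of_ratios",
    donor_floor: float | None = None,
) -> FretResult:
    """Normalised acceptor/donor ratio per adhesion class.

    ``mode`` selects pixelwise mean-of-ratios (default) or ratio-of-means.
    Pixels with donor below ``donor_floor`` (default: background median +
    3 SD, estimated outside the adhesion mask) are excluded and logged.
    """
    acc = np.asarray(acceptor, dtype=float)
    don = np.asarray(donor, dtype=float)
    if donor_floor is None:
        bgpx = don[~masks.all_mask]
        donor_floor = float(np.median(bgpx) + 3 * np.std(bgpx)) if bgpx.size else 0.0
    valid = don > donor_floor
    n_dropped = int((~valid & masks.all_mask).sum())
    if n_dropped:
        log.info("%d adhesion pixels below the donor floor excluded", n_dropped)

    cell = np.ones_like(valid) if cell_mask is None else np.asarray(cell_mask).astype(bool)
    cell_valid = cell & valid
    if not cell_valid.any():
        raise NanocurveError("no valid pixels above the donor floor in the cell")

    def class_ratio(mask: np.ndarray) -> float:
        m = mask & valid
        if not m.any():
            raise NanocurveError("adhesion class has no valid pixels")
        if mode == "mean_of_ratios":
            return float(np.mean(acc[m] / don[m]))
        if mode == "ratio_of_means":
            return float(acc[m].mean() / don[m].mean())
        raise NanocurveError(f"unknown mode {mode!r}")

    if mode == "mean_of_ratios":
        cellwide = float(np.mean(acc[cell_valid] / don[cell_valid]))
    else:
        cellwide = float(acc[cell_valid].mean() / don[cell_valid].mean())
    return FretResult(
        curved_ratio=class_ratio(masks.curved_mask) / cellwide,
        focal_ratio=class_ratio(masks.focal_mask) / cellwide,
        cellwide_ratio=cellwide,
        n_curved_px=int((masks.curved_mask & valid).sum()),
        n_focal_px=int((masks.focal_mask & valid).sum()),
        mode=mode,
    )
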