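"""Time-lapse analysis at pillars: traces, grouping, temporal variability."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .errors import DriftError, NanocurveError
from .registration import ROISet, WindowSet

log = logging.getLogger(__name__)

__all__ = ["PillarTrace", "extract_traces", "group_by_intensity", "temporal_sd"]


@dataclass
class PillarTrace:
    """Per-frame mean intensity over one pillar's disc ROI."""

    pillar_id: int
    intensity: np.ndarray  # (n_frames,)
    group: str | None = None

    @property
    def normalized(self) -> np.ndarray:
        """Trace divided by its value at frame 0 (so frame 0 is exactly 1)."""
        return self.intensity / self.intensity[0]


def _check_drift(movie: np.ndarray, max_drift_px: float) -> None:
    ref = movie[0]
    for t in range(1, movie.shape[0]):
        shift, _, _ = phase_cross_correlation(ref, movie[t], normalization=None)
        if np.hypot(*shift) > max_drift_px:
            raise DriftError(
                f"frame {t} drifted {np.hypot(*shift):.2f} px from frame 0 "
                f"(limit {max_drift_px} px)"
            )


def extract_traces(
    movie: np.ndarray,
    windows: WindowSet,
    rois: ROISet,
    max_drift_px: float = 2.0,
    check_drift: bool = True,
) -> list[PillarTrace]:
    """One intensity trace per in-cell pillar from a (T, H, W) movie.

    The lattice is assumed static (windows registered on frame 0); a
    cross-correlation drift check guards that assumption.
    """
    if movie.ndim != 3:
        raise NanocurveError("movie must be (T, H, W)")
    if check_drift:
        _check_drift(movie, max_drift_px)
    pm = rois["pillar"]
    traces = []
    for k in windows.in_cell_indices():
        sy, sx = windows.window_slice(k)
        vals = movie[:, sy, sx][:, pm].mean(axis=1)
        traces.append(PillarTrace(pillar_id=int(k), intensity=vals))
    return traces


def group_by_intensity(
    intensities: np.ndarray, scheme: str = "top25_bottom75"
) -> np.ndarray:
    """Label pillars "high"/"low" by reference-channel intensity.

    ``top25_bottom75``: top 25% high, rest low.  ``quartile_top25_bottom25``:
    top 25% high, bottom 25% low, middle unlabelled (None).  Quantiles use
    the nearest-rank convention; ties across the cut resolve by pillar index.
    """
    x = np.asarray(intensities, dtype=float)
    n = len(x)
    if n < 8:
        raise NanocurveError(f"need >= 8 pillars to group, found {n}")
    k = int(np.ceil(0.25 * n))
    # stable sort: descending value, ascending index on ties
    order = np.lexsort((np.arange(n), -x))
    labels = np.array([None] * n, dtype=object)
    if scheme == "top25_bottom75":
        labels[order[:k]] = "high"
        labels[order[k:]] = "low"
    elif scheme == "quartile_top25_bottom25":
        labels[order[:k]] = "high"
        labels[order[-k:]] = "low"
    else:
        raise NanocurveError(f"unknown grouping scheme {scheme!r}")
    if n and np.sum(x == np.sort(x)[::-1][k - 1]) > 1:
        log.info("ties span the quantile cut; resolved deterministically by pillar index")
    return labels


def temporal_sd(
    traces: list[PillarTrace], normalize: bool = True
) -> list[float | None]:
    """Sample standard deviation (n-1 denominator) per trace.

    With ``normalize`` the trace is first divided by its frame-0 value;
    traces with zero initial intensity are excluded (None) and logged.
    """
    out: list[float | None] = []
    for tr in traces:
        if len(tr.intensity) < 2:
            raise NanocurveError("trace too short for a standard deviation")
        if normalize:
            if tr.intensity[0] == 0:
                log.info("pillar %d excluded: zero initial intensity", tr.pillar_id)
                out.append(None)
                continue
            out.append(float(np.std(tr.normalized, ddof=1)))
        else:
            out.append(float(np.std(tr.intensity, ddof=1)))
    return out
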