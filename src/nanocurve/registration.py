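"""Detection of the periodic nanostructure lattice and per-structure ROIs.

The workflow mirrors the classic nanostructure-quantification recipe:

1. detect the lattice (pitch, orientation, origin) from a registration image
   (bright-field for bars, a membrane channel for pillars);
2. tile one square window per lattice node, flag windows inside the cell;
3. average the in-cell windows into a low-noise structure template;
4. derive end/side (bars) or pillar/annulus (pillars) ROI masks in window
   coordinates, to be translated onto every structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .errors import LatticeError, NotABarError
from .gridutil import lattice_basis, lattice_nodes

__all__ = [
    "NanostructureLattice",
    "WindowSet",
    "ROISet",
    "detect_lattice",
    "tile_windows",
    "average_windows",
    "derive_bar_rois",
    "derive_pillar_rois",
]


@dataclass(frozen=True)
class NanostructureLattice:
    """A detected (or specified) periodic array."""

    origin_xy: tuple[float, float]  # one node, (x, y) pixels
    pitch_um: float
    orientation_deg: float
    pixel_size_um: float
    residual_um: float = 0.0  # RMS offset of detected centres from the ideal grid

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um

    def nodes(self, shape: tuple[int, int], margin: float = 0.0) -> np.ndarray:
        return lattice_nodes(self.origin_xy, self.pitch_px, self.orientation_deg, shape, margin)

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin_xy": list(self.origin_xy),
                "pitch_um": self.pitch_um,
                "orientation_deg": self.orientation_deg,
                "pixel_size_um": self.pixel_size_um,
                "residual_um": self.residual_um,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NanostructureLattice":
        d = json.loads(text)
        d["origin_xy"] = tuple(d["origin_xy"])
        return cls(**d)


@dataclass
class WindowSet:
    """Congruent square windows centred on lattice nodes."""

    centres_xy: np.ndarray  # (n, 2) integer pixel centres
    side: int  # odd window side, <= pitch
    in_cell: np.ndarray  # (n,) bool
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.centres_xy)

    @property
    def half(self) -> int:
        return self.side // 2

    def window_slice(self, k: int) -> tuple[slice, slice]:
        x, y = self.centres_xy[k]
        h = self.half
        return slice(y - h, y + h + 1), slice(x - h, x + h + 1)

    def extract(self, image: np.ndarray, k: int) -> np.ndarray:
        sy, sx = self.window_slice(k)
        return image[sy, sx]

    def in_cell_indices(self) -> np.ndarray:
        return np.flatnonzero(self.in_cell)


@dataclass
class ROISet:
    """Binary ROI masks in window coordinates."""

    kind: str  # {"bar", "pillar"}
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            if not m.any():
                raise LatticeError(f"ROI mask {name!r} is empty")
        if self.kind == "bar":
            if (self.masks["end"] & self.masks["side"]).any():
                raise LatticeError("end and side masks overlap")
        elif self.kind == "pillar":
            if (self.masks["pillar"] & self.masks["annulus"]).any():
                raise LatticeError("pillar and annulus masks overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


# ---------------------------------------------------------------------------
# lattice detection
# ---------------------------------------------------------------------------


def _autocorrelation(image: np.ndarray) -> np.ndarray:
    img = image - image.mean()
    f = np.fft.fft2(img)
    ac = np.fft.ifft2(np.abs(f) ** 2).real
    return np.fft.fftshift(ac)


def _subpixel_peak(a: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Quadratic (parabolic) sub-pixel refinement of a local maximum."""

    def refine(m1, m0, p1):
        denom = m1 - 2 * m0 + p1
        if denom >= 0:
            return 0.0
        return 0.5 * (m1 - p1) / denom

    dy = dx = 0.0
    if 0 < iy < a.shape[0] - 1:
        dy = refine(a[iy - 1, ix], a[iy, ix], a[iy + 1, ix])
    if 0 < ix < a.shape[1] - 1:
        dx = refine(a[iy, ix - 1], a[iy, ix], a[iy, ix + 1])
    return iy + dy, ix + dx


def _local_peak_near(a: np.ndarray, target_yx: np.ndarray, radius: int) -> tuple[float, float] | None:
    cy, cx = int(round(target_yx[0])), int(round(target_yx[1]))
    r = radius
    y0, y1 = max(0, cy - r), min(a.shape[0], cy + r + 1)
    x0, x1 = max(0, cx - r), min(a.shape[1], cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return None
    patch = a[y0:y1, x0:x1]
    iy, ix = np.unravel_index(np.argmax(patch), patch.shape)
    return _subpixel_peak(a, y0 + iy, x0 + ix)


def detect_lattice(
    registration_image: np.ndarray,
    pitch_band_um: tuple[float, float],
    pixel_size_um: float,
    anisotropy_tol: float = 0.05,
) -> NanostructureLattice:
    """Detect a square periodic lattice from an intensity image.

    Uses the 2D autocorrelation: the strongest off-centre peak within the
    pitch band gives the lattice vector; the farthest collinear harmonic
    refines the pitch; Fourier phase at the lattice frequency gives the
    origin with sub-pixel precision.

    Raises
    ------
    LatticeError
        If no significant periodicity exists in the band, or the two lattice
        directions disagree in pitch beyond ``anisotropy_tol``.
    """
    img = np.asarray(registration_image, dtype=float)
    h, w = img.shape
    pmin = pitch_band_um[0] / pixel_size_um
    pmax = pitch_band_um[1] / pixel_size_um
    if min(h, w) < 3 * pmin:
        raise LatticeError("image too small for 3x3 structures within the pitch band")

    ac = _autocorrelation(img)
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    rad = np.hypot(yy - cy, xx - cx)
    band = (rad >= 0.9 * pmin) & (rad <= 1.1 * pmax)

    peaks = peak_local_max(
        ac, min_distance=max(2, int(pmin / 3)), exclude_border=False, threshold_rel=0.0
    )
    cand = [p for p in peaks if band[p[0], p[1]]]
    if not cand:
        raise LatticeError("no lattice: no autocorrelation peak in the pitch band")
    vals = np.array([ac[p[0], p[1]] for p in cand])
    if vals.max() < 0.03 * ac[cy, cx]:
        raise LatticeError("no lattice: periodicity not significant in the pitch band")
    # among comparably strong peaks prefer the shortest lattice vector
    # (diagonal peaks of a square lattice are as strong as the axial ones)
    strong = [p for p, v in zip(cand, vals) if v >= 0.6 * vals.max()]
    radii = [np.hypot(p[0] - cy, p[1] - cx) for p in strong]
    best = strong[int(np.argmin(radii))]

    py, px = _subpixel_peak(ac, best[0], best[1])
    v1 = np.array([py - cy, px - cx])  # (dy, dx)
    p1 = np.linalg.norm(v1)
    if not (0.8 * pmin <= p1 <= 1.25 * pmax):
        raise LatticeError("no lattice: dominant period outside the pitch band")

    # harmonic refinement: locate the k-th collinear peak and divide
    kmax = int(min(h, w) / 2 / p1 * 0.9)
    if kmax >= 2:
        tgt = np.array([cy, cx]) + kmax * v1
        ref = _local_peak_near(ac, tgt, radius=max(2, int(p1 / 4)))
        if ref is not None:
            vk = np.array([ref[0] - cy, ref[1] - cx])
            if abs(np.linalg.norm(vk) / kmax - p1) < 0.5 * p1:
                v1 = vk / kmax
                p1 = np.linalg.norm(v1)

    # perpendicular direction (square lattice check)
    v2t = np.array([v1[1], -v1[0]])  # rotate 90 deg
    hits = []
    for sgn in (+1, -1):
        ref = _local_peak_near(ac, np.array([cy, cx]) + sgn * v2t, radius=max(2, int(p1 / 4)))
        if ref is not None:
            hits.append(np.linalg.norm(np.array([ref[0] - cy, ref[1] - cx])))
    if hits:
        p2 = float(np.mean(hits))
        if abs(p2 - p1) / p1 > anisotropy_tol:
            raise LatticeError(
                f"anisotropic lattice: perpendicular pitch {p2:.2f} px vs {p1:.2f} px"
            )

    pitch_px = p1
    orientation = float(np.degrees(np.arctan2(v1[0], v1[1])) % 180.0)
    # canonicalise to [0, 90) for a square lattice
    if orientation >= 90.0:
        orientation -= 90.0

    # origin from Fourier phase along each lattice direction
    u1, u2 = lattice_basis(1.0, orientation)  # unit vectors (x, y)
    base = img - img.min()
    xs = np.arange(w)
    ys = np.arange(h)
    X, Y = np.meshgrid(xs, ys)
    offs = []
    for e in (u1, u2):
        phase = np.exp(-2j * np.pi * (X * e[0] + Y * e[1]) / pitch_px)
        c = np.sum(base * phase)
        t = (-np.angle(c) * pitch_px / (2 * np.pi)) % pitch_px
        offs.append(t)
    origin = offs[0] * u1 + offs[1] * u2

    # refine pitch, orientation and origin by a least-squares affine grid fit
    # to per-node centres of mass (the phase/autocorrelation estimates carry
    # edge bias when the field holds a non-integer number of periods)
    pitch_px, orientation, origin = _refine_grid(img, pitch_px, orientation, origin)
    orientation = orientation % 90.0  # square lattice: basis is 4-fold symmetric

    u1, u2 = lattice_basis(pitch_px, orientation)
    frac = np.linalg.solve(np.stack([u1, u2], axis=1), origin) % 1.0
    origin = np.stack([u1, u2], axis=1) @ frac
    origin_xy = (float(origin[0]), float(origin[1]))

    lat = NanostructureLattice(
        origin_xy=origin_xy,
        pitch_um=float(pitch_px * pixel_size_um),
        orientation_deg=float(orientation),
        pixel_size_um=pixel_size_um,
    )
    return NanostructureLattice(
        origin_xy=origin_xy,
        pitch_um=lat.pitch_um,
        orientation_deg=lat.orientation_deg,
        pixel_size_um=pixel_size_um,
        residual_um=_grid_residual(img, lat),
    )


def _node_centroids(
    img: np.ndarray, nodes: np.ndarray, r: int
) -> tuple[np.ndarray, np.ndarray]:
    """Local background-clipped centres of mass around predicted nodes."""
    meas, ok = [], []
    gy, gx = np.mgrid[-r : r + 1, -r : r + 1]
    for k, (x, y) in enumerate(nodes):
        xi, yi = int(round(x)), int(round(y))
        patch = img[yi - r : yi + r + 1, xi - r : xi + r + 1].astype(float)
        wgt = np.clip(patch - np.median(patch), 0.0, None)
        tot = wgt.sum()
        if tot <= 0:
            continue
        cx = (wgt * gx).sum() / tot + xi
        cy = (wgt * gy).sum() / tot + yi
        meas.append((cx, cy))
        ok.append(k)
    return np.asarray(meas), np.asarray(ok, dtype=int)


def _refine_grid(
    img: np.ndarray,
    pitch_px: float,
    orientation: float,
    origin: np.ndarray,
    n_iter: int = 5,
) -> tuple[float, float, np.ndarray]:
    for _ in range(n_iter):
        r = max(2, int(pitch_px / 4))
        nodes, ij = lattice_nodes(
            (origin[0], origin[1]), pitch_px, orientation, img.shape,
            margin=r + 1, return_indices=True,
        )
        if len(nodes) < 4:
            break
        meas, ok = _node_centroids(img, nodes, r)
        if len(ok) < 4:
            break
        ij = ij[ok]
        if len(np.unique(ij[:, 0])) < 2 or len(np.unique(ij[:, 1])) < 2:
            break
        design = np.column_stack([np.ones(len(ij)), ij])
        params, *_ = np.linalg.lstsq(design, meas, rcond=None)
        o, a1, a2 = params
        p1, p2 = np.linalg.norm(a1), np.linalg.norm(a2)
        pitch_px = 0.5 * (p1 + p2)
        orientation = float(np.degrees(np.arctan2(a1[1], a1[0])) % 180.0)
        origin = o
    return pitch_px, orientation, origin


def _grid_residual(img: np.ndarray, lat: NanostructureLattice, max_nodes: int = 64) -> float:
    """RMS offset (um) between local centres of mass and the ideal grid."""
    r = max(2, int(lat.pitch_px / 4))
    nodes = lat.nodes(img.shape, margin=r + 1)
    if len(nodes) == 0:
        return 0.0
    if len(nodes) > max_nodes:
        nodes = nodes[:: max(1, len(nodes) // max_nodes)]
    sq = []
    for x, y in nodes:
        xi, yi = int(round(x)), int(round(y))
        patch = img[yi - r : yi + r + 1, xi - r : xi + r + 1].astype(float)
        wgt = patch - patch.min()
        tot = wgt.sum()
        if tot <= 0:
            continue
        gy, gx = np.mgrid[-r : r + 1, -r : r + 1]
        dy = (wgt * gy).sum() / tot + (yi - y)
        dx = (wgt * gx).sum() / tot + (xi - x)
        sq.append(dx**2 + dy**2)
    if not sq:
        return 0.0
    return float(np.sqrt(np.mean(sq)) * lat.pixel_size_um)


# ---------------------------------------------------------------------------
# window tiling and averaging
# ---------------------------------------------------------------------------


def tile_windows(
    lattice: NanostructureLattice,
    image_shape: tuple[int, int],
    cell_mask: np.ndarray | None = None,
    min_cell_frac: float = 0.8,
) -> WindowSet:
    """One square window per lattice node fully inside the image.

    A window is flagged ``in_cell`` when at least ``min_cell_frac`` of its
    pixels lie in ``cell_mask`` (all windows are in-cell when no mask is
    given).
    """
    side = int(np.floor(lattice.pitch_px))
    if side % 2 == 0:
        side -= 1
    if side < 3:
        raise LatticeError("pitch too small to tile windows")
    half = side // 2
    nodes = lattice.nodes(image_shape, margin=0)
    centres = []
    for x, y in nodes:
        xi, yi = int(round(x)), int(round(y))
        if (
            half <= xi < image_shape[1] - half
            and half <= yi < image_shape[0] - half
        ):
            centres.append((xi, yi))
    if not centres:
        raise LatticeError("zero complete windows fit inside the image")
    centres = np.asarray(centres, dtype=int)

    if cell_mask is None:
        flags = np.ones(len(centres), dtype=bool)
    else:
        cell = np.asarray(cell_mask).astype(bool)
        flags = np.empty(len(centres), dtype=bool)
        for k, (x, y) in enumerate(centres):
            win = cell[y - half : y + half + 1, x - half : x + half + 1]
            flags[k] = win.mean() >= min_cell_frac
    return WindowSet(centres_xy=centres, side=side, in_cell=flags, image_shape=tuple(image_shape))


def average_windows(image: np.ndarray, windows: WindowSet) -> np.ndarray:
    """Pixelwise mean over all in-cell windows."""
    idx = windows.in_cell_indices()
    if len(idx) == 0:
        raise LatticeError("no in-cell windows to average")
    acc = np.zeros((windows.side, windows.side), dtype=float)
    for k in idx:
        acc += windows.extract(image, k)
    return acc / len(idx)


# ---------------------------------------------------------------------------
# ROI derivation
# ---------------------------------------------------------------------------


def derive_bar_rois(
    averaged_window: np.ndarray,
    bar_width_px: float | None = None,
    cap_depth: int | None = None,
    flank_width: int = 2,
    min_eccentricity: float = 1.2,
) -> ROISet:
    """Derive bar-end and bar-side masks from an averaged membrane window.

    The footprint is the largest Otsu-thresholded component; its principal
    axis defines the long axis.  End caps are the footprint pixels within
    ``cap_depth`` of the axial extremes, dilated by ``flank_width`` (clipped
    to the footprint); side bands are footprint pixels at least
    ``cap_depth + 2 * flank_width`` away from the extremes.  ``cap_depth``
    defaults to the bar width in pixels.
    """
    win = np.asarray(averaged_window, dtype=float)
    thr = threshold_otsu(win)
    bw = win > thr
    if not bw.any():
        raise NotABarError("threshold produced an empty footprint")
    lab = cc_label(bw, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    fp = lab == np.argmax(sizes)

    ys, xs = np.nonzero(fp)
    coords = np.stack([xs, ys], axis=1).astype(float)
    c = coords.mean(axis=0)
    cov = np.cov((coords - c).T)
    evals, evecs = np.linalg.eigh(cov)
    l2, l1 = evals  # ascending
    if l2 <= 0:
        ecc = np.inf
    else:
        ecc = np.sqrt(l1 / l2)
    if ecc < min_eccentricity:
        raise NotABarError(
            f"footprint eccentricity {ecc:.2f} < {min_eccentricity}: not a bar "
            "(consider pillar ROIs)"
        )
    major = evecs[:, 1]  # (x, y)

    if cap_depth is None:
        if bar_width_px is not None:
            cap_depth = max(1, int(round(bar_width_px)))
        else:
            cap_depth = max(1, int(round(np.sqrt(12.0 * l2))))  # uniform-width estimate

    # axial coordinate of every window pixel, centred on the footprint
    yy, xx = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
    t = (xx - c[0]) * major[0] + (yy - c[1]) * major[1]
    t_fp = t[fp]
    t0 = 0.5 * (t_fp.max() + t_fp.min())
    t = t - t0
    half_t = 0.5 * (t_fp.max() - t_fp.min())

    caps = fp & (np.abs(t) >= half_t - cap_depth)
    end = binary_dilation(caps, disk(flank_width)) & fp
    side = fp & (np.abs(t) <= half_t - cap_depth - 2 * flank_width)
    if not caps.any() or not side.any():
        raise NotABarError("cap/flank geometry leaves an empty ROI; bar too short")
    return ROISet(kind="bar", masks={"end": end, "side": side, "footprint": fp})


def derive_pillar_rois(window_side: int, r_in: int = 9, r_out: int = 20) -> ROISet:
    """Pillar disc (distance <= r_in) and annulus (r_in < distance <= r_out).

    Defaults follow the published 0-9 / 10-20 pixel convention.
    """
    if r_in >= r_out:
        raise LatticeError(f"r_in ({r_in}) must be < r_out ({r_out})")
    half = window_side // 2
    yy, xx = np.mgrid[0:window_side, 0:window_side]
    d = np.hypot(yy - half, xx - half)
    pillar = d <= r_in
    annulus = (d > r_in) & (d <= r_out)
    if not annulus.any():
        raise LatticeError("window too small for the requested annulus")
    return ROISet(kind="pillar", masks={"pillar": pillar, "annulus": annulus})
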