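"""Renderers for 2D nanostructure fields, gradient arrays and time-lapses.

The photometric model is deliberately phenomenological: within a structure's
membrane-wrap zone the noiseless expectation of a membrane-bound channel is

    background + W_s * base_intensity            (side-wall zone)
    background + W_s * base_intensity * E_s      (high-curvature end zone)

where ``W_s`` is the per-structure wrapping factor and ``E_s`` the channel's
curvature enrichment at structure ``s``.  Off-structure membrane inside the
cell sits at ``background + base_intensity * flat_level``.  Photon shot noise
is Poisson; read noise is additive Gaussian; the result is clipped at zero.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import RenderError
from ..gridutil import lattice_nodes
from .specs import MEMBRANE_ROLES, ChannelSpec, GroundTruth, LatticeSpec, WrapField

__all__ = [
    "structure_centres",
    "render_structure_field",
    "render_gradient_bar_field",
    "render_timelapse",
]


def structure_centres(lattice: LatticeSpec, shape: tuple[int, int]) -> np.ndarray:
    """Centres ``(x, y)`` in pixels of all structures inside an image."""
    return lattice_nodes(lattice.origin, lattice.pitch_px, lattice.orientation_deg, shape)


def _paint_structures(
    shape: tuple[int, int],
    items: Sequence[tuple[float, float, str, float, float]],
    pixel_size_um: float,
    orientation_deg: float,
    end_cap_um: float,
    halo_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise structure zones.

    ``items`` is a sequence of ``(x, y, kind, length_um, width_um)`` where
    ``width_um`` doubles as the pillar diameter.  Returns ``zone_idx`` (int
    image, -1 outside any zone, else the structure index) and ``end_mask``
    (bool image marking the high-curvature sub-zone).
    """
    h, w = shape
    zone_idx = np.full(shape, -1, dtype=np.int32)
    end_mask = np.zeros(shape, dtype=bool)
    th = np.deg2rad(orientation_deg)
    ax, ay = np.cos(th), np.sin(th)

    for s, (cx, cy, kind, length_um, width_um) in enumerate(items):
        r_um = width_um / 2 + halo_um
        reach_um = (length_um / 2 + halo_um) if kind == "bar" else r_um
        reach = int(np.ceil(reach_um / pixel_size_um)) + 1
        x0, x1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
        y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = (xx - cx) * pixel_size_um
        dy = (yy - cy) * pixel_size_um
        if kind == "pillar":
            d = np.hypot(dx, dy)
            zone = d <= r_um
            end = zone
        else:
            t = dx * ax + dy * ay
            sperp = -dx * ay + dy * ax
            half_seg = max(length_um / 2 - width_um / 2, 0.0)
            d = np.hypot(np.maximum(np.abs(t) - half_seg, 0.0), sperp)
            zone = d <= r_um
            end = zone & (np.abs(t) >= length_um / 2 - end_cap_um)
        zone_idx[y0:y1, x0:x1][zone] = s
        end_mask[y0:y1, x0:x1][zone] = end[zone]
    return zone_idx, end_mask


def _channel_expectation(
    ch: ChannelSpec,
    zone_idx: np.ndarray,
    end_mask: np.ndarray,
    cell: np.ndarray,
    wrap: np.ndarray,
    e_per_structure: np.ndarray,
    wrap_end: np.ndarray | None = None,
) -> np.ndarray:
    shape = zone_idx.shape
    if ch.role == "cell":
        return ch.background + ch.base_intensity * cell.astype(float)
    if ch.role not in MEMBRANE_ROLES:  # registration / bright-field-like
        return ch.background + ch.base_intensity * (zone_idx >= 0).astype(float)

    if wrap_end is None:
        wrap_end = wrap
    exp = np.full(shape, float(ch.background))
    exp[cell] += ch.base_intensity * ch.flat_level
    zin = (zone_idx >= 0) & cell
    sidx = zone_idx[zin]
    vals = ch.base_intensity * wrap[sidx]
    vals_end = ch.base_intensity * wrap_end[sidx] * e_per_structure[sidx]
    exp[zin] = ch.background + np.where(end_mask[zin], vals_end, vals)
    return exp


def _apply_noise(exp: np.ndarray, read_noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(exp).astype(float)
    if read_noise_sd > 0:
        out += rng.normal(0.0, read_noise_sd, size=exp.shape)
    return np.clip(out, 0.0, None)


def _enrichment_arrays(
    channels: Sequence[ChannelSpec],
    n: int,
    per_structure_E: Mapping[str, np.ndarray] | None,
) -> dict[str, np.ndarray]:
    out = {}
    for ch in channels:
        if per_structure_E and ch.role in per_structure_E:
            arr = np.asarray(per_structure_E[ch.role], dtype=float)
            if arr.shape != (n,):
                raise RenderError(
                    f"per-structure enrichment for {ch.role!r} has shape {arr.shape}, "
                    f"expected ({n},)"
                )
        else:
            arr = np.full(n, ch.end_enrichment)
        out[ch.role] = arr
    return out


def render_structure_field(
    lattice: LatticeSpec,
    channels: Sequence[ChannelSpec],
    wrap: WrapField | None = None,
    cell_footprint: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
    noise: bool = True,
    per_structure_E: Mapping[str, np.ndarray] | None = None,
    blur_sigma_px: float = 0.0,
    end_cap_um: float = 0.3,
    halo_um: float = 0.2,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a multichannel image of a nanostructure array.

    Returns a ``(n_channels, h, w)`` float array (channel order follows
    ``channels``) and the :class:`GroundTruth` describing it.
    """
    if cell_footprint is not None:
        cell = np.asarray(cell_footprint).astype(bool)
        shape = cell.shape
    else:
        if shape is None:
            raise RenderError("either cell_footprint or shape must be given")
        cell = np.ones(shape, dtype=bool)

    if min(shape) * lattice.pixel_size_um < 2 * lattice.pitch_um:
        raise RenderError(
            f"image extent {shape} at {lattice.pixel_size_um} um/px does not cover "
            f"2x2 periods of a {lattice.pitch_um} um lattice"
        )
    nodes = structure_centres(lattice, shape)
    if len(nodes) < 4:
        raise RenderError("lattice does not fit the image extent (fewer than 4 structures)")

    n = len(nodes)
    if wrap is None:
        wrap = WrapField.none(n)
    if len(wrap) != n:
        raise RenderError(f"wrap field has {len(wrap)} factors for {n} structures")

    if lattice.structure_kind == "bar":
        items = [(x, y, "bar", lattice.bar_length_um, lattice.bar_width_um) for x, y in nodes]
    else:
        items = [(x, y, "pillar", 0.0, lattice.pillar_diameter_um) for x, y in nodes]
    zone_idx, end_mask = _paint_structures(
        shape, items, lattice.pixel_size_um, lattice.orientation_deg, end_cap_um, halo_um
    )

    e_arrays = _enrichment_arrays(channels, n, per_structure_E)
    rng = np.random.default_rng(seed)
    out = np.empty((len(channels),) + tuple(shape), dtype=float)
    for c, ch in enumerate(channels):
        exp = _channel_expectation(
            ch, zone_idx, end_mask, cell, wrap.factors, e_arrays[ch.role], wrap.at_end
        )
        if blur_sigma_px > 0:
            exp = gaussian_filter(exp, blur_sigma_px)
        out[c] = _apply_noise(exp, ch.read_noise_sd, rng) if noise else exp

    enriched_fraction = None
    if "integrin" in e_arrays:
        enriched_fraction = float(np.mean(e_arrays["integrin"] > 1.0))
    gt = GroundTruth(
        lattice=lattice,
        enrichment={ch.role: ch.end_enrichment for ch in channels},
        wrap_factors=wrap.factors.copy(),
        node_xy=nodes,
        per_structure_enrichment={k: v.copy() for k, v in per_structure_E.items()}
        if per_structure_E
        else None,
        enriched_fraction=enriched_fraction,
        seed=seed,
    )
    return out, gt


def render_gradient_bar_field(
    diameters_um: Sequence[float],
    enrichment_curve: Mapping[float, float] | Callable[[float], float],
    channels: Sequence[ChannelSpec],
    n_bars_per_diameter: int = 4,
    pitch_um: float = 8.0,
    pixel_size_um: float = 0.1,
    seed: int = 0,
    noise: bool = True,
    end_cap_um: float = 0.3,
    halo_um: float = 0.2,
) -> tuple[np.ndarray, GroundTruth]:
    """Render sub-arrays of bars whose end-curvature diameter varies.

    Each diameter gets its own column of ``n_bars_per_diameter`` bars; the
    integrin channel's enrichment at a bar is ``enrichment_curve(diameter)``.
    """
    diameters = [float(d) for d in diameters_um]
    if sorted(diameters) != diameters:
        raise RenderError("diameters must be sorted ascending")
    if n_bars_per_diameter < 4:
        raise RenderError("need >= 4 bars per diameter")
    for d in diameters:
        if d >= pitch_um:
            raise RenderError(f"diameter {d} um exceeds the pitch {pitch_um} um")

    if callable(enrichment_curve):
        curve = {d: float(enrichment_curve(d)) for d in diameters}
    else:
        curve = {d: float(enrichment_curve[d]) for d in diameters}

    pitch_px = pitch_um / pixel_size_um
    h = int(round((n_bars_per_diameter + 0.5) * pitch_px))
    w = int(round((len(diameters) + 0.5) * pitch_px))
    items = []
    diam_per_bar = []
    for col, d in enumerate(diameters):
        length = min(d + 1.0, pitch_um - 1.0)
        length = max(length, d * 1.05)  # keep a stadium, never a disc
        for row in range(n_bars_per_diameter):
            cx = (col + 0.75) * pitch_px
            cy = (row + 0.75) * pitch_px
            items.append((cx, cy, "bar", length, d))
            diam_per_bar.append(d)

    zone_idx, end_mask = _paint_structures(
        (h, w), items, pixel_size_um, 0.0, end_cap_um, halo_um
    )
    n = len(items)
    e_int = np.array([curve[d] for d in diam_per_bar])
    per_structure = {"integrin": e_int}
    e_arrays = _enrichment_arrays(channels, n, per_structure)
    cell = np.ones((h, w), dtype=bool)
    wrap = np.ones(n)
    rng = np.random.default_rng(seed)
    out = np.empty((len(channels), h, w), dtype=float)
    for c, ch in enumerate(channels):
        exp = _channel_expectation(ch, zone_idx, end_mask, cell, wrap, e_arrays[ch.role])
        out[c] = _apply_noise(exp, ch.read_noise_sd, rng) if noise else exp

    lattice = LatticeSpec(
        pitch_um=pitch_um,
        origin=(0.75 * pitch_px, 0.75 * pitch_px),
        structure_kind="bar",
        bar_length_um=max(min(d + 1.0, pitch_um - 1.0) for d in diameters),
        bar_width_um=diameters[0],
        pixel_size_um=pixel_size_um,
    )
    gt = GroundTruth(
        lattice=lattice,
        enrichment={ch.role: ch.end_enrichment for ch in channels},
        wrap_factors=wrap,
        node_xy=np.array([(x, y) for x, y, *_ in items]),
        per_structure_enrichment={"integrin": e_int},
        bar_diameters_um=np.array(diam_per_bar),
        seed=seed,
    )
    return out, gt


def render_timelapse(
    lattice: LatticeSpec,
    channels: Sequence[ChannelSpec],
    traces: np.ndarray,
    frame_interval_s: float,
    n_frames: int,
    dynamic_role: str = "poi",
    wrap: WrapField | None = None,
    cell_footprint: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
    noise: bool = True,
    end_cap_um: float = 0.3,
    halo_um: float = 0.2,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a ``(n_frames, n_channels, h, w)`` sequence.

    ``traces[s, t]`` is the enrichment of the dynamic channel at structure
    ``s`` in frame ``t``; static channels repeat their expectation with
    independent noise per frame.
    """
    if n_frames < 2:
        raise RenderError("need n_frames >= 2")
    if frame_interval_s <= 0:
        raise RenderError("frame_interval_s must be > 0")
    if cell_footprint is not None:
        cell = np.asarray(cell_footprint).astype(bool)
        shape = cell.shape
    else:
        if shape is None:
            raise RenderError("either cell_footprint or shape must be given")
        cell = np.ones(shape, dtype=bool)

    nodes = structure_centres(lattice, shape)
    n = len(nodes)
    traces = np.asarray(traces, dtype=float)
    if traces.shape != (n, n_frames):
        raise RenderError(
            f"traces have shape {traces.shape}; expected ({n}, {n_frames}) "
            "(one trace per structure, one value per frame)"
        )
    if wrap is None:
        wrap = WrapField.none(n)

    if lattice.structure_kind == "bar":
        items = [(x, y, "bar", lattice.bar_length_um, lattice.bar_width_um) for x, y in nodes]
    else:
        items = [(x, y, "pillar", 0.0, lattice.pillar_diameter_um) for x, y in nodes]
    zone_idx, end_mask = _paint_structures(
        shape, items, lattice.pixel_size_um, lattice.orientation_deg, end_cap_um, halo_um
    )

    rng = np.random.default_rng(seed)
    out = np.empty((n_frames, len(channels)) + tuple(shape), dtype=float)
    base_e = _enrichment_arrays(channels, n, None)
    for t in range(n_frames):
        for c, ch in enumerate(channels):
            e = traces[:, t] if ch.role == dynamic_role else base_e[ch.role]
            exp = _channel_expectation(
                ch, zone_idx, end_mask, cell, wrap.factors, e, wrap.at_end
            )
            out[t, c] = _apply_noise(exp, ch.read_noise_sd, rng) if noise else exp

    gt = GroundTruth(
        lattice=lattice,
        enrichment={ch.role: ch.end_enrichment for ch in channels},
        wrap_factors=wrap.factors.copy(),
        node_xy=nodes,
        traces=traces.copy(),
        seed=seed,
    )
    return out, gt
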