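"""Ground-truth recovery benchmarks on synthetic fields.

Each function renders a field with the fabricated nanostructure geometry,
runs the full analysis pipeline (lattice detection included) and returns the
recovered quantity next to the planted truth.  These are the recipes behind
the acceptance report and the recovery test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridutil import lattice_nodes
from .ratiometric import (
    background_level,
    classify_enriched,
    end_side_ratios,
    pillar_ratios,
    spearman,
    spearman_at_pillars,
)
from .registration import (
    average_windows,
    derive_bar_rois,
    derive_pillar_rois,
    detect_lattice,
    tile_windows,
)
from .synth import ChannelSpec, LatticeSpec, WrapField, render_structure_field

#: fabricated nanobar array: 200 nm x 2 um bars, 5 um pitch, 0.1 um/px
BAR_LATTICE = LatticeSpec(origin=(30.0, 30.0))
PILLAR_LATTICE = LatticeSpec(
    structure_kind="pillar", pillar_diameter_um=1.0, origin=(30.0, 30.0)
)
PITCH_BAND_UM = (2.0, 10.0)


@dataclass
class EndSideRecovery:
    per_cell_means: np.ndarray
    grand_mean: float
    n_cells: int
    min_bars_per_cell: int
    true_enrichment: float


def _cell_disc(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(yy - h / 2, xx - w / 2) <= 0.46 * min(h, w)


def endside_recovery(
    enrichment: float = 1.0,
    n_cells: int = 10,
    seed: int = 0,
    random_wrap: bool = False,
    shape: tuple[int, int] = (410, 410),
) -> EndSideRecovery:
    """Per-cell membrane-normalised end/side ratios on synthetic cells.

    One imaging field per cell; the full pipeline runs per field: lattice
    detection from the bright-field channel, window tiling restricted to the
    cell footprint, membrane-window averaging, bar ROI derivation,
    background-corrected ratio computation.
    """
    ss = np.random.SeedSequence([seed, 0xBA25])
    cell_seeds = ss.generate_state(2 * n_cells)
    cell = _cell_disc(shape)
    means, n_bars = [], []
    for c in range(n_cells):
        n = len(lattice_nodes(BAR_LATTICE.origin, BAR_LATTICE.pitch_px, 0.0, shape))
        wrap = (
            WrapField.uniform(n, 0.7, 1.3, rng=int(cell_seeds[2 * c + 1]))
            if random_wrap
            else None
        )
        channels = [
            ChannelSpec(role="registration"),
            ChannelSpec(role="membrane", base_intensity=150.0),
            ChannelSpec(role="integrin", base_intensity=200.0, end_enrichment=enrichment),
        ]
        img, _ = render_structure_field(
            BAR_LATTICE, channels, wrap=wrap, cell_footprint=cell,
            seed=int(cell_seeds[2 * c]),
        )
        lat = detect_lattice(img[0], PITCH_BAND_UM, BAR_LATTICE.pixel_size_um)
        wins = tile_windows(lat, shape, cell)
        rois = derive_bar_rois(average_windows(img[1], wins), bar_width_px=2)
        bg = (background_level(img[2], cell), background_level(img[1], cell))
        res = end_side_ratios(img[2], img[1], wins, rois, cell_id=c, background=bg)
        means.append(res.per_cell_mean)
        n_bars.append(len(res.per_bar))
    means = np.asarray(means)
    return EndSideRecovery(
        per_cell_means=means,
        grand_mean=float(means.mean()),
        n_cells=n_cells,
        min_bars_per_cell=int(min(n_bars)),
        true_enrichment=enrichment,
    )


def pitch_recovery(seed: int = 0, shape: tuple[int, int] = (410, 410)) -> float:
    """Detected pitch (um) on a bright-field render of the fabricated array."""
    img, _ = render_structure_field(
        BAR_LATTICE, [ChannelSpec(role="registration")], shape=shape, seed=seed
    )
    lat = detect_lattice(img[0], PITCH_BAND_UM, BAR_LATTICE.pixel_size_um)
    return float(lat.pitch_um)


@dataclass
class EnrichedFractionRecovery:
    detected_fraction: float
    true_fraction: float
    n_pillars: int


def enriched_fraction_recovery(
    true_fraction: float = 0.30,
    e_enriched: float = 2.5,
    seed: int = 0,
    shape: tuple[int, int] = (960, 960),
    threshold: float = 1.5,
) -> EnrichedFractionRecovery:
    """Classify enriched pillars on a field with a planted enriched subset."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9111A5]))
    n = len(lattice_nodes(PILLAR_LATTICE.origin, PILLAR_LATTICE.pitch_px, 0.0, shape))
    n_enriched = int(round(true_fraction * n))
    e = np.ones(n)
    e[rng.choice(n, size=n_enriched, replace=False)] = e_enriched
    channels = [
        ChannelSpec(role="membrane", base_intensity=150.0),
        ChannelSpec(role="integrin", base_intensity=200.0),
    ]
    img, gt = render_structure_field(
        PILLAR_LATTICE, channels, shape=shape, seed=int(rng.integers(2**31)),
        per_structure_E={"integrin": e}, halo_um=0.4,
    )
    lat = detect_lattice(img[0], PITCH_BAND_UM, PILLAR_LATTICE.pixel_size_um)
    wins = tile_windows(lat, shape)
    rois = derive_pillar_rois(wins.side)
    res = pillar_ratios(img[1], img[0], wins, rois, background=(10.0, 10.0))
    _, frac = classify_enriched(res.pillar_norm_ratios, threshold=threshold)
    return EnrichedFractionRecovery(
        detected_fraction=float(frac),
        true_fraction=float(gt.enriched_fraction),
        n_pillars=len(res.pillar_norm_ratios),
    )


@dataclass
class SpearmanRecovery:
    rho: float
    rho_true_sample: float
    n_pillars: int


def spearman_recovery(
    rho_s: float = 0.6,
    n_pillars: int = 353,
    seed: int = 0,
    shape: tuple[int, int] = (990, 990),
) -> SpearmanRecovery:
    """Recover a planted rank correlation between POI and enrichment.

    Per-pillar enrichment and POI level are drawn from a Gaussian copula
    whose normal-score correlation targets the requested Spearman rho.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EA2]))
    n = len(lattice_nodes(PILLAR_LATTICE.origin, PILLAR_LATTICE.pitch_px, 0.0, shape))
    if n < n_pillars:
        raise ValueError(f"field holds only {n} pillars; need {n_pillars}")
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z = rng.multivariate_normal([0, 0], [[1, rho_p], [rho_p, 1]], size=n)
    e_int = np.exp(0.35 * z[:, 0])
    e_poi = np.exp(0.35 * z[:, 1])
    channels = [
        ChannelSpec(role="membrane", base_intensity=150.0),
        ChannelSpec(role="integrin", base_intensity=200.0),
        ChannelSpec(role="poi", base_intensity=150.0),
    ]
    img, _ = render_structure_field(
        PILLAR_LATTICE, channels, shape=shape, seed=int(rng.integers(2**31)),
        per_structure_E={"integrin": e_int, "poi": e_poi}, halo_um=0.4,
    )
    lat = detect_lattice(img[0], PITCH_BAND_UM, PILLAR_LATTICE.pixel_size_um)
    wins = tile_windows(lat, shape)
    # restrict the cell to exactly n_pillars windows
    drop = len(wins) - n_pillars
    if drop > 0:
        wins.in_cell[len(wins) - drop :] = False
    res = spearman_at_pillars(img[2], img[1], img[0], wins, rois=derive_pillar_rois(wins.side),
                              background=(10.0, 10.0, 10.0))
    kept = wins.in_cell_indices()
    truth = spearman(e_poi[kept], e_int[kept])
    return SpearmanRecovery(rho=float(res.rho), rho_true_sample=float(truth), n_pillars=res.n)
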