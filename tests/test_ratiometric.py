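"""End/side and pillar ratiometrics, enrichment classification, Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import known_lattice
from nanocurve.errors import NanocurveError
from nanocurve.gridutil import lattice_nodes
from nanocurve.ratiometric import (
    background_level,
    classify_enriched,
    direct_end_side,
    end_side_ratios,
    gradient_group,
    pillar_ratios,
    spearman,
    spearman_at_pillars,
)
from nanocurve.registration import (
    ROISet,
    WindowSet,
    average_windows,
    derive_bar_rois,
    derive_pillar_rois,
    tile_windows,
)
from nanocurve.synth import ChannelSpec, LatticeSpec, WrapField, render_structure_field

SHAPE = (360, 360)


def _toy_windows_and_rois():
    """A single 5x5 window with hand-drawn 2-pixel end and side masks."""
    wins = WindowSet(
        centres_xy=np.array([[2, 2]]), side=5, in_cell=np.array([True]),
        image_shape=(5, 5),
    )
    end = np.zeros((5, 5), bool)
    side = np.zeros((5, 5), bool)
    end[2, 0] = end[2, 4] = True
    side[1, 2] = side[3, 2] = True
    rois = ROISet(kind="bar", masks={"end": end, "side": side})
    return wins, rois


def test_toy_ratio_norm_hand_arithmetic():
    wins, rois = _toy_windows_and_rois()
    integrin = np.zeros((5, 5))
    membrane = np.zeros((5, 5))
    integrin[rois["end"]] = 20.0
    integrin[rois["side"]] = 10.0
    membrane[rois["end"]] = 12.0
    membrane[rois["side"]] = 12.0
    res = end_side_ratios(integrin, membrane, wins, rois)
    assert res.per_cell_mean == pytest.approx((20 / 10) / (12 / 12))  # = 2.0


def _bar_field(e=1.0, seed=0, wrap=None, noise=True, uneven_ends=False):
    lat = LatticeSpec(origin=(30.0, 30.0))
    n = len(lattice_nodes(lat.origin, lat.pitch_px, 0.0, SHAPE))
    if wrap == "random":
        wrap = WrapField.uniform(n, rng=seed + 500, uneven_ends=uneven_ends)
    chans = [
        ChannelSpec(role="membrane", base_intensity=150.0),
        ChannelSpec(role="integrin", base_intensity=200.0, end_enrichment=e),
    ]
    img, gt = render_structure_field(lat, chans, wrap=wrap, shape=SHAPE,
                                     seed=seed, noise=noise)
    wins = tile_windows(known_lattice(lat), SHAPE)
    rois = derive_bar_rois(average_windows(img[0], wins), bar_width_px=2)
    return img, wins, rois


def test_uniform_truth_gives_one():
    img, wins, rois = _bar_field(e=1.0, seed=1)
    res = end_side_ratios(img[1], img[0], wins, rois, background=(10.0, 10.0))
    assert res.per_cell_mean == pytest.approx(1.0, abs=0.02)


def test_recovers_printed_effect_size():
    means = []
    for seed in range(5):
        img, wins, rois = _bar_field(e=1.9, seed=seed, wrap="random")
        res = end_side_ratios(img[1], img[0], wins, rois, background=(10.0, 10.0))
        means.append(res.per_cell_mean)
    assert np.mean(means) == pytest.approx(1.9, abs=0.05)


@pytest.mark.parametrize("e", [1.0, 1.5, 2.0, 3.0])
def test_parameter_recovery_within_tenth(e):
    # >= 20 bars/cell, 10 cells, default noise, fixed seeds
    means = []
    for seed in range(10):
        img, wins, rois = _bar_field(e=e, seed=seed + int(10 * e), wrap="random")
        res = end_side_ratios(img[1], img[0], wins, rois, background=(10.0, 10.0))
        assert len(res.per_bar) >= 20
        means.append(res.per_cell_mean)
    assert abs(np.mean(means) - e) < 0.1


def test_wrap_confound_cancels_only_in_normalized_ratio():
    # uneven end-wrapping biases the direct ratio but not the normalised one
    img, wins, rois = _bar_field(e=2.0, seed=3, wrap="random", noise=False,
                                 uneven_ends=True)
    norm = end_side_ratios(img[1], img[0], wins, rois, background=(10.0, 10.0))
    direct = direct_end_side(img[1], wins, rois, background=10.0)
    assert norm.per_cell_mean == pytest.approx(2.0, abs=1e-6)
    per_bar_direct = direct.per_bar.ratio_raw.to_numpy()
    assert np.std(per_bar_direct) > 0.05  # biased bar-to-bar by the wrap


def test_direct_end_side_uniform_and_exact():
    img, wins, rois = _bar_field(e=1.0, seed=0, noise=False)
    res = direct_end_side(img[1], wins, rois, background=10.0)
    assert res.per_cell_mean == pytest.approx(1.0)
    img, wins, rois = _bar_field(e=2.0, seed=0, noise=False)
    res = direct_end_side(img[1], wins, rois, background=10.0)
    assert res.per_cell_mean == pytest.approx(2.0)


def test_nonpositive_side_mean_excluded():
    wins, rois = _toy_windows_and_rois()
    channel = np.zeros((5, 5))
    channel[rois["end"]] = 5.0  # side stays 0 -> excluded after bg subtraction
    with pytest.raises(NanocurveError):
        direct_end_side(channel, wins, rois, background=1.0)


def test_background_level_is_cell_free_median():
    img = np.full((10, 10), 7.0)
    cell = np.zeros((10, 10), bool)
    cell[:5] = True
    img[cell] = 100.0
    assert background_level(img, cell) == 7.0


# --- gradient grouping ------------------------------------------------------


def test_gradient_group_counts_and_oracle():
    rng = np.random.default_rng(0)
    rows = []
    for f in range(8):
        for d in [0.1, 0.5, 1.0, 2.0, 3.0, 5.0]:
            for _ in range(4):
                rows.append({"field": f, "diameter_um": d,
                             "ratio_norm": rng.uniform(0.5, 3.0)})
    df = pd.DataFrame(rows)
    out = gradient_group(df)
    assert len(out) == 48  # 6 diameters x 8 fields
    # independent aggregation oracle
    for _, r in out.iterrows():
        sel = df[(df.field == r.field) & (df.diameter_um == r.diameter_um)]
        assert r.ratio_norm == pytest.approx(sel.ratio_norm.sum() / len(sel))


def test_gradient_group_constant_input():
    df = pd.DataFrame(
        {"field": [0, 0, 1, 1], "diameter_um": [1.0, 1.0, 1.0, 1.0],
         "ratio_norm": [2.0] * 4}
    )
    out = gradient_group(df)
    assert (out.ratio_norm == 2.0).all()


# --- pillar ratios ----------------------------------------------------------


def _pillar_field(per_e=None, seed=0, shape=(460, 460), noise=True):
    lat = LatticeSpec(structure_kind="pillar", pillar_diameter_um=1.0, origin=(30.0, 30.0))
    chans = [
        ChannelSpec(role="membrane", base_intensity=150.0),
        ChannelSpec(role="integrin", base_intensity=200.0),
    ]
    kw = {"per_structure_E": {"integrin": per_e}} if per_e is not None else {}
    img, gt = render_structure_field(lat, chans, shape=shape, seed=seed,
                                     noise=noise, halo_um=0.4, **kw)
    wins = tile_windows(known_lattice(lat), shape)
    rois = derive_pillar_rois(wins.side)
    return img, gt, wins, rois


def test_uniform_pillars_norm_ratio_one():
    img, _, wins, rois = _pillar_field(noise=False)
    res = pillar_ratios(img[1], img[0], wins, rois, background=(10.0, 10.0))
    assert np.allclose(res.per_roi.norm_ratio, 1.0)


def test_norm_ratio_mean_is_exactly_one():
    img, _, wins, rois = _pillar_field(seed=2)
    res = pillar_ratios(img[1], img[0], wins, rois)
    assert res.per_roi.norm_ratio.mean() == pytest.approx(1.0, abs=1e-12)


def test_two_pillar_toy_normalization_by_hand():
    pillar = np.zeros((5, 5), bool)
    pillar[2, 2] = True
    annulus = np.zeros((5, 5), bool)
    annulus[0, 0] = True
    rois = ROISet(kind="pillar", masks={"pillar": pillar, "annulus": annulus})
    img_i = np.zeros((9, 18))
    img_m = np.ones((9, 18))
    wins = WindowSet(centres_xy=np.array([[2, 2], [11, 2]]), side=5,
                     in_cell=np.ones(2, bool), image_shape=(9, 18))
    # pillar ratios 6 and 2; annulus ratios 1 and 1 -> mean 2.5
    img_i[2, 2] = 6.0
    img_i[2, 11] = 2.0
    img_i[0, 0] = img_i[0, 9] = 1.0
    res = pillar_ratios(img_i, img_m, wins, rois, min_pillars=2)
    got = dict(zip(zip(res.per_roi.window, res.per_roi.roi_type), res.per_roi.norm_ratio))
    assert got[(0, "pillar")] == pytest.approx(6 / 2.5)
    assert got[(1, "pillar")] == pytest.approx(2 / 2.5)


def test_min_pillar_count_enforced():
    img, _, wins, rois = _pillar_field()
    with pytest.raises(NanocurveError):
        pillar_ratios(img[1], img[0], wins, rois, min_pillars=10_000)


# --- enrichment classification ---------------------------------------------


def test_enriched_fraction_recovery_30pct():
    rng = np.random.default_rng(42)
    e = np.where(rng.random(81) < 0.3, 2.5, 1.0)  # 9x9 nodes in a 460 px field
    img, gt, wins, rois = _pillar_field(per_e=e, seed=7)
    res = pillar_ratios(img[1], img[0], wins, rois)
    _, frac = classify_enriched(res.pillar_norm_ratios)
    assert abs(frac - gt.enriched_fraction) < 0.05


def test_uniform_field_fraction_zero():
    img, _, wins, rois = _pillar_field(seed=1)
    res = pillar_ratios(img[1], img[0], wins, rois)
    _, frac = classify_enriched(res.pillar_norm_ratios)
    assert frac == 0.0


def test_threshold_sweep_matches_roc_oracle():
    rng = np.random.default_rng(3)
    e = np.where(rng.random(81) < 0.4, 2.5, 1.0)
    img, gt, wins, rois = _pillar_field(per_e=e, seed=5)
    res = pillar_ratios(img[1], img[0], wins, rois)
    ratios = res.pillar_norm_ratios
    truth = gt.per_structure_enrichment["integrin"] > 1.0
    for t in np.linspace(0.5, 2.5, 9):
        flags, _ = classify_enriched(ratios, threshold=t)
        # exhaustive label-comparison oracle
        tp = fp = 0
        for f, tr in zip(flags, truth):
            tp += f and tr
            fp += f and not tr
        assert flags[truth].sum() == tp
        assert flags[~truth].sum() == fp


# --- Spearman ---------------------------------------------------------------


def test_spearman_increasing_is_one():
    assert spearman(np.arange(10), np.arange(10) ** 2) == pytest.approx(1.0)


def test_spearman_six_point_rank_formula():
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 6.0])
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = 6
    d2 = np.sum((rx - ry) ** 2)
    expected = 1 - 6 * d2 / (n * (n**2 - 1))
    assert spearman(x, y) == pytest.approx(expected)


def test_spearman_all_5_permutations_vs_formula():
    x = np.arange(5)
    for perm in itertools.permutations(range(5)):
        y = np.array(perm, dtype=float)
        d2 = np.sum((x - y) ** 2)
        expected = 1 - 6 * d2 / (5 * 24)
        assert spearman(x, y) == pytest.approx(expected)


def test_spearman_constant_is_none():
    assert spearman(np.ones(10), np.arange(10)) is None


def test_spearman_at_pillars_recovers_planted_correlation():
    rng = np.random.default_rng(11)
    n = 81
    rho_p = 2 * np.sin(np.pi * 0.6 / 6)  # Gaussian copula for Spearman 0.6
    cov = [[1, rho_p], [rho_p, 1]]
    z = rng.multivariate_normal([0, 0], cov, size=n)
    e_int = np.exp(0.35 * z[:, 0])
    e_poi = np.exp(0.35 * z[:, 1])
    lat = LatticeSpec(structure_kind="pillar", pillar_diameter_um=1.0, origin=(30.0, 30.0))
    chans = [
        ChannelSpec(role="membrane", base_intensity=150.0),
        ChannelSpec(role="integrin", base_intensity=200.0),
        ChannelSpec(role="poi", base_intensity=150.0),
    ]
    img, _ = render_structure_field(
        lat, chans, shape=(460, 460), seed=9, halo_um=0.4,
        per_structure_E={"integrin": e_int, "poi": e_poi},
    )
    wins = tile_windows(known_lattice(lat), (460, 460))
    rois = derive_pillar_rois(wins.side)
    res = spearman_at_pillars(img[2], img[1], img[0], wins, rois)
    truth = spearman(e_poi, e_int)
    assert res.n == 81
    assert res.rho == pytest.approx(truth, abs=0.1)
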