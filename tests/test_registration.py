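"""Lattice detection, window tiling, averaging and ROI geometry."""

import numpy as np
import pytest

from conftest import known_lattice, n_nodes
from nanocurve.errors import LatticeError, NotABarError
from nanocurve.registration import (
    NanostructureLattice,
    average_windows,
    derive_bar_rois,
    derive_pillar_rois,
    detect_lattice,
    tile_windows,
)
from nanocurve.synth import ChannelSpec, LatticeSpec, render_structure_field

SHAPE = (360, 360)


def _registration_image(seed=0, noise=True, shape=SHAPE, origin=(30.0, 30.0)):
    lat = LatticeSpec(origin=origin)
    img, _ = render_structure_field(
        lat, [ChannelSpec(role="registration")], shape=shape, seed=seed, noise=noise
    )
    return img[0], lat


class TestDetectLattice:
    def test_exact_grid_noiseless(self):
        img, lat = _registration_image(noise=False)
        det = detect_lattice(img, (2, 10), 0.1)
        assert det.pitch_um / det.pixel_size_um == pytest.approx(50.0, abs=0.05)
        assert min(det.orientation_deg, 90 - det.orientation_deg) == pytest.approx(0, abs=0.2)
        assert det.residual_um < 0.01

    def test_fabricated_geometry_pitch_5um(self):
        img, _ = _registration_image(seed=4)
        det = detect_lattice(img, (2, 10), 0.1)
        assert det.pitch_um == pytest.approx(5.0, abs=0.05)

    def test_toy_autocorrelation_oracle(self):
        # 32x32 image with point rows at pitch 8; brute-force autocorrelation
        # over all integer shifts must peak at the same pitch
        img = np.zeros((32, 32))
        for y in range(4, 32, 8):
            for x in range(4, 32, 8):
                img[y, x] = 1.0
        z = img - img.mean()
        best, best_v = None, -np.inf
        for dy in range(32):
            for dx in range(32):
                if dy == dx == 0:
                    continue
                v = np.sum(z * np.roll(np.roll(z, dy, axis=0), dx, axis=1))
                r = np.hypot(min(dy, 32 - dy), min(dx, 32 - dx))
                if 4 <= r <= 12 and v > best_v:
                    best_v, best = v, r
        det = detect_lattice(img, (4 * 0.1, 12 * 0.1), 0.1)
        assert det.pitch_um / 0.1 == pytest.approx(best, abs=0.3)

    def test_translation_equivariance(self):
        img, _ = _registration_image(noise=False)
        det0 = detect_lattice(img, (2, 10), 0.1)
        dy, dx = 7, 13
        det1 = detect_lattice(np.roll(np.roll(img, dy, axis=0), dx, axis=1), (2, 10), 0.1)
        assert det1.pitch_um == pytest.approx(det0.pitch_um, abs=0.01)
        p = det0.pitch_um / det0.pixel_size_um
        ddx = (det1.origin_xy[0] - det0.origin_xy[0] - dx) % p
        ddy = (det1.origin_xy[1] - det0.origin_xy[1] - dy) % p
        assert min(ddx, p - ddx) < 0.2
        assert min(ddy, p - ddy) < 0.2

    @pytest.mark.parametrize("seed", range(5))
    def test_pitch_recovery_half_pixel_at_snr5(self, seed):
        # base/read noise tuned so the structure SNR is ~5
        lat = LatticeSpec(origin=(27.0, 33.0))
        ch = [ChannelSpec(role="registration", base_intensity=25.0, background=10.0,
                          read_noise_sd=4.0)]
        img, _ = render_structure_field(lat, ch, shape=SHAPE, seed=seed)
        det = detect_lattice(img[0], (2, 10), 0.1)
        assert abs(det.pitch_um / 0.1 - 50.0) < 0.5

    def test_no_lattice_raises(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 5, SHAPE)
        with pytest.raises(LatticeError, match="no lattice"):
            detect_lattice(img, (2, 10), 0.1)

    def test_detects_pillars_from_membrane_image(self, pillar_lattice):
        img, _ = render_structure_field(
            pillar_lattice, [ChannelSpec(role="membrane", base_intensity=150.0)],
            shape=SHAPE, seed=2,
        )
        det = detect_lattice(img[0], (2, 10), 0.1)
        assert det.pitch_um == pytest.approx(5.0, abs=0.05)


class TestTileWindows:
    def test_window_count_100(self):
        lat = NanostructureLattice((25.0, 25.0), 5.0, 0.0, 0.1)
        wins = tile_windows(lat, (500, 500))
        assert len(wins) == 100
        assert wins.side == 49  # largest odd side below the 50 px pitch

    def test_half_cell_flags_half(self, cell_disc):
        lat = NanostructureLattice((25.0, 25.0), 5.0, 0.0, 0.1)
        cell = np.zeros((500, 500), bool)
        cell[:, :250] = True  # left half
        wins = tile_windows(lat, (500, 500), cell)
        frac = wins.in_cell.mean()
        assert 0.35 <= frac <= 0.55

    def test_per_cell_bar_counts_in_paper_range(self, cell_disc):
        # tens-to-hundreds of structures per cell
        lat = NanostructureLattice((30.0, 30.0), 5.0, 0.0, 0.1)
        cell = cell_disc((410, 410))
        wins = tile_windows(lat, (410, 410), cell)
        assert 26 <= wins.in_cell.sum() <= 158

    def test_zero_windows_raises(self):
        lat = NanostructureLattice((25.0, 25.0), 5.0, 0.0, 0.1)
        with pytest.raises(LatticeError):
            tile_windows(lat, (30, 30))


class TestAverageWindows:
    def test_identical_windows_average_equals_one(self, bar_lattice):
        img, _ = render_structure_field(
            bar_lattice, [ChannelSpec(role="membrane")], shape=SHAPE, noise=False
        )
        wins = tile_windows(known_lattice(bar_lattice), SHAPE)
        avg = average_windows(img[0], wins)
        assert np.allclose(avg, wins.extract(img[0], 0))

    def test_noise_reduction_sqrt_n(self, bar_lattice):
        # average of N iid-noise windows has sd ~ sigma/sqrt(N)
        rng = np.random.default_rng(1)
        sigma = 5.0
        img = rng.normal(100.0, sigma, SHAPE)
        wins = tile_windows(known_lattice(bar_lattice), SHAPE)
        avg = average_windows(img, wins)
        expected = sigma / np.sqrt(len(wins.in_cell_indices()))
        assert np.std(avg) == pytest.approx(expected, rel=0.2)


class TestBarROIs:
    @pytest.fixture
    def avg_window(self, bar_lattice):
        img, _ = render_structure_field(
            bar_lattice, [ChannelSpec(role="membrane", base_intensity=150.0)],
            shape=SHAPE, seed=0,
        )
        wins = tile_windows(known_lattice(bar_lattice), SHAPE)
        return average_windows(img[0], wins)

    def test_masks_disjoint_and_symmetric(self, avg_window):
        rois = derive_bar_rois(avg_window, bar_width_px=2)
        end, side = rois["end"], rois["side"]
        assert not (end & side).any()
        # bar along x: both masks symmetric under the two mirror symmetries
        assert np.array_equal(end, end[::-1, :])
        assert np.array_equal(end, end[:, ::-1])
        assert np.array_equal(side, side[::-1, :])
        assert np.array_equal(side, side[:, ::-1])

    def test_translated_masks_hit_every_bar(self, bar_lattice):
        img, gt = render_structure_field(
            bar_lattice,
            [ChannelSpec(role="membrane", base_intensity=150.0),
             ChannelSpec(role="integrin", end_enrichment=2.0, background=0.0)],
            shape=SHAPE, noise=False,
        )
        wins = tile_windows(known_lattice(bar_lattice), SHAPE)
        rois = derive_bar_rois(average_windows(img[0], wins), bar_width_px=2)
        for k in wins.in_cell_indices():
            win = wins.extract(img[1], k)
            assert win[rois["end"]].mean() == pytest.approx(400.0)
            assert win[rois["side"]].mean() == pytest.approx(200.0)

    def test_toy_footprint_pixel_predicate_oracle(self):
        # hand-drawn 21x21 bar footprint along x, width 3, length 15
        win = np.zeros((21, 21))
        win[9:12, 3:18] = 100.0
        cap_depth, flank = 2, 1
        rois = derive_bar_rois(win, cap_depth=cap_depth, flank_width=flank)
        fp = win > 50.0
        # oracle: exhaustive per-pixel membership from the known geometry
        for y in range(21):
            for x in range(21):
                in_fp = bool(fp[y, x])
                t = abs(x - 10)  # axial distance from the bar centre
                half_t = 7
                cap_zone = in_fp and t >= half_t - cap_depth
                # end mask: caps dilated by flank (axially/laterally), in footprint
                near_cap = in_fp and any(
                    fp[yy, xx] and abs(xx - 10) >= half_t - cap_depth
                    for yy in range(max(0, y - flank), min(21, y + flank + 1))
                    for xx in range(max(0, x - flank), min(21, x + flank + 1))
                    if (yy - y) ** 2 + (xx - x) ** 2 <= flank**2
                )
                side_zone = in_fp and t <= half_t - cap_depth - 2 * flank
                assert rois["end"][y, x] == (cap_zone or near_cap), (x, y)
                assert rois["side"][y, x] == side_zone, (x, y)

    def test_disc_footprint_rejected(self):
        win = np.zeros((31, 31))
        yy, xx = np.mgrid[0:31, 0:31]
        win[np.hypot(yy - 15, xx - 15) <= 8] = 100.0
        with pytest.raises(NotABarError, match="not a bar"):
            derive_bar_rois(win)


class TestPillarROIs:
    def test_default_9_20_counts_match_enumeration(self):
        rois = derive_pillar_rois(49)
        # brute-force distance enumeration over the window
        n_pillar = n_annulus = 0
        for y in range(49):
            for x in range(49):
                d = np.hypot(y - 24, x - 24)
                n_pillar += d <= 9
                n_annulus += 9 < d <= 20
        assert rois["pillar"].sum() == n_pillar
        assert rois["annulus"].sum() == n_annulus

    def test_r_in_zero_single_pixel(self):
        rois = derive_pillar_rois(49, r_in=0, r_out=20)
        assert rois["pillar"].sum() == 1

    def test_invalid_radii_rejected(self):
        with pytest.raises(LatticeError):
            derive_pillar_rois(49, r_in=20, r_out=9)

    def test_masks_partition(self):
        rois = derive_pillar_rois(49)
        assert not (rois["pillar"] & rois["annulus"]).any()
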