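import numpy as np
import pytest

from conftest import brute_force_local_thickness
from follimech.synthetic import simulate_oct_volume
from follimech.oct_morphometry import (GeometryError, SegmentationError,
                                       SegmentationMasks, extract_midplane,
                                       local_thickness_map,
                                       relative_antrum_volume, segment_volume,
                                       thickness_distribution)


def nested_sphere_volume(r_in, r_out, voxel=3.0, levels=(0.08, 1.0)):
    """Hard two-intensity shell (no smoothing, no noise)."""
    half = int(np.ceil(r_out / voxel)) + 4
    n = 2 * half + 1
    idx = (np.arange(n) - half) * voxel
    rho = np.sqrt(idx[:, None, None] ** 2 + idx[None, :, None] ** 2
                  + idx[None, None, :] ** 2)
    vol = np.full((n, n, n), levels[0], dtype=float)
    vol[(rho <= r_out) & (rho > r_in)] = levels[1]
    return vol, (rho <= r_out) & (rho > r_in), rho <= r_in


class TestSegmentVolume:
    def test_exact_thresholds_exact_masks(self):
        vol, wall_true, antrum_true = nested_sphere_volume(100, 200)
        masks = segment_volume(vol, voxel_size=3.0, thresholds=(0.3, 0.5),
                               smooth_sigma=0)
        np.testing.assert_array_equal(masks.wall, wall_true)
        np.testing.assert_array_equal(masks.antrum, antrum_true)

    def test_noiseless_phantom_coc_exact(self, oct_phantom_noiseless):
        ph = oct_phantom_noiseless
        masks = segment_volume(ph, thresholds=(0.3, 0.75), smooth_sigma=0)
        # COC voxels are the truth blob up to the anti-aliased rim
        inter = masks.coc & ph.truth["coc_mask"]
        dice = 2 * inter.sum() / (masks.coc.sum() + ph.truth["coc_mask"].sum())
        assert dice > 0.95

    def test_default_noise_wall_dice(self, oct_phantom_noisy):
        ph = oct_phantom_noisy
        masks = segment_volume(ph)
        inter = masks.wall & ph.truth["wall_mask"]
        dice = 2 * inter.sum() / (masks.wall.sum() + ph.truth["wall_mask"].sum())
        assert dice >= 0.95

    def test_no_cavity_raises(self):
        solid = np.full((20, 20, 20), 0.1)
        solid[5:15, 5:15, 5:15] = 1.0  # solid bright block, no cavity
        with pytest.raises(SegmentationError):
            segment_volume(solid, voxel_size=3.0, thresholds=(0.3, 0.5),
                           smooth_sigma=0)

    def test_masks_disjoint_invariant(self, oct_phantom_noisy):
        masks = segment_volume(oct_phantom_noisy)
        assert not (masks.wall & masks.antrum).any()
        assert not (masks.wall & masks.coc).any()
        assert not (masks.antrum & masks.coc).any()


class TestRelativeAntrumVolume:
    def test_nested_sphere_analytic_ratio(self):
        vol, *_ = nested_sphere_volume(100, 200)
        masks = segment_volume(vol, voxel_size=3.0, thresholds=(0.3, 0.5),
                               smooth_sigma=0)
        assert relative_antrum_volume(masks) == pytest.approx(1 / 7, rel=0.02)

    def test_empty_antrum_gives_zero(self):
        vol, wall, antrum = nested_sphere_volume(100, 200)
        masks = SegmentationMasks(wall=wall, antrum=np.zeros_like(wall),
                                  coc=np.zeros_like(wall), voxel_size=3.0)
        assert relative_antrum_volume(masks) == 0.0

    def test_empty_wall_raises(self):
        empty = np.zeros((4, 4, 4), bool)
        masks = SegmentationMasks(wall=empty, antrum=empty, coc=empty,
                                  voxel_size=1.0)
        with pytest.raises(ZeroDivisionError):
            relative_antrum_volume(masks)

    def test_ratio_invariant_under_grid_refinement(self):
        """Dimensionless ratio is stable under proportional voxel
        rescaling, and the discretization error shrinks with voxel
        size on the analytic shell."""
        errors = []
        for voxel in (6.0, 4.0, 2.0):
            vol, *_ = nested_sphere_volume(100, 200, voxel=voxel)
            masks = segment_volume(vol, voxel_size=voxel,
                                   thresholds=(0.3, 0.5), smooth_sigma=0)
            errors.append(abs(relative_antrum_volume(masks) - 1 / 7))
        assert errors[2] < errors[0]


class TestExtractMidplane:
    def test_equatorial_annulus_and_radius(self):
        vol, *_ = nested_sphere_volume(100, 200)
        masks = segment_volume(vol, voxel_size=3.0, thresholds=(0.3, 0.5),
                               smooth_sigma=0)
        mid = extract_midplane(masks)
        assert mid.radius_um == pytest.approx(200.0, rel=0.02)
        assert (mid.cross_section_mask == 2).any()  # enclosed cavity

    def test_translation_invariance(self):
        vol, *_ = nested_sphere_volume(80, 150, voxel=3.0)
        masks = segment_volume(vol, voxel_size=3.0, thresholds=(0.3, 0.5),
                               smooth_sigma=0)
        r0 = extract_midplane(masks).radius_um
        shifted = np.roll(vol, (4, -4, 3), axis=(0, 1, 2))
        masks2 = segment_volume(shifted, voxel_size=3.0, thresholds=(0.3, 0.5),
                                smooth_sigma=0)
        assert extract_midplane(masks2).radius_um == pytest.approx(r0, rel=1e-6)

    def test_open_annulus_raises(self):
        wall = np.zeros((9, 32, 32), bool)
        wall[4, 10:20, 10:12] = True  # a bar, not a ring
        masks = SegmentationMasks(wall=wall, antrum=np.zeros_like(wall),
                                  coc=np.zeros_like(wall), voxel_size=1.0)
        with pytest.raises(GeometryError):
            extract_midplane(masks)


def annulus_mask(r_out_px, r_in_px, size=None):
    size = size or int(2 * r_out_px + 8)
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size]
    rho = np.hypot(yy - c, xx - c)
    return (rho <= r_out_px) & (rho > r_in_px)


class TestLocalThickness:
    def test_solid_disk_thickness_is_diameter(self):
        mask = annulus_mask(25, -1, size=65)  # solid disk, diameter 50 px
        th = local_thickness_map(mask)
        # interior pixels are covered by the single largest inscribed
        # disk, so thickness equals the diameter (to rasterization)
        c = 32
        yy, xx = np.mgrid[0:65, 0:65]
        interior = np.hypot(yy - c, xx - c) <= 15
        vals = th[interior]
        assert np.ptp(vals) == 0  # constant over the interior
        assert vals[0] == pytest.approx(50.0, abs=2.0)

    def test_annulus_thickness_is_width(self):
        mask = annulus_mask(60, 50)  # 10 px wall
        th = local_thickness_map(mask)
        assert np.median(th[mask]) == pytest.approx(10.0, abs=1.0)

    @pytest.mark.parametrize("builder", [
        lambda: annulus_mask(20, 14, size=48),
        lambda: annulus_mask(12, -1, size=30),
        lambda: np.random.default_rng(3).random((40, 40)) > 0.4,
        lambda: np.pad(np.ones((5, 30), bool), 4),
    ])
    def test_exact_agreement_with_exhaustive_oracle(self, builder):
        """Disk-propagation result equals the all-pairs inscribed-disk
        oracle exactly on masks up to 64x64."""
        mask = builder()
        if not mask.any():
            pytest.skip("degenerate random mask")
        got = local_thickness_map(mask)
        want = brute_force_local_thickness(mask)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_pixel_size_scaling(self):
        mask = annulus_mask(20, 14, size=48)
        np.testing.assert_allclose(local_thickness_map(mask, 3.0),
                                   3.0 * local_thickness_map(mask, 1.0))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            local_thickness_map(np.zeros((8, 8), bool))


class TestThicknessDistribution:
    def test_constant_annulus_single_mode(self):
        th = np.zeros((32, 32))
        th[10:20, 10:20] = 40.0
        d = thickness_distribution(th, bin_width=5.0)
        assert d.weighted_mean == pytest.approx(40.0)
        assert (d.weights > 0).sum() == 1
        assert d.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_region_hand_arithmetic(self):
        """75% of pixels at 40 um and 25% at 100 um average to 55 um."""
        th = np.zeros((20, 20))
        th[:15] = 40.0
        th[15:20] = 100.0
        d = thickness_distribution(th)
        assert d.weighted_mean == pytest.approx(0.75 * 40 + 0.25 * 100)

    def test_mean_invariant_to_bin_width(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(10, 80, size=(30, 30))
        means = {thickness_distribution(th, bw).weighted_mean
                 for bw in (1.0, 5.0, 13.0)}
        assert len(means) == 1


class TestTimepointOrdering:
    def test_thickness_sequence_on_default_phantoms(self):
        """Mean measured thickness follows 0 h ~ 4 h > 8 h > 11 h on
        default presets (global wall thinning as the antrum expands),
        and the antrum ratio increases 0 -> 11 h."""
        from follimech.presets import make_preset

        thick, ratio = [], []
        for tp in (0, 4, 8, 11):
            preset = make_preset("young", tp)
            t_vals, r_vals = [], []
            for seed in range(2):
                ph = simulate_oct_volume(preset, seed=seed)
                masks = segment_volume(ph)
                mid = extract_midplane(masks)
                lt = local_thickness_map(mid.cross_section_mask == 1,
                                         mid.pixel_size)
                t_vals.append(thickness_distribution(lt).weighted_mean)
                r_vals.append(relative_antrum_volume(masks))
            thick.append(np.mean(t_vals))
            ratio.append(np.mean(r_vals))
        assert thick[0] > thick[2] > thick[3]
        assert thick[1] > thick[2]
        assert ratio == sorted(ratio)
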