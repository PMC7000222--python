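"""Shape-change metrics, boundary velocity and the activity–motility relation."""

import numpy as np
import pytest

from conftest import disk_mask
from fretscope import (DataError, SceneConfig, build_mask,
                       boundary_velocity_map, compute_fret_index,
                       fractional_changes, generate_scene,
                       motility_fret_correlation, near_membrane_signal)
from fretscope.morphodynamics import BoundaryMotilityMap
from fretscope.segmentation import CellMaskStack


def rect_mask(n_pixels: int, shape=(32, 32)) -> np.ndarray:
    """Rectangle of exactly n_pixels (rows of 10)."""
    m = np.zeros(shape, dtype=bool)
    rows, rem = divmod(n_pixels, 10)
    m[2:2 + rows, 2:12] = True
    if rem:
        m[2 + rows, 2:2 + rem] = True
    return m


class TestFractionalChanges:
    def test_area_sequence_example(self):
        # areas 100, 110, 90 → (10 + 20)/100/2 = 0.15
        masks = CellMaskStack(masks=np.stack([rect_mask(100), rect_mask(110),
                                              rect_mask(90)]))
        res = fractional_changes(masks)
        np.testing.assert_array_equal(res.areas_px2, [100, 110, 90])
        assert res.mean_fractional_area_change == pytest.approx(0.15)

    def test_static_masks_give_zero(self):
        m = disk_mask(12)
        res = fractional_changes(CellMaskStack(masks=np.stack([m, m, m])))
        assert res.mean_fractional_area_change == 0.0
        assert res.mean_fractional_perimeter_change == 0.0

    def test_growing_disk_matches_analytic(self):
        # lattice-disk areas track πr² to ≲1% at r ≥ 20
        masks = CellMaskStack(masks=np.stack(
            [disk_mask(r, (96, 96)) for r in (20, 22, 24)]))
        res = fractional_changes(masks)
        analytic = (np.pi * (22**2 - 20**2) + np.pi * (24**2 - 22**2)) \
            / (np.pi * 20**2) / 2
        assert res.mean_fractional_area_change == pytest.approx(analytic,
                                                                rel=0.03)

    def test_frame_reversal_renormalization_identity(self):
        masks = [rect_mask(n) for n in (100, 130, 90, 115)]
        fwd = fractional_changes(CellMaskStack(masks=np.stack(masks)))
        rev = fractional_changes(CellMaskStack(masks=np.stack(masks[::-1])))
        # Σ|ΔA| is reversal-invariant; only the A₁ normalization changes
        assert rev.mean_fractional_area_change * masks[-1].sum() == \
            pytest.approx(fwd.mean_fractional_area_change * masks[0].sum())

    def test_single_frame_rejected(self):
        with pytest.raises(DataError):
            fractional_changes(CellMaskStack(masks=rect_mask(100)[None]))


class TestBoundaryVelocity:
    def test_static_mask_zero_velocity(self):
        m = disk_mask(15)
        mm = boundary_velocity_map(CellMaskStack(masks=np.stack([m, m])))
        assert np.abs(mm.velocity_um_per_min).max() < 0.05

    def test_growing_disk_velocity_magnitude(self):
        # 1 px/frame at 0.2 µm/px, 2 frames/min → 0.4 µm/min, protrusion sign
        masks = CellMaskStack(masks=np.stack(
            [disk_mask(r, (96, 96)) for r in (20, 21, 22)]))
        mm = boundary_velocity_map(masks)
        assert np.all(mm.velocity_um_per_min > 0)
        assert mm.velocity_um_per_min.mean() == pytest.approx(0.4, rel=0.10)

    def test_shrinking_disk_is_retraction(self):
        masks = CellMaskStack(masks=np.stack(
            [disk_mask(r, (96, 96)) for r in (22, 21, 20)]))
        mm = boundary_velocity_map(masks)
        assert np.all(mm.velocity_um_per_min < 0)

    def test_motility_is_modulus(self):
        masks = CellMaskStack(masks=np.stack(
            [disk_mask(r, (96, 96)) for r in (22, 21, 22)]))
        mm = boundary_velocity_map(masks)
        np.testing.assert_array_equal(mm.motility_um_per_min,
                                      np.abs(mm.velocity_um_per_min))
        with pytest.raises(DataError):
            BoundaryMotilityMap(velocity_um_per_min=np.ones((4, 2)),
                                motility_um_per_min=np.zeros((4, 2)))

    def test_protruding_sector_localized(self):
        base = disk_mask(18, (96, 96))
        grown = base.copy()
        yy, xx = np.mgrid[:96, :96]
        ang = np.arctan2(yy - 47.5, xx - 47.5)
        wedge = (np.abs(np.angle(np.exp(1j * ang))) < np.pi / 6)
        grown |= wedge & (np.hypot(yy - 47.5, xx - 47.5) <= 22)
        mm = boundary_velocity_map(CellMaskStack(masks=np.stack([base, grown])))
        v = mm.velocity_um_per_min[:, 0]
        moved = np.abs(v) > 0.2
        assert 0 < moved.sum() < len(v) / 2


class TestNearMembraneSignal:
    def test_uniform_intensity_gives_uniform_grid(self):
        m = disk_mask(18, (64, 64))
        masks = CellMaskStack(masks=m[None])
        sig = near_membrane_signal(np.where(m, 5.0, 0.0)[None], masks)
        np.testing.assert_allclose(sig[~np.isnan(sig)], 5.0, atol=0.5)

    def test_subpixel_depth_rejected(self):
        masks = CellMaskStack(masks=disk_mask(10)[None])
        with pytest.raises(DataError):
            near_membrane_signal(np.ones((1, 64, 64)), masks, depth_um=0.1)


class TestMotilityCorrelation:
    def make_map(self, signal, motility):
        return BoundaryMotilityMap(velocity_um_per_min=motility,
                                   motility_um_per_min=np.abs(motility),
                                   near_membrane_signal=signal)

    def test_exact_cubic_on_bin_centers_recovered(self):
        centers = np.array([1.5, 4.5, 7.5, 10.5, 13.5])
        y0, a, b, c = 0.3, -0.05, 0.01, -0.0002
        motility = y0 + a * centers + b * centers**2 + c * centers**3
        mmap = self.make_map(centers[:, None], np.abs(motility)[:, None] * 0
                             + motility[:, None])
        corr = motility_fret_correlation(mmap)
        np.testing.assert_allclose(corr.cubic_coefficients, (y0, a, b, c),
                                   atol=1e-9)
        assert corr.fit_r2 == pytest.approx(1.0)

    def test_constant_motility_r2_zero_by_convention(self):
        signal = np.array([[1.0, 4.0, 7.0, 10.0, 13.0]])
        motility = np.full_like(signal, 0.25)
        corr = motility_fret_correlation(self.make_map(signal, motility))
        assert corr.fit_r2 == 0.0
        np.testing.assert_allclose(corr.mean_motility_per_bin, 0.25)

    def test_bins_are_width_three_left_closed(self):
        signal = np.array([[2.9, 3.0, 5.9, 6.0]])
        motility = np.array([[1.0, 2.0, 3.0, 4.0]])
        corr = motility_fret_correlation(self.make_map(signal, motility))
        # 2.9→[0,3); 3.0 and 5.9→[3,6); 6.0→[6,9)
        np.testing.assert_array_equal(corr.n_per_bin, [1, 2, 1])
        np.testing.assert_allclose(corr.mean_motility_per_bin,
                                   [1.0, 2.5, 4.0])

    def test_anticorrelated_scene_yields_negative_trend(self):
        cfg = SceneConfig(seed=5, image_shape=(72, 72), cell_radius_px=24,
                          n_frames=30, boundary_motility_amp_px=1.2,
                          motility_activity_coupling=-0.9,
                          gauss_noise_sd=0.5, detector_gain=0.5)
        frames, _ = generate_scene(cfg)
        fret_t = compute_fret_index(frames)
        mask = build_mask(frames.acceptor)
        mmap = boundary_velocity_map(mask)
        mmap.near_membrane_signal = near_membrane_signal(
            fret_t, mask, n_frames=mask.n_frames - 1)
        corr = motility_fret_correlation(mmap)
        assert corr.spearman_rho < 0
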