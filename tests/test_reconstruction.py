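"""Gate selection and weighted filtered backprojection."""

import numpy as np
import pytest

from expo4dct import (
    ScannerGeometry,
    derivative_images,
    gating_budget,
    rasterize,
    reconstruct_4dct,
    reconstruct_phase,
    select_window,
    to_hu,
)
from conftest import make_tagged_sinogram


class TestSelectWindow:
    def test_satisfied_condition_gives_half_rotation_window(self, suite_objects, small_grid):
        # 20 bpm at pitch 0.06: breathing period inside the transit time
        geom = ScannerGeometry(pitch=0.06, projections_per_rotation=180)
        sino = make_tagged_sinogram(suite_objects, geom, small_grid, bpm=20.0)
        budget = gating_budget(geom, 3.0)
        assert budget.window_widening == 0.0
        start, stop, _ = select_window(sino, 0, budget)
        assert stop - start == 90

    def test_window_centered_on_bin_phase(self, moving_sino):
        for b in (0, 3, 7):
            start, stop, center = select_window(moving_sino, b)
            frac = moving_sino.phase_fraction[center]
            d = abs(frac - b / 10)
            assert min(d, 1 - d) <= 1 / 20
            assert start <= center < stop

    def test_window_grows_with_breathing_period(self, moving_sino, small_geom):
        w_slow = select_window(moving_sino, 0, gating_budget(small_geom, 6.0))
        w_fast = select_window(moving_sino, 0, gating_budget(small_geom, 3.5))
        assert (w_slow[1] - w_slow[0]) > (w_fast[1] - w_fast[0])

    def test_untagged_sinogram_rejected(self, suite_objects, small_geom, small_grid):
        from dataclasses import replace

        sino = replace(make_tagged_sinogram(suite_objects, small_geom, small_grid),
                       phase_fraction=None, n_phases=None)
        with pytest.raises(ValueError, match="phase-tagged"):
            select_window(sino, 0)

    def test_insufficient_duration_rejected(self, moving_sino, small_geom):
        huge = gating_budget(small_geom, 60.0)
        with pytest.raises(ValueError, match="insufficient acquisition"):
            select_window(moving_sino, 0, huge)


class TestStaticOracle:
    def test_weighted_fbp_matches_textbook_fbp(self, frozen_sino, static_objects, small_grid):
        """Weights must normalize out on a static phantom: either scheme equals
        a plain ramp-filtered backprojection of the static sinogram."""
        from skimage.transform import iradon

        m = frozen_sino.geometry.projections_per_rotation // 2
        oracle = iradon(
            frozen_sino.data[:m].T / small_grid.px,
            theta=-np.degrees(frozen_sino.angles[:m]),
            filter_name="ramp",
            interpolation="linear",
            circle=True,
            output_size=small_grid.n,
        )
        contrast = 0.018
        for scheme in ("cosine_squared", "expo"):
            img = reconstruct_phase(frozen_sino, 0, scheme).pixels
            rmse = np.sqrt(np.mean((img - oracle) ** 2))
            assert rmse < 0.01 * contrast

    def test_schemes_agree_on_static_data(self, frozen_sino):
        cos2 = reconstruct_phase(frozen_sino, 2, "cosine_squared").pixels
        expo = reconstruct_phase(frozen_sino, 2, "expo").pixels
        assert np.max(np.abs(cos2 - expo)) < 1e-6

    def test_reconstruction_recovers_attenuation_scale(self, frozen_sino, static_objects, small_grid):
        img = reconstruct_phase(frozen_sino, 0, "expo").pixels
        truth = rasterize(static_objects, small_grid)
        xs = small_grid.coords()
        X, Y = np.meshgrid(xs, xs)
        plateau = (np.abs(X) < 25.0) & (np.abs(Y) < 60.0)  # slab-only region
        assert img[plateau].mean() == pytest.approx(truth[plateau].mean(), rel=0.05)


class TestDegeneracy:
    def test_pi_minimum_window_makes_schemes_bit_identical(self, suite_objects, small_grid):
        geom = ScannerGeometry(pitch=0.06, projections_per_rotation=180)
        sino = make_tagged_sinogram(suite_objects, geom, small_grid, bpm=20.0)
        assert gating_budget(geom, 3.0).condition_satisfied
        cos2 = reconstruct_phase(sino, 3, "cosine_squared").pixels
        expo = reconstruct_phase(sino, 3, "expo").pixels
        assert np.array_equal(cos2, expo)


class TestFourDCT:
    def test_ten_phase_reconstruction(self, moving_sino):
        phases = reconstruct_4dct(moving_sino, 10, "expo")
        assert len(phases) == 10
        assert [p.phase_bin for p in phases] == list(range(10))

    def test_static_phantom_phases_identical(self, frozen_sino):
        phases = reconstruct_4dct(frozen_sino, 10, "cosine_squared")
        ref = phases[0].pixels
        for p in phases[1:]:
            assert np.max(np.abs(p.pixels - ref)) < 1e-6

    def test_extreme_phases_separated_by_excursion(self, moving_sino, small_grid):
        ei = reconstruct_phase(moving_sino, 0, "expo").pixels
        ee = reconstruct_phase(moving_sino, 5, "expo").pixels
        ys = small_grid.coords()
        xs = small_grid.coords()
        col = int(np.argmin(np.abs(xs + 60.0)))  # through the 20 mm disk
        band = slice(col - 2, col + 3)

        def centroid(img):
            prof = np.clip(img[:, band].mean(axis=1) - 0.001, 0, None)
            return (prof * ys).sum() / prof.sum()

        sep = centroid(ei) - centroid(ee)
        assert sep == pytest.approx(30.0, abs=1.5 * small_grid.px)


class TestDerivativeImages:
    def test_single_phase_collapses(self, frozen_sino):
        ph = reconstruct_phase(frozen_sino, 0, "expo")
        d = derivative_images([ph])
        assert np.array_equal(d.mip, ph.pixels)
        assert np.array_equal(d.minip, ph.pixels)
        assert np.array_equal(d.avg, ph.pixels)

    def test_constant_stack(self):
        c = np.full((8, 8), 3.5)
        d = derivative_images([c, c, c])
        assert np.array_equal(d.mip, c) and np.array_equal(d.minip, c)

    def test_voxelwise_ordering_and_mip_extent(self, moving_sino):
        phases = reconstruct_4dct(moving_sino, 10, "expo")
        d = derivative_images(phases)
        assert np.all(d.minip <= d.avg + 1e-12)
        assert np.all(d.avg <= d.mip + 1e-12)
        thr = 0.009
        for p in phases:
            assert (d.mip > thr).sum() >= (p.pixels > thr).sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            derivative_images([np.zeros((4, 4)), np.zeros((5, 5))])


class TestHounsfield:
    def test_anchor_points(self):
        assert to_hu(np.array(0.019), 0.019) == 0.0
        assert to_hu(np.array(0.0), 0.019) == -1000.0
        assert to_hu(np.array(0.038), 0.019) == 1000.0

    def test_invalid_mu_water(self):
        with pytest.raises(ValueError):
            to_hu(np.zeros(3), 0.0)
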