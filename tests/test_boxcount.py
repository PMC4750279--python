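import numpy as np
import pytest

from conftest import brute_force_count
from fdlung.binning import make_cutoff_ranges
from fdlung.boxcount import (
    BoxCountCurve,
    box_count_curve,
    count_boxes,
    default_box_sizes,
    fd_curve,
    fit_power_law,
)
from fdlung.errors import ParameterError
from fdlung.phantoms import make_fractal
from fdlung.volume_io import AttenuationVolume, VoxelMask

MENGER_FD = np.log(20) / np.log(3)


class TestCountBoxes:
    def test_solid_4_cube_size_2_aligned(self):
        data = np.ones((4, 4, 4), bool)
        assert count_boxes(data, 2, "aligned") == 8
        assert count_boxes(data, 2, "aligned") == brute_force_count(data, 2, "aligned")

    def test_single_voxel_counts_one_box_any_placement(self):
        data = np.zeros((8, 8, 8), bool)
        data[0, 0, 0] = True
        for s in (1, 2, 3, 5, 8):
            for placement in ("aligned", "offset"):
                assert count_boxes(data, s, placement) == 1

    def test_empty_pattern_counts_zero(self):
        data = np.zeros((8, 8, 8), bool)
        assert count_boxes(data, 3, "aligned") == 0
        assert count_boxes(data, 3, "offset") == 0

    def test_menger_sponge_size_3_aligned_is_400(self):
        sponge = make_fractal("menger", 27, depth=3)
        assert count_boxes(sponge, 3, "aligned") == 400
        assert brute_force_count(sponge.data, 3, "aligned") == 400

    def test_invalid_box_size(self):
        with pytest.raises(ParameterError):
            count_boxes(np.ones((4, 4, 4), bool), 0)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("placement", ["aligned", "offset"])
    def test_matches_brute_force_oracle_on_random_patterns(self, seed, placement):
        rng = np.random.default_rng(seed)
        data = rng.random((24, 24, 24)) < rng.uniform(0.005, 0.4)
        for s in (1, 2, 3, 4, 5, 7, 8, 11, 16):
            assert count_boxes(data, s, placement) == brute_force_count(data, s, placement)

    def test_oracle_equivalence_on_anisotropic_pattern(self, rng):
        data = rng.random((32, 20, 11)) < 0.1
        for s in (1, 2, 3, 6, 10):
            for placement in ("aligned", "offset"):
                assert count_boxes(data, s, placement) == brute_force_count(data, s, placement)

    @pytest.mark.parametrize("placement", ["aligned", "offset"])
    def test_monotone_occupancy(self, rng, placement):
        base = rng.random((16, 16, 16)) < 0.05
        grown = base | (rng.random((16, 16, 16)) < 0.05)
        for s in (1, 2, 4, 7):
            assert count_boxes(grown, s, placement) >= count_boxes(base, s, placement)


class TestBoxCountCurve:
    def test_single_voxel_curve_is_flat_one(self):
        data = np.zeros((8, 8, 8), bool)
        data[2, 3, 4] = True
        curve = box_count_curve(data, [1, 2, 4])
        np.testing.assert_array_equal(curve.enb, [1, 1, 1])

    def test_solid_27_cube_closed_form(self):
        curve = box_count_curve(np.ones((27, 27, 27), bool), [1, 3, 9, 27])
        np.testing.assert_array_equal(curve.nb_aligned, [19683, 729, 27, 1])

    def test_enb_is_mean_of_both_placements(self, rng):
        data = rng.random((16, 16, 16)) < 0.2
        curve = box_count_curve(data, [1, 2, 3, 4])
        np.testing.assert_allclose(curve.enb, (curve.nb_aligned + curve.nb_offset) / 2.0)

    def test_empty_size_list_rejected(self):
        with pytest.raises(ParameterError):
            box_count_curve(np.ones((4, 4, 4), bool), [])


class TestFitPowerLaw:
    def test_exactly_collinear_points_give_closed_form_slope(self):
        curve = BoxCountCurve([1, 3, 9, 27], [8000, 400, 20, 1], [8000, 400, 20, 1])
        assert fit_power_law(curve) == pytest.approx(MENGER_FD, abs=1e-9)

    def test_flat_curve_has_dimension_zero(self):
        curve = BoxCountCurve([1, 2, 4], [1, 1, 1], [1, 1, 1])
        assert fit_power_law(curve) == 0.0

    def test_all_zero_counts_give_zero(self):
        curve = BoxCountCurve([1, 2, 4], [0, 0, 0], [0, 0, 0])
        assert fit_power_law(curve) == 0.0


class TestKnownDimensions:
    def test_line_plane_cube_recovery(self):
        sizes = [1, 2, 4, 8, 16, 32]
        line = box_count_curve(make_fractal("line", 64), sizes)
        assert 0.95 <= fit_power_law(line, "aligned") <= 1.0
        plane = box_count_curve(make_fractal("plane", 64), sizes)
        assert 1.95 <= fit_power_law(plane, "aligned") <= 2.0
        # all integer sizes 1..16: the ceil(N/s)^3 oracle gives 2.8978
        cube = box_count_curve(make_fractal("cube", 64), list(range(1, 17)))
        assert 2.85 <= fit_power_law(cube, "aligned") <= 3.0
        # divisor (power-of-two) sizes lie exactly on the power law
        cube_pow2 = box_count_curve(make_fractal("cube", 64), sizes)
        assert fit_power_law(cube_pow2, "aligned") == pytest.approx(3.0, abs=1e-9)

    def test_menger_power_of_three_aligned_is_exact(self):
        sponge = make_fractal("menger", 27, depth=3)
        curve = box_count_curve(sponge, [1, 3, 9, 27])
        assert fit_power_law(curve, "aligned") == pytest.approx(MENGER_FD, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_fd_always_within_embedding_dimension(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.random((20, 20, 20)) < rng.uniform(0, 1)
        curve = box_count_curve(data, [1, 2, 3, 4, 5, 8, 10])
        for placement in ("aligned", "offset", "averaged"):
            assert 0.0 <= fit_power_law(curve, placement) <= 3.0


class TestFDCurve:
    def test_empty_ranges_have_dimension_exactly_zero(self, rng):
        # occupied values confined to ranges 10..20 of 50
        ranges = make_cutoff_ranges(0, 5000, 50)
        data = rng.uniform(ranges[10].low, ranges[20].high, (16, 16, 16))
        vol = AttenuationVolume(data)
        mask = VoxelMask(np.ones(vol.shape, bool))
        curve = fd_curve(vol, mask, ranges, [1, 2, 4, 8])
        for point in curve.points:
            if point.range.index < 10 or point.range.index > 20:
                assert point.fd == 0.0
                assert point.n_occupied == 0

    def test_menger_band_recovers_its_dimension_exactly(self):
        sponge = make_fractal("menger", 27, depth=3).data
        ranges = make_cutoff_ranges(-3000, 10000, 100)
        data = np.full(sponge.shape, -3000.0)  # out-of-band background, range 0
        data[sponge] = ranges[50].center
        vol = AttenuationVolume(data)
        mask = VoxelMask(sponge)
        curve = fd_curve(vol, mask, ranges, [1, 3, 9, 27], placement="aligned")
        assert curve.points[50].fd == pytest.approx(MENGER_FD, abs=1e-9)
        assert all(p.fd == 0.0 for p in curve.points if p.range.index != 50)

    def test_solid_band_recovers_dimension_three(self, rng):
        ranges = make_cutoff_ranges(0, 1000, 10)
        data = rng.uniform(ranges[4].low, ranges[4].high, (64, 64, 64))
        vol = AttenuationVolume(data)
        mask = VoxelMask(np.ones(vol.shape, bool))
        curve = fd_curve(vol, mask, ranges, list(range(1, 17)), placement="aligned")
        assert 2.85 <= curve.points[4].fd <= 3.0

    def test_matches_composition_of_parts(self, rng):
        from fdlung.binning import binarize_all

        vol = AttenuationVolume(rng.uniform(0, 100, (12, 12, 12)))
        mask = VoxelMask(rng.random((12, 12, 12)) < 0.5)
        ranges = make_cutoff_ranges(0, 100, 8)
        sizes = [1, 2, 3, 4, 6]
        curve = fd_curve(vol, mask, ranges, sizes)
        for pattern, point in zip(binarize_all(vol, mask, ranges), curve.points):
            assert point.n_occupied == pattern.n_occupied
            assert point.fd == pytest.approx(
                fit_power_law(box_count_curve(pattern, sizes)), abs=1e-12
            )


def test_default_box_sizes_capped_by_shape():
    np.testing.assert_array_equal(default_box_sizes((64, 64, 64)), np.arange(1, 33))
    assert default_box_sizes((370, 370, 370)).max() == 100
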