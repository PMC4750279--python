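import numpy as np
import pytest

from fdlung.binning import binarize_all
from fdlung.boxcount import box_count_curve, fd_curve, fit_power_law
from fdlung.curvefit import fit_two_gaussians
from fdlung.errors import InfeasibleTargetError, ParameterError
from fdlung.phantoms import (
    CLUSTER_BOX_SIZES,
    EXPOSURE_GROUP_PARAMS,
    PARAM_ORDER,
    GroupSpec,
    calibrate_occupancy,
    make_attenuation_phantom,
    make_cohort,
    make_fractal,
)


class TestDeterministicFractals:
    def test_occupied_counts_match_closed_forms(self):
        assert make_fractal("menger", 27, depth=3).n_occupied == 20**3
        assert make_fractal("menger", 9, depth=2).n_occupied == 20**2
        assert make_fractal("cube", 16).n_occupied == 16**3
        assert make_fractal("line", 64).n_occupied == 64
        assert make_fractal("plane", 32).n_occupied == 32**2

    def test_line_fd_is_exactly_one_over_divisor_sizes(self):
        curve = box_count_curve(make_fractal("line", 64), [1, 2, 4, 8, 16])
        assert fit_power_law(curve, "aligned") == pytest.approx(1.0, abs=1e-9)

    def test_menger_requires_power_of_three_size(self):
        with pytest.raises(ParameterError):
            make_fractal("menger", 30, depth=3)

    def test_dust_requires_seed_and_valid_occupancy(self):
        with pytest.raises(ParameterError):
            make_fractal("random_dust", 16, occupancy=0.5)
        with pytest.raises(ParameterError):
            make_fractal("random_dust", 16, occupancy=1.5, seed=0)

    def test_dust_occupancy_is_bernoulli(self):
        pattern = make_fractal("random_dust", 32, occupancy=0.2, seed=7)
        n = pattern.n_occupied
        expect = 0.2 * 32**3
        assert abs(n - expect) < 5 * np.sqrt(32**3 * 0.2 * 0.8)

    def test_dust_seeded_reproducibility(self):
        a = make_fractal("random_dust", 16, occupancy=0.3, seed=5)
        b = make_fractal("random_dust", 16, occupancy=0.3, seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestOccupancyCalibration:
    def test_endpoints(self):
        cal = calibrate_occupancy(64, seed=0)
        assert cal.fd_for_occupancy(0.0) == 0.0
        assert 2.85 <= cal.fd_for_occupancy(1.0) <= 3.0  # solid cube at size 64

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_over_occupancy_ladder(self, seed):
        ladder = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 20)])
        cal = calibrate_occupancy(48, seed=seed, ladder=ladder)
        assert np.all(np.diff(cal.fds) >= 0)

    def test_inverse_is_consistent(self):
        cal = calibrate_occupancy(48, seed=0)
        for fd in (0.5, 1.5, 2.0):
            occ = float(cal.occupancy_for_fd(fd))
            assert abs(float(cal.fd_for_occupancy(occ)) - fd) < 0.05


class TestAttenuationPhantom:
    SCALED_CON = dict(height_a=1.15, position_a=735.0, width_a=1086.0,
                      height_b=0.64, position_b=3776.0, width_b=1562.0)

    def test_per_range_counts_conserved_exactly(self):
        ph = make_attenuation_phantom(self.SCALED_CON, size=32, seed=3)
        patterns = binarize_all(ph.volume, ph.mask, ph.ranges)
        for pattern, point in zip(patterns, ph.target_curve.points):
            assert pattern.n_occupied == point.n_occupied
        assert sum(p.n_occupied for p in patterns) == ph.mask.n_voxels

    def test_seeded_reproducibility_is_bitwise(self):
        a = make_attenuation_phantom(self.SCALED_CON, size=32, seed=9)
        b = make_attenuation_phantom(self.SCALED_CON, size=32, seed=9)
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.mask.data, b.mask.data)

    def test_degenerate_zero_heights_give_empty_curve(self):
        ph = make_attenuation_phantom(
            dict(height_a=0, position_a=0, width_a=1, height_b=0, position_b=0, width_b=1),
            size=32,
            seed=0,
        )
        assert ph.mask.n_voxels == 0
        curve = fd_curve(ph.volume, ph.mask, ph.ranges, ph.box_sizes, ph.placement)
        assert np.all(curve.fds == 0.0)

    def test_overloaded_target_is_infeasible(self):
        heavy = dict(height_a=2.9, position_a=1000, width_a=6000,
                     height_b=2.9, position_b=8000, width_b=6000)
        with pytest.raises(InfeasibleTargetError):
            make_attenuation_phantom(heavy, size=32, seed=0)

    def test_invalid_targets_rejected(self):
        bad_height = dict(height_a=3.4, position_a=0, width_a=100,
                          height_b=1.0, position_b=0, width_b=100)
        with pytest.raises(ParameterError):
            make_attenuation_phantom(bad_height, size=32)
        bad_pos = dict(height_a=1.0, position_a=99999, width_a=100,
                       height_b=1.0, position_b=0, width_b=100)
        with pytest.raises(ParameterError):
            make_attenuation_phantom(bad_pos, size=32)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_pipeline_recovers_control_scale_targets(self, seed):
        """End-to-end: generated curve, analysed and fitted, returns the
        control-group two-Gaussian parameters to within the generator's
        measured fidelity (heights/widths ~ a few %, positions < 8%)."""
        truth = EXPOSURE_GROUP_PARAMS["CON"]["means"]
        ph = make_attenuation_phantom(truth, size=64, seed=seed, n_iter=2)
        curve = fd_curve(ph.volume, ph.mask, ph.ranges, ph.box_sizes, ph.placement)
        params = fit_two_gaussians(curve).parameters()
        for key in ("height_a", "height_b"):
            assert abs(params[key] - truth[key]) / truth[key] < 0.12, key
        for key in ("width_a", "width_b"):
            assert abs(params[key] - truth[key]) / truth[key] < 0.15, key
        for key in ("position_a", "position_b"):
            assert abs(params[key] - truth[key]) < 0.08 * (truth[key] + 1000), key


class TestCohort:
    def test_small_group_rejected(self):
        spec = GroupSpec(1, EXPOSURE_GROUP_PARAMS["CON"]["means"],
                         EXPOSURE_GROUP_PARAMS["CON"]["sds"])
        with pytest.raises(ParameterError):
            make_cohort({"a": spec, "b": spec}, size=32)

    def test_labels_sizes_and_determinism(self):
        means = dict(EXPOSURE_GROUP_PARAMS["CON"]["means"])
        means["height_a"] *= 0.5
        means["height_b"] *= 0.5
        sds = {k: 0.0 for k in PARAM_ORDER}
        sds["height_b"] = 0.05
        specs = {"x": GroupSpec(2, means, sds), "y": GroupSpec(3, means, sds)}
        subs = make_cohort(specs, size=32, seed=4)
        assert [s.group for s in subs] == ["x", "x", "y", "y", "y"]
        assert len({s.subject_id for s in subs}) == 5
        subs2 = make_cohort(specs, size=32, seed=4)
        for a, b in zip(subs, subs2):
            np.testing.assert_array_equal(a.volume.data, b.volume.data)
        # drawn parameters vary across subjects in the stochastic coordinate
        hbs = [s.true_params["height_b"] for s in subs]
        assert len(set(np.round(hbs, 6))) > 1
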