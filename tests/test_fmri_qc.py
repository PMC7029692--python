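import numpy as np
import pytest

from conngrad.fmri_qc import (
    MotionParams,
    apply_exclusion_rules,
    build_nuisance_design,
    flag_artifact_timepoints,
    friston24_expand,
    group_cluster_stats,
    mask_between_by_within,
    regress_nuisance,
    seed_connectivity_map,
)
from conngrad.grids import BinaryMask, VolumeGrid
from conngrad.similarity import TimeSeriesSet

from conftest import brute_force_censor


def still_motion(t=120):
    return MotionParams(np.zeros((t, 6)))


class TestFriston24:
    def test_all_zero(self):
        out = friston24_expand(still_motion(50))
        assert out.shape == (50, 24)
        assert (out == 0).all()

    def test_hand_expansion_single_param(self):
        mp = MotionParams(np.column_stack([[1.0, 2.0], np.zeros((2, 5))]))
        out = friston24_expand(mp)
        np.testing.assert_array_equal(out[:, 0], [1, 2])  # p
        np.testing.assert_array_equal(out[:, 1], [1, 4])  # p^2
        np.testing.assert_array_equal(out[:, 2], [0, 1])  # p(t-1)
        np.testing.assert_array_equal(out[:, 3], [0, 1])  # p(t-1)^2

    def test_column_count(self, rng):
        out = friston24_expand(MotionParams(rng.standard_normal((30, 6))))
        assert out.shape[1] == 24

    def test_wrong_column_count_rejected(self, rng):
        with pytest.raises(ValueError, match="6"):
            MotionParams(rng.standard_normal((30, 5)))


class TestFlagArtifacts:
    def test_translation_jump_flagged(self):
        vals = np.zeros((100, 6))
        vals[50:, 0] = 1.2  # 1.2 mm framewise jump at t=50
        censor = flag_artifact_timepoints(MotionParams(vals), np.zeros(100))
        assert censor[50]
        assert censor.sum() == 1

    def test_global_signal_deviation_flagged(self, rng):
        g = rng.normal(0, 1, 200)
        g = (g - g.mean()) / g.std() * 0.5  # keep everything well under 2.5 SD
        spike_t = 77
        g[spike_t] = 10.0
        censor = flag_artifact_timepoints(still_motion(200), g)
        assert censor[spike_t]

    def test_still_scan_no_flags(self):
        censor = flag_artifact_timepoints(still_motion(80), np.ones(80))
        assert not censor.any()

    def test_absolute_mode(self):
        vals = np.zeros((10, 6))
        vals[:, 1] = 1.5  # constant offset: no framewise change, big absolute
        mp = MotionParams(vals)
        assert not flag_artifact_timepoints(mp, np.zeros(10)).any()
        assert flag_artifact_timepoints(mp, np.zeros(10), absolute=True).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            flag_artifact_timepoints(still_motion(10), np.zeros(11))

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            t = int(rng.integers(50, 150))
            vals = rng.normal(0, 0.5, (t, 6))
            g = rng.normal(100, 5, t)
            got = flag_artifact_timepoints(MotionParams(vals), g)
            np.testing.assert_array_equal(got, brute_force_censor(vals, g))


class TestExclusionRules:
    def test_107_volumes_at_tr28_excluded(self):
        # 107 * 2.8 = 299.6 s < 300 s
        censor = np.ones(130, dtype=bool)
        censor[:107] = False
        d = apply_exclusion_rules(censor, 2.8, still_motion(130))
        assert d.exclude
        assert d.retained_seconds == pytest.approx(299.6)

    def test_108_volumes_at_tr28_kept(self):
        censor = np.ones(130, dtype=bool)
        censor[:108] = False
        d = apply_exclusion_rules(censor, 2.8, still_motion(130))
        assert not d.exclude
        assert d.retained_seconds == pytest.approx(302.4)

    def test_single_large_translation_excludes(self):
        vals = np.zeros((200, 6))
        vals[100, 2] = 3.5
        d = apply_exclusion_rules(np.zeros(200, bool), 2.8, MotionParams(vals))
        assert d.exclude
        assert "3.5" in d.reason

    def test_brute_force_recheck(self, rng):
        for _ in range(30):
            t = int(rng.integers(100, 160))
            vals = rng.normal(0, 1.0, (t, 6))
            g = rng.normal(0, 1, t)
            censor = brute_force_censor(vals, g)
            d = apply_exclusion_rules(censor, 2.8, MotionParams(vals))
            retained = (~censor).sum() * 2.8
            want = retained < 300 or np.abs(vals[:, :3]).max() > 3
            assert d.exclude == want


class TestRegressNuisance:
    def _ts(self, series, line_roi):
        series = np.atleast_2d(series)
        return TimeSeriesSet(line_roi(series.shape[0]), series)

    def test_series_equal_to_regressor_zeroed(self, rng, line_roi):
        x = rng.standard_normal(100)
        ts = self._ts(x, line_roi)
        out = regress_nuisance(ts, x[:, None])
        np.testing.assert_allclose(out.series, 0.0, atol=1e-10)

    def test_orthogonal_series_unchanged(self, line_roi):
        t = np.arange(100)
        reg = np.sin(2 * np.pi * t / 100)
        y = np.cos(2 * np.pi * t / 100)  # orthogonal, zero-mean
        out = regress_nuisance(self._ts(y, line_roi), reg[:, None])
        np.testing.assert_allclose(out.series[0], y, atol=1e-10)

    def test_planted_signal_recovery(self, rng, line_roi):
        motion = rng.standard_normal(200)
        signal = rng.standard_normal(200)
        y = 2.0 * motion + signal
        X = np.column_stack([motion, np.ones(200)])
        out = regress_nuisance(self._ts(y, line_roi), X)
        resid = out.series[0]
        assert abs(np.corrcoef(resid, signal)[0, 1]) > 0.99
        assert abs(np.corrcoef(resid, motion)[0, 1]) < 1e-6

    def test_residuals_orthogonal_to_design(self, rng, line_roi):
        mp = MotionParams(rng.normal(0, 0.2, (120, 6)))
        censor = np.zeros(120, bool)
        censor[[10, 55]] = True
        X = build_nuisance_design(mp, censor, tissue_signals=rng.standard_normal((120, 3)))
        ts = self._ts(rng.standard_normal((7, 120)), line_roi)
        out = regress_nuisance(ts, X)
        # columns scaled to unit norm before the check
        Xn = X / np.linalg.norm(X, axis=0)
        resid_n = out.series / np.linalg.norm(out.series, axis=1, keepdims=True)
        assert np.abs(resid_n @ Xn).max() <= 1e-8

    def test_rank_deficient_design_names_columns(self, rng, line_roi):
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x, np.ones(50)])
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(self._ts(rng.standard_normal((2, 50)), line_roi), X)


class TestSeedConnectivityMap:
    def _setup(self, rng, t=80):
        grid = VolumeGrid((4, 4, 4))
        bold = rng.standard_normal((4, 4, 4, t))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        return bold, BinaryMask(grid, mask)

    def test_seed_voxel_itself_high_z(self, rng):
        bold, mask = self._setup(rng)
        z = seed_connectivity_map(bold, mask)
        assert z[0, 0, 0] > 5  # r clipped at 1 - 1e-7 -> atanh ~ 8.4

    def test_orthogonal_series_near_zero(self, rng):
        bold, mask = self._setup(rng, t=100)
        t = np.arange(100)
        bold[0, 0, 0] = np.sin(2 * np.pi * t / 100)
        bold[3, 3, 3] = np.cos(2 * np.pi * t / 100)
        z = seed_connectivity_map(bold, mask)
        assert abs(z[3, 3, 3]) < 1e-10

    def test_sign_flip_antisymmetry(self, rng):
        bold, mask = self._setup(rng)
        bold[2, 2, 2] = bold[0, 0, 0]
        z1 = seed_connectivity_map(bold, mask)[2, 2, 2]
        bold[2, 2, 2] = -bold[2, 2, 2]
        z2 = seed_connectivity_map(bold, mask)[2, 2, 2]
        assert z2 == pytest.approx(-z1, abs=1e-10)

    def test_constant_voxel_zero(self, rng):
        bold, mask = self._setup(rng)
        bold[1, 1, 1] = 7.0
        z = seed_connectivity_map(bold, mask)
        assert z[1, 1, 1] == 0.0

    def test_empty_mask_error(self, rng):
        grid = VolumeGrid((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            seed_connectivity_map(
                rng.standard_normal((4, 4, 4, 30)),
                BinaryMask(grid, np.zeros((4, 4, 4), bool)),
            )


class TestGroupClusterStats:
    def test_all_zero_maps_no_clusters(self):
        maps = np.zeros((5, 6, 6, 6))
        st = group_cluster_stats(maps, n_perm=50, rng=0)
        assert not st.cluster_sig_mask.any()
        assert st.df == 4

    def test_swapping_negates_paired_t(self, rng):
        A = rng.standard_normal((8, 5, 5, 5))
        B = rng.standard_normal((8, 5, 5, 5))
        st1 = group_cluster_stats(A, B, n_perm=20, rng=1)
        st2 = group_cluster_stats(B, A, n_perm=20, rng=1)
        np.testing.assert_allclose(st1.t_values, -st2.t_values, atol=1e-10)
        assert st1.method == "paired_difference"

    def test_unequal_participants_error(self, rng):
        with pytest.raises(ValueError, match="equal participant"):
            group_cluster_stats(
                rng.standard_normal((8, 5, 5, 5)), rng.standard_normal((7, 5, 5, 5))
            )

    def test_strong_effect_detected(self, rng):
        maps = rng.standard_normal((20, 8, 8, 8)) * 0.2
        maps[:, 2:6, 2:6, 2:6] += 1.0
        st = group_cluster_stats(maps, n_perm=200, rng=2)
        blob = np.zeros((8, 8, 8), bool)
        blob[2:6, 2:6, 2:6] = True
        assert (st.cluster_sig_mask & blob).any()

    def test_mask_between_by_within(self, rng):
        maps = rng.standard_normal((20, 8, 8, 8)) * 0.2
        maps[:, 2:6, 2:6, 2:6] += 1.0
        within = group_cluster_stats(maps, n_perm=200, rng=3)
        between = group_cluster_stats(maps, n_perm=200, rng=4)
        masked = mask_between_by_within(between, within)
        assert masked.sum() <= between.cluster_sig_mask.sum()
        assert (masked <= (between.cluster_sig_mask & within.cluster_sig_mask)).all()

    def test_too_few_participants(self, rng):
        with pytest.raises(ValueError, match="two participants"):
            group_cluster_stats(rng.standard_normal((1, 4, 4, 4)))
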