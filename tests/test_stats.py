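"""Inferential layer: repeated-measures model, contrasts, FDR, age-correlation
maps, cluster permutation, ROI fits and within-subject error bars."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from silenttrack.errors import InvalidParameterError
from silenttrack import stats
from silenttrack.types import StatMap

FEATS = ("lip", "envelope", "formant", "pitch")
CONDS = ("natural", "reversed")


def make_table(n_subjects, cell_effect=None, noise_sd=0.0, rng=None, subject_offsets=None):
    """Balanced subject x feature x condition table from a cell-mean model."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_subjects):
        off = 0.0 if subject_offsets is None else subject_offsets[i]
        for f in FEATS:
            for c in CONDS:
                mu = 0.1 + off
                if cell_effect:
                    mu += cell_effect.get((f, c), 0.0)
                rows.append((f"s{i}", 30.0, f, c, mu + noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["subject_id", "age", "feature", "condition", "value"])


class TestModel:
    def test_zero_noise_recovers_cell_means(self):
        effect = {("formant", c): 0.02 for c in CONDS}
        tbl = make_table(6, cell_effect=effect)
        fit = stats.fit_feature_naturalness_model(tbl)
        f_stat, dfn, dfd, p = fit.f_tests["feature"]
        assert f_stat == np.inf and p == 0.0
        cm = fit.cell_means.set_index(["feature", "condition"])["mean"]
        assert np.isclose(cm[("formant", "natural")], 0.12)
        assert np.isclose(cm[("lip", "natural")], 0.10)

    def test_subject_offsets_absorbed(self):
        rng = np.random.default_rng(1)
        tbl = make_table(8, noise_sd=0.01, rng=rng)
        fit_a = stats.fit_feature_naturalness_model(tbl)
        tbl_b = tbl.copy()
        mask = tbl_b["subject_id"] == "s0"
        tbl_b.loc[mask, "value"] += 7.0
        fit_b = stats.fit_feature_naturalness_model(tbl_b)
        for effect in ("feature", "naturalness"):
            assert np.isclose(fit_a.f_tests[effect][0], fit_b.f_tests[effect][0])

    def test_null_pvalues_uniform(self):
        """Under pure noise the feature-effect p values must be uniform."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            tbl = make_table(6, noise_sd=1.0, rng=rng)
            fit = stats.fit_feature_naturalness_model(tbl)
            pvals.append(fit.f_tests["feature"][3])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_unbalanced_table_rejected(self):
        tbl = make_table(4).iloc[:-1]
        with pytest.raises(InvalidParameterError):
            stats.fit_feature_naturalness_model(tbl)


class TestContrasts:
    def test_six_feature_contrasts(self):
        fit = stats.fit_feature_naturalness_model(make_table(5, noise_sd=0.01))
        out = stats.pairwise_contrasts(fit, "features")
        assert len(out) == 6

    def test_four_naturalness_contrasts(self):
        fit = stats.fit_feature_naturalness_model(make_table(5, noise_sd=0.01))
        out = stats.pairwise_contrasts(fit, "naturalness-within-feature")
        assert len(out) == 4

    def test_null_familywise_behavior(self):
        rng = np.random.default_rng(3)
        any_sig = 0
        n_sim = 60
        for _ in range(n_sim):
            fit = stats.fit_feature_naturalness_model(make_table(6, noise_sd=1.0, rng=rng))
            out = stats.pairwise_contrasts(fit, "naturalness-within-feature")
            any_sig += (out["p_fdr"] <= 0.05).any()
        assert any_sig / n_sim <= 0.15

    def test_planted_envelope_effect_ranks_first(self):
        rng = np.random.default_rng(4)
        wins = 0
        for s in range(20):
            effect = {("envelope", "natural"): 0.05}
            tbl = make_table(12, cell_effect=effect, noise_sd=0.02,
                             rng=np.random.default_rng(100 + s))
            fit = stats.fit_feature_naturalness_model(tbl)
            out = stats.pairwise_contrasts(fit, "naturalness-within-feature")
            best = out.loc[out["p_fdr"].idxmin(), "contrast"]
            wins += best.startswith("envelope")
        assert wins >= 18

    def test_unknown_family_rejected(self):
        fit = stats.fit_feature_naturalness_model(make_table(4, noise_sd=0.01))
        with pytest.raises(InvalidParameterError):
            stats.pairwise_contrasts(fit, "bogus")


class TestBenjaminiHochberg:
    def test_worked_example(self):
        adj = stats.benjamini_hochberg([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert stats.benjamini_hochberg([0.3])[0] == 0.3

    def test_adjusted_at_least_raw_capped_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 40)
        adj = stats.benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in the raw ranks

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.benjamini_hochberg([0.5, 1.2])


class TestCorrTMap:
    def test_closed_form_t(self):
        rng = np.random.default_rng(6)
        ages = np.linspace(20, 60, 50)
        target_r = 0.5
        base = (ages - ages.mean()) / ages.std()
        noise = rng.standard_normal(50)
        noise -= noise.mean() + base * (noise @ base) / (base @ base)
        noise /= noise.std()
        y = target_r * base + np.sqrt(1 - target_r**2) * noise
        sm = stats.corr_t_map(y[:, None], ages)
        assert np.isclose(sm.r[0], 0.5, atol=1e-12)
        assert np.isclose(sm.t[0], 4.0, atol=1e-9)

    def test_null_r_quantile_matches_fisher(self):
        rng = np.random.default_rng(7)
        n = 50
        ages = rng.uniform(19, 63, n)
        idx = rng.standard_normal((n, 4000))
        sm = stats.corr_t_map(idx, ages)
        q95 = np.quantile(np.abs(sm.r), 0.95)
        assert abs(q95 - 1.96 / np.sqrt(n)) < 0.04

    def test_perfect_correlation_infinite_t(self):
        ages = np.linspace(20, 60, 10)
        sm = stats.corr_t_map((-2 * ages)[:, None], ages)
        assert sm.r[0] == -1.0 and sm.t[0] == -np.inf


class TestClusterPermutation:
    def test_single_voxel_equals_brute_force(self):
        rng = np.random.default_rng(8)
        n = 40
        ages = rng.uniform(19, 63, n)
        y = (-0.01 * ages + rng.normal(0, 0.1, n))[:, None]
        res = stats.cluster_permutation(y, ages, (1, 1, 1), n_perm=200, seed=7)
        assert len(res.clusters) == 1

        r_obs = np.corrcoef(ages, y[:, 0])[0, 1]
        t_obs = r_obs * np.sqrt((n - 2) / (1 - r_obs**2))
        thr = sps.t.ppf(0.975, n - 2)
        rng2 = np.random.default_rng(7)  # same seed -> same shuffle sequence
        count = 0
        for _ in range(200):
            pa = rng2.permutation(ages)
            rp = np.corrcoef(pa, y[:, 0])[0, 1]
            tp = rp * np.sqrt((n - 2) / (1 - rp**2))
            count += (abs(tp) if abs(tp) > thr else 0.0) >= abs(t_obs)
        assert res.clusters[0].p_value == (1 + count) / 201

    def test_p_resolution_and_floor(self):
        rng = np.random.default_rng(9)
        n = 30
        ages = np.linspace(19, 63, n)
        y = (-0.05 * ages)[:, None] + rng.normal(0, 0.01, (n, 1))
        res = stats.cluster_permutation(y, ages, (1, 1, 1), n_perm=100, seed=1)
        assert res.clusters[0].p_value >= 1 / 101

    def test_planted_block_detected_with_negative_sign(self):
        """A negative age effect confined to a 3x3x3 block must come out as
        a significant negative cluster covering most of the block."""
        shape = (6, 6, 6)
        block = np.zeros(shape, dtype=bool)
        block[:3, :3, :3] = True
        block_idx = np.flatnonzero(block.ravel())
        detected = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            n = 50
            ages = rng.uniform(19, 63, n)
            idx = rng.standard_normal((n, 216))
            z = (ages - ages.mean()) / ages.std()
            idx[:, block_idx] += (-0.75 * z)[:, None]  # per-voxel r about -0.6
            res = stats.cluster_permutation(idx, ages, shape, n_perm=200, seed=s)
            sig_neg = [c for c in res.significant() if c.sign < 0]
            if sig_neg and len(np.intersect1d(sig_neg[0].voxels, block_idx)) >= 14:
                detected += 1
        assert detected >= 9

    def test_constant_ages_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.cluster_permutation(np.zeros((10, 8)), np.full(10, 40.0), (2, 2, 2), n_perm=100)

    def test_no_suprathreshold_voxels_gives_empty_result(self):
        rng = np.random.default_rng(10)
        n = 20
        ages = rng.uniform(19, 63, n)
        idx = np.tile(rng.standard_normal(n)[:, None], (1, 8)) * 1e-6
        idx += rng.normal(0, 1e-9, (n, 8))
        res = stats.cluster_permutation(idx + 1.0, ages, (2, 2, 2), n_perm=100, seed=0)
        assert res.min_p >= res.clusters[0].p_value if res.clusters else res.min_p == 1.0


class TestRoiAndHelpers:
    def test_perfectly_linear_index_r2_one(self):
        ages = np.linspace(20, 60, 30)
        idx = np.tile((0.01 * ages)[:, None], (1, 5))
        fit = stats.roi_regression(idx, ages, np.ones(5, dtype=bool), "occipital")
        assert np.isclose(fit.r_squared, 1.0)
        assert np.isclose(fit.eta_squared, 1.0)

    def test_eta_squared_equals_r_squared(self):
        rng = np.random.default_rng(11)
        ages = rng.uniform(19, 63, 40)
        idx = rng.standard_normal((40, 6))
        fit = stats.roi_regression(idx, ages, np.ones(6, dtype=bool))
        assert fit.eta_squared == fit.r_squared

    def test_planted_slope_recovered(self):
        slopes = []
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            ages = rng.uniform(19, 63, 50)
            idx = (-0.002 * ages)[:, None] + rng.normal(0, 0.02, (50, 1))
            fit = stats.roi_regression(idx, ages, np.ones(1, dtype=bool))
            slopes.append(fit.slope)
        se = np.std(slopes, ddof=1) / np.sqrt(20)
        assert abs(np.mean(slopes) - (-0.002)) < 2 * se + 1e-4

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.roi_regression(np.zeros((10, 4)), np.arange(10.0), np.zeros(4, dtype=bool))

    def test_lowest_t_unique_minimum(self):
        sm = StatMap(r=np.zeros(5), t=np.array([1.0, -2.0, 0.5, -3.0, 2.0]), n_subjects=10)
        assert stats.lowest_t_voxel(sm) == 3

    def test_lowest_t_tie_breaks_low_index(self):
        sm = StatMap(r=np.zeros(10), t=np.ones(10), n_subjects=10)
        sm.t[5] = sm.t[9] = -4.0
        assert stats.lowest_t_voxel(sm) == 5

    def test_lowest_t_respects_mask(self):
        sm = StatMap(r=np.zeros(4), t=np.array([-5.0, -1.0, -2.0, -3.0]), n_subjects=10)
        mask = np.array([False, True, True, True])
        assert stats.lowest_t_voxel(sm, within=mask) == 3


class TestWithinSubjectSE:
    def test_identical_profiles_zero_se(self):
        profile = np.array([0.1, 0.2, 0.15, 0.3])
        offsets = np.array([0.0, 1.0, -0.5, 2.0, 0.7])
        y = offsets[:, None] + profile[None, :]
        se = stats.within_subject_se(y)
        assert np.allclose(se, 0.0, atol=1e-12)

    def test_two_condition_morey_factor(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal((10, 2))
        se = stats.within_subject_se(y)
        adj = y - y.mean(axis=1, keepdims=True) + y.mean()
        expected = adj.std(axis=0, ddof=1) / np.sqrt(10) * np.sqrt(2.0)
        assert np.allclose(se, expected)

    def test_matches_brute_force_recipe(self):
        rng = np.random.default_rng(13)
        y = rng.standard_normal((12, 8)) + rng.standard_normal((12, 1)) * 3
        se = stats.within_subject_se(y)
        # independent re-implementation, loop form
        n, c = y.shape
        adj = np.empty_like(y)
        grand = y.mean()
        for i in range(n):
            adj[i] = y[i] - y[i].mean() + grand
        expected = np.array(
            [np.std(adj[:, j], ddof=1) / np.sqrt(n) * np.sqrt(c / (c - 1)) for j in range(c)]
        )
        assert np.allclose(se, expected)

    def test_single_condition_rejected(self):
        with pytest.raises(InvalidParameterError):
            stats.within_subject_se(np.zeros((5, 1)))
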