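"""Mutual-information estimation against Gaussian oracles."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from mvpakit.collapse import CollapseConfig
from mvpakit.dimreduction import ReducerSpec
from mvpakit.infoloss import (
    ReductionPair,
    build_reduction_pairs,
    estimate_mi,
    fit_gmm_aic,
    gaussian_mi_closed_form,
    ksg_mi,
    mi_accuracy_correlation,
    mi_dimension_ttests,
)

from conftest import make_epochs


class TestClosedForm:
    def test_identity_covariance_gives_zero(self):
        assert gaussian_mi_closed_form(np.eye(4), 2, 2) == pytest.approx(0.0)

    def test_bivariate_rho_09(self):
        S = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert gaussian_mi_closed_form(S, 1, 1) == pytest.approx(
            -0.5 * np.log(1 - 0.81), abs=1e-10
        )

    def test_block_diagonal_gives_zero(self):
        S = np.block(
            [[np.array([[2.0, 0.5], [0.5, 1.0]]), np.zeros((2, 1))],
             [np.zeros((1, 2)), np.array([[3.0]])]]
        )
        assert gaussian_mi_closed_form(S, 2, 1) == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_definite_errors(self):
        with pytest.raises(ValueError, match="positive definite"):
            gaussian_mi_closed_form(np.array([[1.0, 2.0], [2.0, 1.0]]), 1, 1)


class TestGMMFit:
    def test_single_gaussian_selects_one_component(self):
        ones = 0
        for seed in range(8):
            x = np.random.default_rng(seed).standard_normal((3000, 2))
            ones += fit_gmm_aic(x, range(1, 6), seed=seed).n_components == 1
        assert ones >= 7

    def test_two_separated_gaussians_select_two(self):
        rng = np.random.default_rng(5)
        x = np.vstack(
            [rng.standard_normal((2000, 2)), rng.standard_normal((2000, 2)) + 10.0]
        )
        assert fit_gmm_aic(x, range(1, 6), seed=0).n_components == 2

    def test_log_density_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4000, 2)) @ np.array([[1.0, 0.3], [0.0, 0.7]])
        gm = fit_gmm_aic(x, [1], seed=0)
        at_mean = x.mean(axis=0, keepdims=True)
        ref = sp_stats.multivariate_normal(
            mean=x.mean(axis=0), cov=np.cov(x.T)
        ).logpdf(at_mean)
        assert gm.score_samples(at_mean)[0] == pytest.approx(float(ref), rel=0.01)


class TestKSG:
    def test_correlated_gaussians_near_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(8000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(8000)
        mi = ksg_mi(x[:, None], y[:, None], k=3)
        assert mi == pytest.approx(-0.5 * np.log(1 - 0.81), abs=0.05)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(8)
        mi = ksg_mi(rng.standard_normal((5000, 1)), rng.standard_normal((5000, 1)))
        assert abs(mi) < 0.05


class TestEstimateMI:
    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(9)
        pair = ReductionPair(rng.standard_normal((4000, 1)), rng.standard_normal((4000, 1)))
        res = estimate_mi(pair, n_mc_samples=4000, repeats=2, seed=0)
        assert res.mi_mean == pytest.approx(0.0, abs=0.05)
        assert res.mi_mean >= 0.0

    def test_correlated_gaussians_recover_closed_form(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(5000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(5000)
        res = estimate_mi(
            ReductionPair(x[:, None], y[:, None]), n_mc_samples=5000, repeats=2, seed=1
        )
        assert res.mi_mean == pytest.approx(0.8304, abs=0.05)
        # density-ratio diagnostic should sit near the same value
        assert res.mi_density_per_repeat.mean() == pytest.approx(0.8304, abs=0.1)

    def test_degenerate_operated_data_gives_zero_with_warning(self):
        rng = np.random.default_rng(11)
        pair = ReductionPair(rng.standard_normal((500, 2)), np.zeros((500, 1)))
        with pytest.warns(UserWarning, match="degenerate"):
            res = estimate_mi(pair, n_mc_samples=500, repeats=1, seed=0)
        assert res.mi_mean == 0.0

    def test_nested_reduction_loses_information(self):
        # data-processing trend: coarser reduction cannot carry more MI
        rng = np.random.default_rng(12)
        x = rng.standard_normal((4000, 3))
        noise = 0.5 * rng.standard_normal((4000, 3))
        y_full = x + noise
        mi2 = estimate_mi(
            ReductionPair(x, y_full[:, :2]), n_mc_samples=3000, repeats=2, seed=3
        ).mi_mean
        mi1 = estimate_mi(
            ReductionPair(x, y_full[:, :1]), n_mc_samples=3000, repeats=2, seed=3
        ).mi_mean
        assert mi1 <= mi2 + 0.05


class TestReductionPairs:
    def test_identity_mask_returns_benchmark(self, tiny_subject):
        meg, _ = tiny_subject
        pair = build_reduction_pairs(meg, np.ones(meg.n_channels, bool), seed=0)
        assert np.array_equal(pair.benchmark, pair.operated)

    def test_pca_reduction_shapes(self, tiny_subject):
        meg, _ = tiny_subject
        op = ReducerSpec(method="pca", pca_var_threshold=0.8)
        pair = build_reduction_pairs(meg, op, max_observations=3000, seed=0)
        assert pair.benchmark.shape[0] == pair.operated.shape[0] == 3000
        assert pair.benchmark.shape[1] == meg.n_channels
        assert pair.operated.shape[1] < meg.n_channels
        assert pair.mapping["dimension"] == "channel"

    def test_trial_average_rows_repeat_within_group(self):
        rng = np.random.default_rng(13)
        E = make_epochs(rng.standard_normal((8, 2, 5)))
        op = CollapseConfig(resample_hz=None, avg_group_size=2, seed=4)
        pair = build_reduction_pairs(E, op, max_observations=None)
        assert pair.mapping == {"dimension": "trial", "kind": "average", "group_size": 2}
        ops = pair.operated.reshape(8, 5, 2)
        bench = pair.benchmark.reshape(8, 5, 2)
        # every operated trial-row appears exactly twice (its group partner)
        flat = ops[:, 0, :]
        _, counts = np.unique(flat.round(12), axis=0, return_counts=True)
        assert (counts == 2).all()
        # and equals the mean of its two members
        for g in np.unique(flat.round(12), axis=0):
            members = np.flatnonzero((flat.round(12) == g).all(axis=1))
            assert np.allclose(bench[members, 0].mean(axis=0), flat[members[0]])

    def test_resample_mapping_aligns_rows(self, tiny_subject):
        meg, _ = tiny_subject
        op = CollapseConfig(resample_hz=25.0)
        pair = build_reduction_pairs(meg, op, max_observations=2000, seed=1)
        assert pair.benchmark.shape[0] == pair.operated.shape[0] == 2000
        assert pair.mapping["dimension"] == "temporal"

    def test_sliding_window_mapping(self, tiny_subject):
        meg, _ = tiny_subject
        op = CollapseConfig(resample_hz=None, window_len_ms=50.0)
        pair = build_reduction_pairs(meg, op, max_observations=2000, seed=1)
        assert pair.mapping["kind"] == "sliding_window"

    def test_unsupported_operation_errors(self, tiny_subject):
        meg, _ = tiny_subject
        with pytest.raises(ValueError, match="no reduction"):
            build_reduction_pairs(meg, CollapseConfig(resample_hz=None))
        with pytest.raises(ValueError, match="unsupported"):
            build_reduction_pairs(meg, "pca")


class TestDownstreamStats:
    def test_perfect_line_gives_r_one(self):
        x = np.arange(6.0)
        res = mi_accuracy_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_textbook_t_from_r(self):
        # r = 0.8, n = 6 -> t = 0.8 sqrt(4 / 0.36) = 2.667, p from t(4)
        rng = np.random.default_rng(14)
        for _ in range(50):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            res = mi_accuracy_correlation(x, y)
            t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
            assert res.p == pytest.approx(2 * sp_stats.t.sf(abs(t), df=res.n - 2), rel=1e-9)
        t_ref = 0.8 * np.sqrt(4 / 0.36)
        assert t_ref == pytest.approx(2.667, abs=1e-3)

    def test_null_correlation_small(self):
        rng = np.random.default_rng(15)
        rs = [
            abs(mi_accuracy_correlation(rng.standard_normal(50), rng.standard_normal(50)).r)
            for _ in range(100)
        ]
        assert np.median(rs) < 0.2

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            mi_accuracy_correlation(np.ones(5), np.arange(5.0))

    def test_dimension_ttests(self):
        groups = {
            "channel": np.array([1.0, 2.0, 3.0]),
            "trial": np.array([1.0, 2.0, 3.0]),
            "temporal": np.array([1.001, 2.001, 2.999]),
        }
        out = mi_dimension_ttests(groups)
        t, p = out[("channel", "trial")]
        assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
        jitter = {"a": np.array([0.0, 1e-4, -1e-4]), "b": np.array([1.0, 1.0001, 0.9999])}
        t, p = mi_dimension_ttests(jitter)[("a", "b")]
        assert p < 0.01
        t_swapped, p_swapped = mi_dimension_ttests(
            {"a": jitter["b"], "b": jitter["a"]}
        )[("a", "b")]
        assert t_swapped == pytest.approx(-t) and p_swapped == pytest.approx(p)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            mi_dimension_ttests({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})
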