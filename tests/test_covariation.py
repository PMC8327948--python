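import numpy as np
import pytest

import morphomod as mm
from morphomod.covariation import CovariationError


def brute_force_cr(data, labels):
    """Direct evaluation of the covariance-ratio formula, independent of
    the optimized landmark-block path."""
    n, v = data.shape
    p = v // 3
    s = np.cov(data, rowvar=False)
    var_labels = np.repeat(labels, 3)
    a = var_labels == "NC"
    s11 = s[np.ix_(a, a)].copy()
    s22 = s[np.ix_(~a, ~a)].copy()
    s12 = s[np.ix_(a, ~a)]
    np.fill_diagonal(s11, 0.0)
    np.fill_diagonal(s22, 0.0)
    return np.sqrt(np.sum(s12**2)) / np.sqrt(
        np.sqrt(np.sum(s11**2)) * np.sqrt(np.sum(s22**2))
    )


@pytest.fixture()
def block_map():
    return mm.ModuleMap(assignment=["NC"] * 4 + ["MD"] * 4)


class TestCovarianceRatio:
    def test_matches_direct_formula_evaluation(self, rng, block_map):
        data = rng.normal(size=(9, 24))
        observed = mm.covariance_ratio(data, block_map)
        oracle = brute_force_cr(data, block_map.as_labels())
        assert observed == pytest.approx(oracle, rel=1e-12)

    def test_block_diagonal_covariance_gives_cr_near_zero(self):
        params = mm.SyntheticParams(
            p_nc=16, p_md=16, midline_nc=0, midline_md=0,
            rho_within_nc=0.5, rho_within_md=0.5, rho_between=0.0, seed=5,
        )
        data, mmap = mm.simulate_block_normal(800, params, seed=6)
        assert mm.covariance_ratio(data, mmap) < 0.25

    def test_exchangeable_covariance_gives_cr_near_one(self):
        params = mm.SyntheticParams(
            p_nc=40, p_md=40, midline_nc=0, midline_md=0,
            rho_within_nc=0.4, rho_within_md=0.4, rho_between=0.4, seed=5,
        )
        data, mmap = mm.simulate_block_normal(800, params, seed=7)
        assert mm.covariance_ratio(data, mmap) == pytest.approx(1.0, abs=0.06)

    def test_invariant_to_module_label_exchange(self, rng, block_map):
        data = rng.normal(size=(12, 24))
        flipped = mm.ModuleMap(
            assignment=["MD" if a == "NC" else "NC" for a in block_map.assignment]
        )
        assert mm.covariance_ratio(data, block_map) == pytest.approx(
            mm.covariance_ratio(data, flipped), rel=1e-12
        )

    def test_tiny_module_rejected(self, rng):
        data = rng.normal(size=(10, 9))
        mmap = mm.ModuleMap(assignment=["NC", "MD", "MD"])
        with pytest.raises(CovariationError, match="at least 2 landmarks"):
            mm.covariance_ratio(data, mmap)


class TestModularityTest:
    def test_modular_structure_detected(self):
        params = mm.strong_signal_params(seed=2)
        data, mmap = mm.simulate_block_normal(100, params, seed=2)
        res = mm.modularity_test(data, mmap, n_perm=199, seed=3)
        assert res.cr_observed < 1.0
        assert res.p_value <= 0.05

    def test_seeded_reproducibility(self):
        params = mm.strong_signal_params(seed=2)
        data, mmap = mm.simulate_block_normal(40, params, seed=2)
        r1 = mm.modularity_test(data, mmap, n_perm=199, seed=9)
        r2 = mm.modularity_test(data, mmap, n_perm=199, seed=9)
        np.testing.assert_array_equal(r1.perm_distribution, r2.perm_distribution)

    def test_observed_counted_in_null(self):
        params = mm.strong_signal_params(seed=2)
        data, mmap = mm.simulate_block_normal(40, params, seed=2)
        res = mm.modularity_test(data, mmap, n_perm=199, seed=9)
        assert res.p_value >= 1.0 / 199
        assert res.perm_distribution[0] == res.cr_observed


class TestTwoBlockPLS:
    def test_proportional_blocks_give_r_one(self, rng):
        x = rng.normal(size=(20, 12))
        data = np.hstack([x, 1.5 * x + 2.0])
        mmap = mm.ModuleMap(assignment=["NC"] * 4 + ["MD"] * 4)
        res = mm.two_block_pls(data, mmap, n_perm=99, seed=0)
        assert res.r_pls == pytest.approx(1.0, abs=1e-8)

    def test_first_singular_value_is_largest_eigenvalue_root(self, rng):
        data = rng.normal(size=(15, 24))
        mmap = mm.ModuleMap(assignment=["NC"] * 4 + ["MD"] * 4)
        res = mm.two_block_pls(data, mmap, n_perm=99, seed=0)
        xc = data[:, :12] - data[:, :12].mean(axis=0)
        yc = data[:, 12:] - data[:, 12:].mean(axis=0)
        s12 = xc.T @ yc / 14
        eigs = np.linalg.eigvalsh(s12 @ s12.T)
        assert res.singular_values[0] ** 2 == pytest.approx(eigs[-1], rel=1e-10)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_r_pls_equals_score_correlation(self, rng):
        data = rng.normal(size=(15, 24))
        mmap = mm.ModuleMap(assignment=["NC"] * 4 + ["MD"] * 4)
        res = mm.two_block_pls(data, mmap, n_perm=99, seed=0)
        assert res.r_pls == pytest.approx(
            np.corrcoef(res.x_scores, res.y_scores)[0, 1]
        )

    def test_independent_blocks_null_uniform(self, rng):
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            data = rng.normal(size=(50, 24))
            mmap = mm.ModuleMap(assignment=["NC"] * 4 + ["MD"] * 4)
            res = mm.two_block_pls(data, mmap, n_perm=99, seed=rep)
            rejections += res.p_value <= 0.05
        assert rejections / n_rep <= 0.15

    def test_rotation_of_block_variables_preserves_r(self, rng):
        data = rng.normal(size=(20, 24))
        mmap = mm.ModuleMap(assignment=["NC"] * 4 + ["MD"] * 4)
        r1 = mm.two_block_pls(data, mmap, n_perm=99, seed=0).r_pls
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        rotated = data.copy()
        rotated[:, :12] = data[:, :12] @ q
        r2 = mm.two_block_pls(rotated, mmap, n_perm=99, seed=0).r_pls
        assert r2 == pytest.approx(r1, rel=1e-8)


class TestComparePLSEffects:
    def test_self_comparison_is_null(self):
        params = mm.strong_signal_params(seed=2)
        data, mmap = mm.simulate_block_normal(60, params, seed=2)
        res = mm.two_block_pls(data, mmap, n_perm=199, seed=1)
        z_diff, p = mm.compare_pls_effects([res, res])
        assert z_diff[0, 1] == pytest.approx(0.0)
        assert p[0, 1] == pytest.approx(1.0)

    def test_weak_vs_strong_integration_differ(self):
        strong = mm.SyntheticParams(
            p_nc=16, p_md=16, midline_nc=0, midline_md=0,
            rho_within_nc=0.5, rho_within_md=0.5, rho_between=0.45, seed=4,
        )
        weak = mm.SyntheticParams(
            p_nc=16, p_md=16, midline_nc=0, midline_md=0,
            rho_within_nc=0.5, rho_within_md=0.5, rho_between=0.02, seed=4,
        )
        d1, m1 = mm.simulate_block_normal(100, strong, seed=1)
        d2, m2 = mm.simulate_block_normal(100, weak, seed=2)
        r1 = mm.two_block_pls(d1, m1, n_perm=199, seed=1)
        r2 = mm.two_block_pls(d2, m2, n_perm=199, seed=2)
        _, p = mm.compare_pls_effects([r1, r2])
        assert p[0, 1] <= 0.05

    def test_single_result_rejected(self):
        params = mm.strong_signal_params(seed=2)
        data, mmap = mm.simulate_block_normal(30, params, seed=2)
        res = mm.two_block_pls(data, mmap, n_perm=99, seed=1)
        with pytest.raises(CovariationError, match="at least 2"):
            mm.compare_pls_effects([res])


class TestEigenvalueDispersion:
    def test_identity_correlation_is_zero(self):
        assert mm.relative_eigenvalue_sd(np.eye(8)) == pytest.approx(0.0, abs=1e-12)

    def test_all_ones_correlation_is_one(self):
        assert mm.relative_eigenvalue_sd(np.ones((6, 6))) == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_exchangeable_closed_form(self, rho):
        n = 6
        corr = np.full((n, n), rho)
        np.fill_diagonal(corr, 1.0)
        assert mm.relative_eigenvalue_sd(corr) == pytest.approx(rho, abs=1e-12)

    def test_strictly_increasing_in_rho(self):
        values = []
        for rho in np.linspace(0.05, 0.95, 10):
            corr = np.full((9, 9), rho)
            np.fill_diagonal(corr, 1.0)
            values.append(mm.relative_eigenvalue_sd(corr))
        assert np.all(np.diff(values) > 0)

    def test_zero_variance_variable_named(self, rng):
        data = rng.normal(size=(12, 12))
        data[:, 4] = 3.0
        mmap = mm.ModuleMap(assignment=["NC", "NC", "MD", "MD"])
        with pytest.raises(CovariationError, match="landmark 2 axis y"):
            mm.eigenvalue_dispersion(data, mmap, "NC")

    def test_pipeline_dispersion_in_unit_interval(self, small_sim):
        for which in ("NC", "MD"):
            res = mm.eigenvalue_dispersion(
                small_sim["sym"], small_sim["module_map"], which
            )
            assert 0.0 < res.rel_eig_sd < 1.0
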