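"""Likelihood, linear predictors, the ICAR prior and the joint posterior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import binom

from scalemap import (
    ModelSpec,
    ParameterState,
    binomial_loglik,
    icar_full_conditional,
    icar_logpdf,
    linear_predictor,
    log_posterior,
    standardize_covariate,
)
from scalemap.errors import DegenerateCovariateError, DimensionError, IslandError


def random_state(geog, rng, sigma=0.5):
    st_ = ParameterState.zeros(geog)
    st_.beta0 = rng.normal(size=2)
    st_.beta1 = rng.normal(size=2)
    st_.v1 = rng.normal(0, sigma, geog.n_fine)
    st_.v2 = rng.normal(0, sigma, geog.n_coarse)
    st_.eps1 = rng.normal(0, sigma, geog.n_fine)
    st_.eps2 = rng.normal(0, sigma, geog.n_coarse)
    st_.sigma_v = rng.uniform(0.1, 2.0, 2)
    st_.sigma_eps = rng.uniform(0.1, 2.0, 2)
    return st_


class TestLinearPredictor:
    def test_all_zero_gives_even_odds(self, geog_6in2, data_6in2):
        spec = ModelSpec("independent")
        state = ParameterState.zeros(geog_6in2)
        for level in (1, 2):
            eta = linear_predictor(state, data_6in2, geog_6in2, level, spec)
            assert np.all(eta == 0)
            assert np.all(expit(eta) == 0.5)

    def test_shared_term_is_common_within_parent(self, geog_6in2, data_6in2):
        state = ParameterState.zeros(geog_6in2)
        state.v2 = np.array([0.7, -0.3])
        shared = ModelSpec("shared")
        eta1 = linear_predictor(state, data_6in2, geog_6in2, 1, shared)
        for i, u in enumerate(geog_6in2.fine_ids):
            expected = 0.7 if geog_6in2.parent[u] == "dA" else -0.3
            assert eta1[i] == pytest.approx(expected)
        # the districts' own predictor carries the same field
        eta2 = linear_predictor(state, data_6in2, geog_6in2, 2, shared)
        assert np.allclose(eta2, state.v2)
        # the independent model ignores it at the fine level
        eta1_ind = linear_predictor(state, data_6in2, geog_6in2, 1, ModelSpec())
        assert np.all(eta1_ind == 0)

    def test_matches_term_by_term_sum(self, geog_6in2, data_6in2):
        rng = np.random.default_rng(5)
        state = random_state(geog_6in2, rng)
        for kind in ("independent", "shared"):
            spec = ModelSpec(kind)
            eta = linear_predictor(state, data_6in2, geog_6in2, 1, spec)
            for i, u in enumerate(geog_6in2.fine_ids):
                by_hand = (
                    state.beta0[0]
                    + state.beta1[0] * data_6in2.fine.x[i]
                    + state.v1[i]
                    + state.eps1[i]
                )
                if kind == "shared":
                    by_hand += state.v2[geog_6in2.coarse_ids.index(geog_6in2.parent[u])]
                assert eta[i] == pytest.approx(by_hand, rel=1e-12)

    def test_dimension_mismatch_is_reported(self, geog_6in2, data_6in2):
        state = ParameterState.zeros(geog_6in2)
        state.v1 = np.zeros(4)
        with pytest.raises(DimensionError, match="level 1"):
            linear_predictor(state, data_6in2, geog_6in2, 1, ModelSpec())


PATH3 = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}}


class TestIcarLogpdf:
    def test_constant_field_leaves_only_rank_term(self):
        for sigma in (0.5, 1.0, 3.0):
            val = icar_logpdf(np.full(3, 7.7), PATH3, sigma)
            assert val == pytest.approx(-(3 - 1) * np.log(sigma))

    def test_path_forced_arithmetic(self):
        # pairwise sum (0-1)^2 + (1-3)^2 = 5, rank 2, sigma 1
        assert icar_logpdf([0.0, 1.0, 3.0], PATH3, 1.0) == pytest.approx(-2.5)

    def test_translation_invariance_per_component(self):
        rng = np.random.default_rng(8)
        adj = {"a": {"b"}, "b": {"a"}, "c": {"d"}, "d": {"c"}}
        v = rng.normal(size=4)
        base = icar_logpdf(v, adj, 0.7)
        shifted = v + np.array([3.3, 3.3, -1.1, -1.1])
        assert icar_logpdf(shifted, adj, 0.7) == pytest.approx(base, rel=1e-12)

    def test_matches_degenerate_gaussian_via_pseudoinverse(self):
        # on the sum-to-zero subspace the ICAR density is the Gaussian with
        # precision (D - W)/sigma^2; compare log-density differences
        rng = np.random.default_rng(13)
        n = 6
        adj = {f"u{i}": set() for i in range(n)}
        for _ in range(9):
            i, j = rng.choice(n, size=2, replace=False)
            adj[f"u{i}"].add(f"u{j}")
            adj[f"u{j}"].add(f"u{i}")
        import networkx as nx

        lap = np.zeros((n, n))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for a, nbrs in adj.items():
            ia = int(a[1:])
            for b in nbrs:
                lap[ia, ia] += 1
                lap[ia, int(b[1:])] -= 1
                g.add_edge(ia, int(b[1:]))
        sigma = 1.3
        for _ in range(5):
            z1, z2 = rng.normal(size=(2, n))
            # project each component to its sum-to-zero subspace
            for comp in nx.connected_components(g):
                idx = sorted(comp)
                z1[idx] -= z1[idx].mean()
                z2[idx] -= z2[idx].mean()
            got = icar_logpdf(z1, adj, sigma) - icar_logpdf(z2, adj, sigma)
            want = -0.5 * (z1 @ lap @ z1 - z2 @ lap @ z2) / sigma**2
            assert got == pytest.approx(want, rel=1e-9)

    def test_islands_are_proper_normal(self):
        adj = {"a": {"b"}, "b": {"a"}, "i": set()}
        v = np.array([0.2, -0.2, 1.5])
        sigma = 0.9
        with_island = icar_logpdf(v, adj, sigma)
        pair_only = icar_logpdf(v[:2], {"a": {"b"}, "b": {"a"}}, sigma)
        assert with_island == pytest.approx(
            pair_only - 1.5**2 / (2 * sigma**2) - np.log(sigma)
        )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            icar_logpdf([0.0, 0.0, 0.0], PATH3, 0.0)


class TestIcarFullConditional:
    def test_neighbour_mean_and_scaled_variance(self):
        mean, var = icar_full_conditional(1, [1.0, 0.0, 3.0], PATH3, 2.0)
        assert mean == pytest.approx(2.0)  # average of neighbours (1, 3)
        assert var == pytest.approx(2.0)  # 4 / degree 2

    def test_single_neighbour(self):
        mean, var = icar_full_conditional(0, [0.0, 7.0, 1.0], PATH3, 1.5)
        assert mean == pytest.approx(7.0)
        assert var == pytest.approx(1.5**2)

    def test_island_raises(self):
        with pytest.raises(IslandError):
            icar_full_conditional(0, [0.0], {"i": set()}, 1.0)

    def test_agrees_with_joint_density_curvature(self):
        # quadratic in v_i: recover mean/variance from three evaluations of
        # the joint log density and compare
        rng = np.random.default_rng(4)
        adj = {f"u{i}": set() for i in range(5)}
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (1, 3)]:
            adj[f"u{i}"].add(f"u{j}")
            adj[f"u{j}"].add(f"u{i}")
        v = rng.normal(size=5)
        sigma = 0.8
        for i in range(5):
            f = []
            for t in (-1.0, 0.0, 1.0):
                w = v.copy()
                w[i] = t
                f.append(icar_logpdf(w, adj, sigma))
            a = (f[0] + f[2]) / 2 - f[1]  # curvature/2
            b = (f[2] - f[0]) / 2  # slope at 0
            var_joint = -1.0 / (2 * a)
            mean_joint = b * var_joint
            mean, var = icar_full_conditional(i, v, adj, sigma)
            assert mean_joint == pytest.approx(mean, rel=1e-9, abs=1e-9)
            assert var_joint == pytest.approx(var, rel=1e-9)


class TestBinomialLoglik:
    def test_no_trials_no_information(self, geog_6in2, data_6in2):
        data_6in2.fine.y[:] = 0
        data_6in2.fine.n[:] = 0
        state = ParameterState.zeros(geog_6in2)
        assert binomial_loglik(state, data_6in2, geog_6in2, 1, ModelSpec()) == 0.0

    def test_even_odds_single_trial_pair(self, geog_6in2, data_6in2):
        data_6in2.fine.y[:] = 0
        data_6in2.fine.n[:] = 0
        data_6in2.fine.y[0], data_6in2.fine.n[0] = 1, 2
        state = ParameterState.zeros(geog_6in2)
        got = binomial_loglik(state, data_6in2, geog_6in2, 1, ModelSpec())
        assert got == pytest.approx(np.log(0.5))

    def test_matches_scipy_pmf_oracle(self, geog_6in2, data_6in2):
        rng = np.random.default_rng(11)
        state = random_state(geog_6in2, rng)
        for level in (1, 2):
            spec = ModelSpec("shared")
            eta = linear_predictor(state, data_6in2, geog_6in2, level, spec)
            ld = data_6in2.level(level)
            want = float(binom.logpmf(ld.y, ld.n, expit(eta)).sum())
            got = binomial_loglik(state, data_6in2, geog_6in2, level, spec)
            assert got == pytest.approx(want, rel=1e-10)

    def test_stable_at_extreme_eta(self, geog_6in2, data_6in2):
        state = ParameterState.zeros(geog_6in2)
        state.beta0[0] = 40.0
        val = binomial_loglik(state, data_6in2, geog_6in2, 1, ModelSpec())
        assert np.isfinite(val)

    @given(st.floats(-4, 4), st.floats(0.05, 4))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_concave_in_eta(self, center, h):
        y, n = 3.0, 10.0
        from scalemap.model import _binom_loglik_terms

        f = [float(_binom_loglik_terms(y, n, center + d)) for d in (-h, 0.0, h)]
        assert f[0] + f[2] - 2 * f[1] <= 1e-9


class TestLogPosterior:
    def test_outside_sd_prior_support(self, geog_6in2, data_6in2):
        spec = ModelSpec()
        state = ParameterState.zeros(geog_6in2)
        state.sigma_v[0] = spec.sd_prior_upper + 1.0
        assert log_posterior(state, data_6in2, geog_6in2, spec) == -np.inf

    def test_term_by_term_assembly(self, geog_6in2, data_6in2):
        rng = np.random.default_rng(2)
        state = random_state(geog_6in2, rng)
        spec = ModelSpec("shared")
        want = 0.0
        for level in (1, 2):
            want += binomial_loglik(state, data_6in2, geog_6in2, level, spec)
            k = level - 1
            want += icar_logpdf(
                state.v(level), geog_6in2.adjacency(level), state.sigma_v[k]
            )
            from scipy.stats import norm

            want += float(
                norm.logpdf(state.eps(level), 0, state.sigma_eps[k]).sum()
            )
            want += float(norm.logpdf(state.beta1[k], 0, spec.slope_prior_sd))
        got = log_posterior(state, data_6in2, geog_6in2, spec)
        assert got == pytest.approx(want, rel=1e-10)

    def test_sharing_term_vanishes_when_coarse_field_zero(self, geog_6in2, data_6in2):
        rng = np.random.default_rng(6)
        state = random_state(geog_6in2, rng)
        state.v2[:] = 0.0
        a = log_posterior(state, data_6in2, geog_6in2, ModelSpec("independent"))
        b = log_posterior(state, data_6in2, geog_6in2, ModelSpec("shared"))
        assert a == pytest.approx(b, rel=1e-12)


class TestStandardizeCovariate:
    def test_simple_example(self):
        x, mean, sd = standardize_covariate([1.0, 2.0, 3.0])
        assert np.allclose(x, [-1.0, 0.0, 1.0])
        assert mean == 2.0 and sd == 1.0

    @given(st.lists(st.integers(-10000, 10000).map(float), min_size=3, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_is_standardized(self, xs):
        x, _, _ = standardize_covariate(xs)
        assert np.mean(x) == pytest.approx(0.0, abs=1e-8)
        assert np.std(x, ddof=1) == pytest.approx(1.0, rel=1e-8)

    def test_constant_covariate_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            standardize_covariate([5.0, 5.0, 5.0])
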