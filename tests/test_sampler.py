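"""Sampler contracts: reductions with known answers, determinism,
diagnostics, and posterior summaries."""

import numpy as np
import pytest
from scipy.special import logit

from scalemap import (
    McmcConfig,
    ModelSpec,
    MultiscaleModel,
    PosteriorSamples,
    gelman_rubin,
    posterior_summary,
    run_mcmc,
)
from scalemap.sampler import SCALAR_NAMES, VECTOR_NAMES, _rhat_array


def make_samples(scalars_draws, n_fine=2, n_coarse=1, vectors=None, spec=None):
    """Hand-built PosteriorSamples for diagnostics tests.

    scalars_draws: dict name -> (chains, m) array; unnamed scalars are zero.
    """
    some = next(iter(scalars_draws.values()))
    c, m = np.asarray(some).shape
    scalars = {k: np.zeros((c, m)) for k in SCALAR_NAMES}
    for k, v in scalars_draws.items():
        scalars[k] = np.asarray(v, dtype=float)
    sizes = {"v_fine": n_fine, "eps_fine": n_fine, "v_coarse": n_coarse, "eps_coarse": n_coarse}
    vecs = {k: np.zeros((c, m, sizes[k])) for k in VECTOR_NAMES}
    if vectors:
        for k, v in vectors.items():
            vecs[k] = np.asarray(v, dtype=float)
    return PosteriorSamples(
        scalars=scalars,
        vectors=vecs,
        deviance={1: np.zeros((c, m)), 2: np.zeros((c, m))},
        eta_mean={1: np.zeros(n_fine), 2: np.zeros(n_coarse)},
        acceptance={},
        config=McmcConfig(n_chains=c, n_iter=m, burn_in=0, seed=0),
        spec=spec or ModelSpec(),
        fine_ids=[f"c{i}" for i in range(n_fine)],
        coarse_ids=[f"d{i}" for i in range(n_coarse)],
    )


class TestRunMcmc:
    def test_burnin_equal_iterations_gives_empty_sample(self, geog_6in2, data_6in2):
        config = McmcConfig(n_chains=2, n_iter=50, burn_in=50, seed=1)
        samples = run_mcmc(data_6in2, geog_6in2, ModelSpec(), config)
        assert samples.n_kept == 0
        assert samples.config.seed == 1
        assert samples.spec.model_kind == "independent"

    def test_identical_seed_identical_draws(self, geog_6in2, data_6in2):
        config = McmcConfig(n_chains=2, n_iter=300, burn_in=100, seed=77)
        a = run_mcmc(data_6in2, geog_6in2, ModelSpec("shared"), config)
        b = run_mcmc(data_6in2, geog_6in2, ModelSpec("shared"), config)
        for name in SCALAR_NAMES:
            assert np.array_equal(a.scalars[name], b.scalars[name])
        for name in VECTOR_NAMES:
            assert np.array_equal(a.vectors[name], b.vectors[name])
        c = run_mcmc(data_6in2, geog_6in2, ModelSpec("shared"),
                     McmcConfig(n_chains=2, n_iter=300, burn_in=100, seed=78))
        assert not np.array_equal(a.scalars["beta0_fine"], c.scalars["beta0_fine"])

    def test_fixed_effect_reduction_recovers_pooled_logit(self, geog_6in2, data_6in2):
        # with random effects switched off and equal per-unit rates the
        # intercept's posterior concentrates at logit of the pooled rate
        data_6in2.fine.y[:] = (data_6in2.fine.n * 0.1).astype(np.int64)
        config = McmcConfig(n_chains=2, n_iter=4000, burn_in=1000, seed=3,
                            update_v=False, update_eps=False, update_sigma=False)
        samples = run_mcmc(data_6in2, geog_6in2, ModelSpec(), config)
        pooled = logit(data_6in2.fine.y.sum() / data_6in2.fine.n.sum())
        b0 = samples.pooled("beta0_fine")
        assert b0.mean() == pytest.approx(pooled, abs=3 * b0.std() / 10 + 0.05)

    def test_stored_spatial_fields_are_centred(self, lattice_data):
        geog, data, _, _ = lattice_data
        res = MultiscaleModel(data, geog, kind="shared").fit(
            n_chains=2, n_iter=400, burn_in=200, seed=5
        )
        for name in ("v_fine", "v_coarse"):
            means = res.samples.vectors[name].mean(axis=2)
            assert np.abs(means).max() < 1e-10

    def test_adapted_acceptance_rates_are_reasonable(self, lattice_data):
        geog, data, _, _ = lattice_data
        res = MultiscaleModel(data, geog, kind="shared").fit(
            n_chains=1, n_iter=1500, burn_in=1000, seed=9
        )
        for name, rate in res.samples.acceptance.items():
            if name.startswith("v_"):
                # independence proposal from the prior conditional; its
                # acceptance is data- not tuning-driven
                assert 0.02 < rate < 1.0, name
            else:
                assert 0.1 < rate < 0.7, name


class TestRecentring:
    def test_recentring_transform_preserves_log_posterior(self, geog_6in2, data_6in2):
        # subtracting the CH mean and folding it into the intercept(s) is
        # exactly posterior-invariant on a connected map
        from scalemap import log_posterior
        from scalemap.model import ParameterState

        rng = np.random.default_rng(12)
        for kind in ("independent", "shared"):
            spec = ModelSpec(kind)
            state = ParameterState.zeros(geog_6in2)
            state.v1 = rng.normal(0, 0.8, geog_6in2.n_fine)
            state.v2 = rng.normal(0, 0.8, geog_6in2.n_coarse)
            state.eps1 = rng.normal(0, 0.3, geog_6in2.n_fine)
            state.eps2 = rng.normal(0, 0.3, geog_6in2.n_coarse)
            before = log_posterior(state, data_6in2, geog_6in2, spec)
            m1, m2 = state.v1.mean(), state.v2.mean()
            state.v1 -= m1
            state.v2 -= m2
            state.beta0[0] += m1
            state.beta0[1] += m2
            if kind == "shared":
                state.beta0[0] += m2
            after = log_posterior(state, data_6in2, geog_6in2, spec)
            assert after == pytest.approx(before, rel=1e-12)


class TestGelmanRubin:
    def test_iid_chains_close_to_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(3, 5000))
        s = make_samples({"beta0_fine": draws})
        r = gelman_rubin(s, params=["beta0_fine"])["beta0_fine"]
        assert 0.99 < r < 1.01

    def test_degenerate_separation_flags_infinity(self):
        s = make_samples({"beta0_fine": np.array([[1.0] * 20, [2.0] * 20])})
        assert gelman_rubin(s, params=["beta0_fine"])["beta0_fine"] == np.inf

    def test_constant_everywhere_is_one(self):
        s = make_samples({"beta0_fine": np.ones((2, 20))})
        assert gelman_rubin(s, params=["beta0_fine"])["beta0_fine"] == 1.0

    def test_separated_chains_exceed_threshold(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(2, 2000))
        draws[1] += 5.0
        s = make_samples({"beta0_fine": draws})
        assert gelman_rubin(s, params=["beta0_fine"])["beta0_fine"] > 1.1

    def test_matches_brute_force_variance_decomposition(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 500)) + rng.normal(size=(4, 1)) * 0.3
        m = draws.shape[1]
        w = np.mean([np.var(c, ddof=1) for c in draws])
        b = m * np.var([c.mean() for c in draws], ddof=1)
        want = np.sqrt((m - 1) / m + b / (m * w))
        assert _rhat_array(draws) == pytest.approx(want, rel=1e-12)

    def test_single_chain_directs_to_split_option(self):
        s = make_samples({"beta0_fine": np.zeros((1, 100))})
        with pytest.raises(ValueError, match="split"):
            gelman_rubin(s, params=["beta0_fine"])
        assert gelman_rubin(s, params=["beta0_fine"], split=True)["beta0_fine"] == 1.0

    def test_vector_components_are_addressable(self):
        rng = np.random.default_rng(3)
        s = make_samples(
            {"beta0_fine": rng.normal(size=(2, 200))},
            vectors={"v_fine": rng.normal(size=(2, 200, 2))},
        )
        r = gelman_rubin(s, params=["v_fine[c0]", "v_fine[c1]"])
        assert set(r.index) == {"v_fine[c0]", "v_fine[c1]"}


class TestPosteriorSummary:
    def test_constant_draws(self):
        s = make_samples({"beta1_fine": np.full((2, 50), 3.25)})
        row = posterior_summary(s, ["beta1_fine"]).loc["beta1_fine"]
        assert row["mean"] == 3.25 and row["sd"] == 0.0
        assert row["2.5%"] == row["97.5%"] == 3.25

    def test_percentiles_match_sorting_oracle(self):
        draws = np.arange(1.0, 101.0).reshape(1, 100)
        s = make_samples({"beta0_coarse": draws})
        row = posterior_summary(s, ["beta0_coarse"]).loc["beta0_coarse"]
        flat = np.sort(draws.ravel())
        assert row["2.5%"] == pytest.approx(np.percentile(flat, 2.5))
        assert row["97.5%"] == pytest.approx(np.percentile(flat, 97.5))
        assert row["mean"] == pytest.approx(flat.mean())

    def test_unknown_parameter_lists_names(self):
        s = make_samples({"beta0_fine": np.zeros((2, 20))})
        with pytest.raises(KeyError, match="beta0_fine"):
            posterior_summary(s, ["not_a_parameter"])

    def test_samples_roundtrip_through_cache(self, tmp_path):
        rng = np.random.default_rng(4)
        s = make_samples({"beta0_fine": rng.normal(size=(2, 30))})
        path = tmp_path / "cache.npz"
        s.save(path)
        back = PosteriorSamples.load(path)
        assert np.array_equal(back.scalars["beta0_fine"], s.scalars["beta0_fine"])
        assert back.config == s.config
        assert back.spec == s.spec
        assert back.fine_ids == s.fine_ids
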