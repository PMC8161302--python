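import numpy as np
import pytest
from scipy import stats

from sharedrisk import (
    AreaGraph,
    McmcConfig,
    PriorConfig,
    build_lattice,
    icar_full_conditional,
    icar_logkernel,
    rhat,
    run_chains,
    simulate_icar_field,
    summarize,
)
from sharedrisk.mcmc import (
    McmcInitializationError,
    MetropolisModel,
    adapt_log_scale,
    gibbs_icar_sample,
)


class TestConfigs:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)

    def test_adaptation_cannot_outlive_burn_in(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=10, adapt_until=50)

    def test_priors_positive(self):
        with pytest.raises(ValueError):
            PriorConfig(sigma_upper=0.0)


class TestIcarKernel:
    def test_constant_field_zero_pairwise_term(self, lattice5):
        f = np.full(lattice5.n_areas, 3.7)
        assert icar_logkernel(f, lattice5, 1.0) == pytest.approx(0.0)

    def test_path_graph_hand_value(self, path3):
        # squared neighbour differences: (0-(-1))^2 + (1-0)^2 = 2 -> -1.0
        assert icar_logkernel(np.array([-1.0, 0.0, 1.0]), path3, 1.0) == pytest.approx(
            -1.0
        )

    def test_translation_invariance(self, lattice5, rng):
        f = rng.standard_normal(lattice5.n_areas)
        a = icar_logkernel(f, lattice5, 0.8)
        b = icar_logkernel(f + 11.3, lattice5, 0.8)
        assert a == pytest.approx(b, abs=1e-9)

    def test_invalid_sigma(self, path3):
        with pytest.raises(ValueError):
            icar_logkernel(np.zeros(3), path3, -1.0)

    def test_matches_generalized_inverse_normal_oracle(self, rng):
        # log-density differences of sum-to-zero fields must match the
        # singular multivariate normal with covariance sigma^2 * pinv(L)
        g = build_lattice(2, 3, "rook")
        sigma = 0.9
        L = g.laplacian.toarray()
        oracle = stats.multivariate_normal(
            mean=np.zeros(g.n_areas), cov=sigma**2 * np.linalg.pinv(L),
            allow_singular=True,
        )
        for _ in range(5):
            f1 = simulate_icar_field(g, sigma, rng)
            f2 = simulate_icar_field(g, sigma, rng)
            ours = icar_logkernel(f1, g, sigma) - icar_logkernel(f2, g, sigma)
            theirs = oracle.logpdf(f1) - oracle.logpdf(f2)
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestIcarFullConditional:
    def test_interior_node(self, path3):
        mean, var = icar_full_conditional(np.array([-1.0, 5.0, 1.0]), 1, path3, 2.0)
        assert mean == pytest.approx(0.0)
        assert var == pytest.approx(2.0)  # sigma^2 / n_i = 4 / 2

    def test_leaf_node(self, path3):
        mean, var = icar_full_conditional(np.array([0.0, 0.7, 0.0]), 0, path3, 1.0)
        assert mean == pytest.approx(0.7)
        assert var == pytest.approx(1.0)

    def test_gibbs_matches_direct_sampler(self):
        # dual-route check: conditional-based Gibbs vs the Cholesky sampler
        g = AreaGraph(list("ABCD"), [(0, 1), (1, 2), (2, 3), (3, 0)])
        sigma = 0.8
        gibbs = gibbs_icar_sample(g, sigma, n_draws=4000, seed=21, thin=5)
        rng = np.random.default_rng(22)
        direct = np.array([simulate_icar_field(g, sigma, rng) for _ in range(4000)])
        for j in range(g.n_areas):
            assert stats.ks_2samp(gibbs[:, j], direct[:, j]).pvalue > 0.01


class TestRhat:
    def test_label_permutation_invariance(self, rng):
        chains = rng.standard_normal((4, 200))
        assert rhat(chains) == pytest.approx(rhat(chains[::-1]))

    def test_iid_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert rhat(chains) < 1.05

    def test_separated_chains_flagged(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert rhat(chains) > 3.0

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(rhat(np.ones((2, 10))))

    def test_agrees_with_arviz(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = np.cumsum(rng.standard_normal((4, 500)), axis=1) * 0.05
        chains += rng.standard_normal((4, 500))
        ours = rhat(chains)
        theirs = float(
            arviz.rhat(arviz.convert_to_dataset(chains[:, :, None]))["x"].values[0]
        )
        assert ours == pytest.approx(theirs, abs=0.02)


class TestSummarize:
    def test_constant_draws(self):
        out = summarize({"c": np.full((2, 50), 4.2)})
        row = out.loc["c"]
        assert row["mean"] == pytest.approx(4.2)
        assert row["sd"] == 0.0
        assert (row["q2.5"], row["q97.5"]) == (pytest.approx(4.2), pytest.approx(4.2))

    def test_sequence_mean(self):
        draws = np.arange(1.0, 101.0).reshape(1, 100)
        assert summarize({"x": draws}).loc["x", "mean"] == pytest.approx(50.5)

    def test_normal_interval_matches_closed_form(self, rng):
        x = 2.0 + 0.5 * rng.standard_normal((4, 20000))
        row = summarize({"x": x}).loc["x"]
        assert row["q2.5"] == pytest.approx(2.0 - 1.96 * 0.5, abs=0.02)
        assert row["q97.5"] == pytest.approx(2.0 + 1.96 * 0.5, abs=0.02)

    def test_vector_parameters_expanded(self, rng):
        out = summarize({"v": rng.standard_normal((2, 100, 3))})
        assert list(out.index) == ["v[0]", "v[1]", "v[2]"]


# ---------------------------------------------------------------------- #
class _GaussianRw(MetropolisModel):
    """Adapted random walk targeting one (or two correlated) normals."""

    def __init__(self, correlation=None):
        self.corr = correlation
        self.dim = 1 if correlation is None else 2
        if self.corr is not None:
            cov = np.array([[1.0, self.corr], [self.corr, 1.0]])
            self.prec = np.linalg.inv(cov)
        self.adapt_flags = []
        self.scale_trace = []

    def logpdf(self, x):
        if self.corr is None:
            return -0.5 * float(x[0] ** 2)
        return -0.5 * float(x @ self.prec @ x)

    def init_state(self, rng):
        return {"x": np.zeros(self.dim), "log_scale": np.log(1.0), "t": 0}

    def sweep(self, state, rng, adapting):
        self.adapt_flags.append(adapting)
        self.scale_trace.append(state["log_scale"])
        prop = state["x"] + np.exp(state["log_scale"]) * rng.standard_normal(self.dim)
        log_r = self.logpdf(prop) - self.logpdf(state["x"])
        if np.log(rng.uniform()) < log_r:
            state["x"] = prop
        if adapting:
            state["log_scale"] = adapt_log_scale(
                state["log_scale"], np.exp(min(log_r, 0.0)), state["t"], 0.44
            )
        state["t"] += 1

    def tracked(self, state):
        return {"x": state["x"].copy()}

    def log_posterior(self, state):
        return self.logpdf(state["x"])


class _BrokenInit(_GaussianRw):
    def init_state(self, rng):
        state = super().init_state(rng)
        state["x"] = np.array([np.nan])
        return state


class TestRunChains:
    def test_standard_normal_target_recovered(self):
        cfg = McmcConfig(n_iter=4000, burn_in=500, thin=1, n_chains=4, seed=5)
        draws = run_chains(_GaussianRw(), cfg)["x"][:, :, 0]
        assert abs(draws.mean()) < 0.05
        assert rhat(draws) < 1.01

    def test_correlated_normal_recovered(self):
        cfg = McmcConfig(n_iter=6000, burn_in=1000, thin=1, n_chains=4, seed=6)
        draws = run_chains(_GaussianRw(correlation=0.7), cfg)["x"]
        flat = draws.reshape(-1, 2)
        assert np.corrcoef(flat.T)[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_seed_reproducibility(self):
        cfg = McmcConfig(n_iter=500, burn_in=100, thin=2, n_chains=2, seed=11)
        a = run_chains(_GaussianRw(), cfg)["x"]
        b = run_chains(_GaussianRw(), cfg)["x"]
        assert np.array_equal(a, b)

    def test_nonfinite_init_raises(self):
        cfg = McmcConfig(n_iter=100, burn_in=10)
        with pytest.raises(McmcInitializationError):
            run_chains(_BrokenInit(), cfg)

    def test_adaptation_frozen_after_window(self):
        model = _GaussianRw()
        cfg = McmcConfig(
            n_iter=400, burn_in=200, adapt_until=150, thin=1, n_chains=1, seed=3
        )
        run_chains(model, cfg)
        flags = np.array(model.adapt_flags)
        scales = np.array(model.scale_trace)
        assert flags[:150].all() and not flags[150:].any()
        # proposal scale never changes once adaptation has stopped
        assert np.all(scales[151:] == scales[151])

    def test_retained_draw_count(self):
        cfg = McmcConfig(n_iter=1000, burn_in=100, thin=7, n_chains=2, seed=1)
        draws = run_chains(_GaussianRw(), cfg)["x"]
        assert draws.shape == (2, cfg.n_kept, 1)
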