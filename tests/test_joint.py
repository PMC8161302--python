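import numpy as np
import pytest
from scipy import stats

from sharedrisk import (
    JointModelState,
    JointScenario,
    SharedComponentModel,
    build_lattice,
    export_shared_surface,
    joint_log_mu,
    shared_variance_fractions,
    simulate_joint_dataset,
)
from sharedrisk.joint import _SIGMA_KEYS, _JointGibbs, joint_log_likelihood
from sharedrisk.mcmc import PriorConfig


def make_state(n, alpha=(0.0, 0.0), log_delta=0.0, **fields):
    base = dict(
        alpha=np.asarray(alpha, dtype=float),
        log_delta=log_delta,
        phi_str=np.zeros(n),
        phi_het=np.zeros(n),
        psi_str=np.zeros((2, n)),
        psi_het=np.zeros((2, n)),
        sigma={k: 0.5 for k in _SIGMA_KEYS},
    )
    base.update(fields)
    return JointModelState(**base)


class TestJointLogMu:
    def test_null_state_returns_expected_counts(self):
        E = np.array([[2.0, 3.0], [4.0, 5.0]])
        state = make_state(2)
        assert np.allclose(joint_log_mu(state, E, 1), E[:, 0])
        assert np.allclose(joint_log_mu(state, E, 2), E[:, 1])

    def test_scaling_factor_splits_shared_increment(self):
        # delta = 1.004, phi = 0.5: outcome-1 increment 0.502, outcome-2 0.498
        E = np.ones((3, 2))
        state = make_state(3, log_delta=np.log(1.004), phi_het=np.full(3, 0.5))
        inc1 = np.log(joint_log_mu(state, E, 1))
        inc2 = np.log(joint_log_mu(state, E, 2))
        assert inc1 == pytest.approx(0.5 * 1.004)
        assert inc2 == pytest.approx(0.5 / 1.004)

    def test_invalid_outcome(self):
        with pytest.raises(ValueError, match="outcome"):
            joint_log_mu(make_state(2), np.ones((2, 2)), 3)

    def test_outcome_swap_symmetry(self, rng):
        # swapping psi_1/psi_2 with delta -> 1/delta swaps the two outcomes
        n = 6
        E = np.ones((n, 2))
        psi = rng.standard_normal((2, n))
        phi = rng.standard_normal(n)
        s = make_state(n, log_delta=0.3, phi_het=phi, psi_het=psi)
        swapped = make_state(n, log_delta=-0.3, phi_het=phi, psi_het=psi[::-1].copy())
        assert np.allclose(joint_log_mu(s, E, 1), joint_log_mu(swapped, E, 2))
        assert np.allclose(joint_log_mu(s, E, 2), joint_log_mu(swapped, E, 1))


class TestSharedVarianceFractions:
    def test_no_specific_variation_gives_one(self):
        state = make_state(3, phi_het=np.array([1.0, -1.0, 0.0]))
        eta1, eta2 = shared_variance_fractions(state)
        assert eta1 == pytest.approx(1.0)
        assert eta2 == pytest.approx(1.0)

    def test_equal_variances_give_half(self):
        psi = np.zeros((2, 3))
        psi[0] = [-1.0, 1.0, 0.0]
        state = make_state(3, phi_het=np.array([1.0, -1.0, 0.0]), psi_het=psi)
        eta1, _ = shared_variance_fractions(state)
        assert eta1 == pytest.approx(0.5)

    def test_hand_computed_delta_two_case(self):
        # delta = 2, phi = (1,-1), psi_2 = (1,-1):
        # eta_2 = V(phi/2) / (V(phi/2) + V(psi_2)) = 0.25 / (0.25 + 1) = 0.2
        psi = np.zeros((2, 2))
        psi[1] = [1.0, -1.0]
        state = make_state(
            2, log_delta=np.log(2.0), phi_het=np.array([1.0, -1.0]), psi_het=psi
        )
        _, eta2 = shared_variance_fractions(state)
        assert eta2 == pytest.approx(0.2)

    def test_degenerate_fields_warn_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            eta1, _ = shared_variance_fractions(make_state(4))
        assert np.isnan(eta1)


class TestLikelihood:
    def test_matches_poisson_pmf_oracle(self, lattice5, rng):
        data, _ = simulate_joint_dataset(lattice5, seed=3)
        n = lattice5.n_areas
        for _ in range(5):
            state = make_state(
                n,
                alpha=rng.normal(size=2) * 0.2,
                log_delta=rng.normal() * 0.1,
                phi_str=rng.normal(size=n) * 0.3,
                phi_het=rng.normal(size=n) * 0.1,
                psi_str=rng.normal(size=(2, n)) * 0.2,
                psi_het=rng.normal(size=(2, n)) * 0.1,
            )
            oracle = sum(
                stats.poisson.logpmf(
                    data.Y[:, k - 1], joint_log_mu(state, data.E, k)
                ).sum()
                for k in (1, 2)
            )
            assert joint_log_likelihood(state, data) == pytest.approx(
                oracle, abs=1e-10
            )

    def test_scaling_symmetry_leaves_mu_unchanged(self, rng):
        # (phi, delta) -> (c phi, delta) with psi absorbing the difference
        # is likelihood-invariant: an identifiability caveat, not a bug
        n, c = 5, 1.7
        E = np.ones((n, 2))
        phi = rng.standard_normal(n)
        state = make_state(n, phi_het=phi)
        delta = state.delta
        psi = np.zeros((2, n))
        psi[0] = delta * (1 - c) * phi
        psi[1] = (1 - c) * phi / delta
        rescaled = make_state(n, phi_het=c * phi, psi_het=psi)
        for k in (1, 2):
            assert np.allclose(joint_log_mu(state, E, k), joint_log_mu(rescaled, E, k))


class TestCollapsedCore:
    """The collapsed-marginal and exact-allocation machinery against oracles.

    The sampler integrates the six-way field allocation out of
    ``p(T | delta, sigma)`` analytically and redraws the allocation from
    its Gaussian conditional; both pieces are checked against independent
    brute-force constructions.
    """

    @staticmethod
    def _sampler(graph, seed=0):
        data, _ = simulate_joint_dataset(graph, seed=seed)
        return _JointGibbs(data, graph, PriorConfig(), 0.44)

    def _init_state(self, graph, rng):
        n = graph.n_areas
        return make_state(
            n,
            phi_str=rng.standard_normal(n) * 0.5,
            phi_het=rng.standard_normal(n) * 0.2,
            psi_str=rng.standard_normal((2, n)) * 0.4,
            psi_het=rng.standard_normal((2, n)) * 0.2,
        )

    def test_marginal_matches_dense_gaussian_oracle(self, rng):
        # build the totals' covariance directly from sigma^2 pinv(L) blocks
        # and compare log-density differences across (delta, sigma) settings
        graph = build_lattice(2, 3, "rook")
        sampler = self._sampler(graph)
        n = graph.n_areas
        L = graph.laplacian.toarray()
        Lp = np.linalg.pinv(L, hermitian=True)
        T = rng.standard_normal(2 * n)
        t1 = sampler.eig_vec.T @ T[:n]
        t2 = sampler.eig_vec.T @ T[n:]

        def oracle(log_delta, sig):
            d2 = np.exp(2 * log_delta)
            S = sig["phi_str"] ** 2 * Lp + sig["phi_het"] ** 2 * np.eye(n)
            S1 = sig["psi1_str"] ** 2 * Lp + sig["psi1_het"] ** 2 * np.eye(n)
            S2 = sig["psi2_str"] ** 2 * Lp + sig["psi2_het"] ** 2 * np.eye(n)
            cov = np.block([[d2 * S + S1, S], [S, S / d2 + S2]])
            sign, logdet = np.linalg.slogdet(cov)
            return -0.5 * (logdet + T @ np.linalg.solve(cov, T))

        settings = [
            (0.0, {k: 0.5 for k in _SIGMA_KEYS}),
            (0.2, {k: v for k, v in zip(_SIGMA_KEYS, (0.4, 0.1, 0.3, 0.2, 0.6, 0.1))}),
            (-0.3, {k: v for k, v in zip(_SIGMA_KEYS, (0.8, 0.3, 0.2, 0.4, 0.3, 0.2))}),
        ]
        ref_mine = sampler._log_marginal_totals(t1, t2, *settings[0])
        ref_oracle = oracle(*settings[0])
        for ld, sig in settings[1:]:
            mine = sampler._log_marginal_totals(t1, t2, ld, sig) - ref_mine
            theirs = oracle(ld, sig) - ref_oracle
            assert mine == pytest.approx(theirs, abs=1e-9)

    def test_allocation_redraw_matches_constrained_gaussian_oracle(self):
        # the conditional of the 6n-dim allocation given the two totals is
        # Gaussian; compare the sampler's empirical moments with the
        # closed-form conditional mean / covariance built densely
        graph = build_lattice(2, 3, "rook")
        sampler = self._sampler(graph)
        rng = np.random.default_rng(1)
        state = self._init_state(graph, rng)
        delta = state.delta
        t1 = delta * state.phi + state.psi[0]
        t2 = state.phi / delta + state.psi[1]
        n = graph.n_areas

        n_draws = 20000
        draws = np.empty((n_draws, 6 * n))
        for m in range(n_draws):
            sampler._redraw_allocation(state, rng)
            draws[m] = np.concatenate(
                [state.phi_str, state.phi_het,
                 state.psi_str[0], state.psi_het[0],
                 state.psi_str[1], state.psi_het[1]]
            )
            # constraints hold after every redraw
            if m == 0:
                assert np.allclose(delta * state.phi + state.psi[0], t1, atol=1e-8)
                assert np.allclose(state.phi / delta + state.psi[1], t2, atol=1e-8)
                assert abs(state.phi_str.sum()) < 1e-8

        # dense oracle: prior covariance blocks sigma^2 pinv(L) / sigma^2 I,
        # conditioned on A x = (t1, t2)
        Lp = np.linalg.pinv(graph.laplacian.toarray(), hermitian=True)
        eye = np.eye(n)
        sig = state.sigma
        blocks = [
            sig["phi_str"] ** 2 * Lp, sig["phi_het"] ** 2 * eye,
            sig["psi1_str"] ** 2 * Lp, sig["psi1_het"] ** 2 * eye,
            sig["psi2_str"] ** 2 * Lp, sig["psi2_het"] ** 2 * eye,
        ]
        cov = np.zeros((6 * n, 6 * n))
        for j, blk in enumerate(blocks):
            cov[j * n : (j + 1) * n, j * n : (j + 1) * n] = blk
        A = np.zeros((2 * n, 6 * n))
        A[:n, 0 * n : 1 * n] = delta * eye
        A[:n, 1 * n : 2 * n] = delta * eye
        A[:n, 2 * n : 3 * n] = eye
        A[:n, 3 * n : 4 * n] = eye
        A[n:, 0 * n : 1 * n] = eye / delta
        A[n:, 1 * n : 2 * n] = eye / delta
        A[n:, 4 * n : 5 * n] = eye
        A[n:, 5 * n : 6 * n] = eye
        t = np.concatenate([t1, t2])
        gain = cov @ A.T @ np.linalg.inv(A @ cov @ A.T)
        mean = gain @ t
        cond_cov = cov - gain @ A @ cov

        se = np.sqrt(np.diag(cond_cov) / n_draws)
        assert np.allclose(draws.mean(axis=0), mean, atol=np.maximum(5 * se, 1e-6))
        assert np.allclose(
            draws.var(axis=0), np.diag(cond_cov), atol=0.05, rtol=0.1
        )


class TestFittedModel:
    @pytest.fixture(scope="class")
    def short_fit(self):
        graph = build_lattice(5, 5, "rook")
        data, truth = simulate_joint_dataset(
            graph, JointScenario(mean_expected=(40.0, 40.0)), seed=9
        )
        est = SharedComponentModel(
            n_iter=1500, burn_in=400, thin=2, n_chains=2, random_state=4
        ).fit(data, graph)
        return graph, data, truth, est

    def test_eta_draws_in_unit_interval(self, short_fit):
        _, _, _, est = short_fit
        for name in ("eta1", "eta2"):
            draws = est.draws_[name]
            assert np.all((draws >= 0.0) & (draws <= 1.0))

    def test_shared_surface_record_count_and_centering(self, short_fit):
        graph, data, _, est = short_fit
        surf = est.shared_surface_
        assert len(surf) == graph.n_areas
        assert abs(surf["shared_mean"].mean()) < 1e-8

    def test_export_invariant_to_area_table_order(self, short_fit, rng):
        import pandas as pd

        graph, data, _, est = short_fit
        table = pd.DataFrame({"area_id": data.area_ids, "extra": range(data.n_areas)})
        shuffled = table.sample(frac=1.0, random_state=7)
        a = export_shared_surface(est, table)
        b = export_shared_surface(est, shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_export_rejects_mismatched_ids(self, short_fit):
        import pandas as pd

        _, _, _, est = short_fit
        bad = pd.DataFrame({"area_id": ["zz"]})
        with pytest.raises(ValueError, match="ids"):
            export_shared_surface(est, bad)

    def test_mismatched_graph_rejected(self, short_fit):
        graph, data, _, _ = short_fit
        other = build_lattice(5, 5, "queen")
        est = SharedComponentModel(n_iter=10, burn_in=5)
        with pytest.raises(ValueError, match="area ids"):
            est.fit(data, build_lattice(4, 5))


class TestNullRecovery:
    def test_null_data_yields_null_shared_surface(self):
        graph = build_lattice(5, 5, "rook")
        scen = JointScenario(
            sigma_phi_str=0.0, sigma_phi_het=0.0,
            sigma_psi_str=(0.0, 0.0), sigma_psi_het=(0.0, 0.0),
            mean_expected=(40.0, 40.0),
        )
        data, _ = simulate_joint_dataset(graph, scen, seed=14)
        est = SharedComponentModel(
            n_iter=1500, burn_in=400, thin=2, n_chains=2, random_state=6
        ).fit(data, graph)
        surf = est.shared_surface_
        assert np.all(surf["shared_q2.5"] <= 0.0 + 1e-9)
        assert np.all(surf["shared_q97.5"] >= 0.0 - 1e-9)
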