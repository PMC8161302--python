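"""Shared-component joint Poisson model for two area-level count outcomes.

Both outcomes are Poisson with population-based expected counts as offset;
their log-relative-risks decompose into one **shared** latent surface
``phi`` — entering outcome 1 as ``phi * delta`` and outcome 2 as
``phi / delta``, where the scaling factor ``delta`` absorbs a difference in
the magnitude of the two risk gradients — plus outcome-specific surfaces
``psi_k``:

    Y_ik ~ Poisson(mu_ik)
    log mu_i1 = log E_i1 + alpha_1 + phi_i * delta + psi_i1
    log mu_i2 = log E_i2 + alpha_2 + phi_i / delta + psi_i2

Every latent surface is the sum of a spatially structured intrinsic-CAR
part and an unstructured iid Gaussian part.  The headline summary is the
pair of shared-variance fractions

    eta_1 = V(delta * phi) / (V(delta * phi) + V(psi_1))
    eta_2 = V(phi / delta) / (V(phi / delta) + V(psi_2))

computed per retained draw from the empirical across-area variances of the
full (structured + unstructured) fields, then summarised: the proportion of
each outcome's between-area risk variation captured by the shared surface.

Priors: flat on the intercepts, Normal(0, sd) on ``log delta`` (weak
shrinkage of delta toward 1), U(0, upper) on every field scale.

Inference is Metropolis-within-Gibbs with a partially collapsed core.  The
likelihood depends on the latent fields only through the two totals
``T_1 = delta * phi + psi_1`` and ``T_2 = phi / delta + psi_2``, and all
six field priors share the graph Laplacian, so in the Laplacian eigenbasis
the totals' marginal ``p(T | delta, sigma)`` — with the six-way allocation
integrated out — factorises into per-coordinate bivariate normals.  Each
sweep therefore (i) moves the totals with vectorised single-site
Metropolis steps against the Poisson likelihood, (ii) updates ``delta``
and the six scales by Metropolis against the collapsed marginal, and
(iii) redraws the allocation exactly from its Gaussian conditional given
the totals.  Without the collapsed step, allocation-dependent samplers
mix across the shared/specific decomposition extremely slowly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning

from .datasets import AreaDataset
from .graph import AreaGraph
from .mcmc import (
    McmcConfig,
    MetropolisModel,
    PriorConfig,
    _gibbs_sigma,
    _mh_het_field,
    _mh_structured_field,
    _poisson_delta_loglik,
    adapt_log_scale,
    icar_logkernel,
    run_chains,
    summarize,
)

__all__ = [
    "JointModelState",
    "SharedComponentModel",
    "joint_log_mu",
    "shared_variance_fractions",
    "joint_log_likelihood",
    "fit_joint",
    "export_shared_surface",
]

_SIGMA_KEYS = ("phi_str", "phi_het", "psi1_str", "psi1_het", "psi2_str", "psi2_het")


@dataclass
class JointModelState:
    """One point in the joint model's parameter space."""

    alpha: np.ndarray  # (2,)
    log_delta: float
    phi_str: np.ndarray  # (n,)
    phi_het: np.ndarray  # (n,)
    psi_str: np.ndarray  # (2, n)
    psi_het: np.ndarray  # (2, n)
    sigma: dict[str, float]

    @property
    def delta(self) -> float:
        return float(np.exp(self.log_delta))

    @property
    def phi(self) -> np.ndarray:
        """Full shared field (structured + unstructured)."""
        return self.phi_str + self.phi_het

    @property
    def psi(self) -> np.ndarray:
        """Full specific fields, shape (2, n)."""
        return self.psi_str + self.psi_het


def joint_log_mu(state: JointModelState, E: np.ndarray, outcome: int) -> np.ndarray:
    """Poisson mean of one outcome under the shared-component model.

    ``outcome`` is 1 or 2; the shared field is scaled by ``delta`` for
    outcome 1 and ``1/delta`` for outcome 2.  Despite the name (kept
    parallel to the model equations) this returns ``mu`` itself.
    """
    if outcome not in (1, 2):
        raise ValueError(f"outcome must be 1 or 2, got {outcome}")
    k = outcome - 1
    coef = state.delta if outcome == 1 else 1.0 / state.delta
    log_mu = (
        np.log(np.asarray(E, dtype=float)[:, k])
        + state.alpha[k]
        + coef * state.phi
        + state.psi[k]
    )
    return np.exp(log_mu)


def shared_variance_fractions(state: JointModelState) -> tuple[float, float]:
    """Shared-variance fractions (eta_1, eta_2) of one state.

    Empirical across-area variance of the scaled shared field over the sum
    with the specific field's variance; NaN with a warning when both
    variances vanish (the fraction is then undefined).
    """
    if state.phi.shape[0] < 2:
        raise ValueError("shared-variance fractions need at least 2 areas")
    out = []
    for k, coef in enumerate((state.delta, 1.0 / state.delta)):
        v_shared = float(np.var(coef * state.phi))
        v_specific = float(np.var(state.psi[k]))
        if v_shared + v_specific == 0.0:
            warnings.warn(
                f"eta_{k + 1} undefined: shared and specific fields both constant",
                stacklevel=2,
            )
            out.append(float("nan"))
        else:
            out.append(v_shared / (v_shared + v_specific))
    return out[0], out[1]


def joint_log_likelihood(state: JointModelState, data: AreaDataset) -> float:
    """Full Poisson log-likelihood sum_ik [Y log mu - mu - log(Y!)]."""
    total = 0.0
    for outcome in (1, 2):
        mu = joint_log_mu(state, data.E, outcome)
        y = data.Y[:, outcome - 1]
        total += float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    return total


# --------------------------------------------------------------------- #
# sampler
# --------------------------------------------------------------------- #
class _JointGibbs(MetropolisModel):
    """Metropolis-within-Gibbs schedule with a collapsed (delta, sigma) core."""

    def __init__(
        self,
        data: AreaDataset,
        graph: AreaGraph,
        priors: PriorConfig,
        target_accept: float,
        track_field: bool = True,
    ):
        self.data = data
        self.graph = graph
        self.priors = priors
        self.target = target_accept
        self.track_field = track_field
        self.Y = data.Y.astype(float)
        self.logE = np.log(data.E)
        self.n = graph.n_areas
        self.rank = graph.n_areas - len(graph.components)
        lam, V = graph.laplacian_eigh
        self.eig_vec = V
        # pseudo-inverse eigenvalues of L: variance multiplier of the
        # structured parts per eigencoordinate (0 in the null space, which
        # encodes the per-component sum-to-zero constraint)
        self.eig_g = np.where(lam > 1e-9, 1.0 / np.where(lam > 0, lam, 1.0), 0.0)

    # -- state bookkeeping ------------------------------------------- #
    def init_state(self, rng: np.random.Generator) -> JointModelState:
        n = self.n
        with np.errstate(divide="ignore"):
            alpha0 = np.log(self.Y.sum(axis=0) / self.data.E.sum(axis=0))
        alpha0 = np.where(np.isfinite(alpha0), alpha0, 0.0)
        state = JointModelState(
            alpha=alpha0,
            log_delta=0.0,
            phi_str=np.zeros(n),
            phi_het=np.zeros(n),
            psi_str=np.zeros((2, n)),
            psi_het=np.zeros((2, n)),
            sigma={key: 0.5 for key in _SIGMA_KEYS},
        )
        state._mu = self._compute_mu(state)
        state._scales = {
            "phi_str": np.full(n, np.log(0.1)),
            "phi_het": np.full(n, np.log(0.1)),
            "psi1_str": np.full(n, np.log(0.1)),
            "psi1_het": np.full(n, np.log(0.1)),
            "psi2_str": np.full(n, np.log(0.1)),
            "psi2_het": np.full(n, np.log(0.1)),
            "alpha": np.log(0.05),
            "log_delta": np.log(0.05),
            "c_delta": np.log(0.1),
            **{f"c_{key}": np.log(0.2) for key in _SIGMA_KEYS},
        }
        state._t = 0
        return state

    def _compute_mu(self, state: JointModelState) -> np.ndarray:
        delta = state.delta
        log_mu = (
            self.logE
            + state.alpha[None, :]
            + np.column_stack([delta * state.phi, state.phi / delta])
            + state.psi.T
        )
        return np.exp(log_mu)

    # -- update schedule ---------------------------------------------- #
    def sweep(self, state: JointModelState, rng, adapting: bool) -> None:
        t = state._t
        delta = state.delta
        sc = state._scales
        mu, Y = state._mu, self.Y

        _mh_structured_field(
            state.phi_str, mu, Y, (delta, 1.0 / delta), state.sigma["phi_str"],
            self.graph, sc["phi_str"], rng, t, adapting, self.target,
        )
        _mh_het_field(
            state.phi_het, mu, Y, (delta, 1.0 / delta), state.sigma["phi_het"],
            sc["phi_het"], rng, t, adapting, self.target,
        )
        for k in range(2):
            coefs = (1.0, 0.0) if k == 0 else (0.0, 1.0)
            _mh_structured_field(
                state.psi_str[k], mu, Y, coefs, state.sigma[f"psi{k + 1}_str"],
                self.graph, sc[f"psi{k + 1}_str"], rng, t, adapting, self.target,
            )
            _mh_het_field(
                state.psi_het[k], mu, Y, coefs, state.sigma[f"psi{k + 1}_het"],
                sc[f"psi{k + 1}_het"], rng, t, adapting, self.target,
            )

        # collapsed (delta, sigma) block at fixed totals, then an exact
        # redraw of the six-way allocation given the totals
        self._collapsed_delta_sigma(state, rng, adapting)
        self._redraw_allocation(state, rng)

        self._recenter(state)
        self._update_alpha(state, rng, adapting)
        self._update_log_delta(state, rng, adapting)
        self._update_sigmas(state, rng)
        # refresh the mean cache once per sweep to stop numerical drift
        state._mu = self._compute_mu(state)
        state._t += 1

    # -- collapsed core ------------------------------------------------ #
    def _totals_eig(self, state: JointModelState) -> tuple[np.ndarray, np.ndarray]:
        delta = state.delta
        t1 = self.eig_vec.T @ (delta * state.phi + state.psi[0])
        t2 = self.eig_vec.T @ (state.phi / delta + state.psi[1])
        return t1, t2

    def _log_marginal_totals(
        self, t1: np.ndarray, t2: np.ndarray, log_delta: float, sigma: dict[str, float]
    ) -> float:
        """log p(T1, T2 | delta, sigma) with the allocation integrated out.

        Per Laplacian eigencoordinate the totals are bivariate normal with
        covariance [[d^2 s + s1, s], [s, s/d^2 + s2]] where s, s1, s2 are
        the shared/specific surface variances (g * sigma_str^2 +
        sigma_het^2) at that coordinate.
        """
        d2 = float(np.exp(2.0 * log_delta))
        g = self.eig_g
        s = sigma["phi_str"] ** 2 * g + sigma["phi_het"] ** 2
        a = d2 * s + sigma["psi1_str"] ** 2 * g + sigma["psi1_het"] ** 2
        b = s / d2 + sigma["psi2_str"] ** 2 * g + sigma["psi2_het"] ** 2
        det = a * b - s * s
        quad = (b * t1 * t1 - 2.0 * s * t1 * t2 + a * t2 * t2) / det
        return -0.5 * float(np.sum(np.log(det) + quad))

    def _collapsed_delta_sigma(self, state, rng, adapting: bool) -> None:
        """Metropolis on delta and each scale against the collapsed marginal.

        The totals are held fixed (so the likelihood never enters) and the
        allocation is integrated out analytically; the subsequent exact
        allocation redraw completes a valid partially collapsed Gibbs
        block.  This is what lets delta, the scales and hence eta traverse
        their posteriors: conditioned on any particular allocation they
        are all nearly pinned.
        """
        t1, t2 = self._totals_eig(state)
        current = self._log_marginal_totals(t1, t2, state.log_delta, state.sigma)

        for _ in range(8):  # cheap scalar scans; the totals stay fixed
            # delta
            step = float(np.exp(state._scales["c_delta"]) * rng.standard_normal())
            ld_new = state.log_delta + step
            prop = self._log_marginal_totals(t1, t2, ld_new, state.sigma)
            log_r = (
                prop
                - current
                - (ld_new**2 - state.log_delta**2)
                / (2.0 * self.priors.log_delta_sd**2)
            )
            acc = float(np.exp(min(log_r, 0.0)))
            if np.log(rng.uniform()) < log_r:
                state.log_delta = ld_new
                current = prop
            if adapting:
                state._scales["c_delta"] = adapt_log_scale(
                    state._scales["c_delta"], acc, state._t, self.target
                )

            # scales, one at a time (uniform prior enforced by rejection;
            # the log-scale random walk needs the +log sigma Jacobian)
            for key in _SIGMA_KEYS:
                step = float(
                    np.exp(state._scales[f"c_{key}"]) * rng.standard_normal()
                )
                sig_new = state.sigma[key] * np.exp(step)
                acc = 0.0
                if sig_new < self.priors.sigma_upper:
                    cand = dict(state.sigma)
                    cand[key] = sig_new
                    prop = self._log_marginal_totals(t1, t2, state.log_delta, cand)
                    log_r = prop - current + step
                    acc = float(np.exp(min(log_r, 0.0)))
                    if np.log(rng.uniform()) < log_r:
                        state.sigma = cand
                        current = prop
                if adapting:
                    state._scales[f"c_{key}"] = adapt_log_scale(
                        state._scales[f"c_{key}"], acc, state._t, self.target
                    )

    def _redraw_allocation(self, state: JointModelState, rng) -> None:
        """Exact draw of the six fields from their conditional given totals.

        Kriging-residual construction per eigencoordinate: draw an
        unconstrained prior sample z, then correct it to satisfy the two
        total constraints, which yields an exact draw from the Gaussian
        conditional.  The structured parts keep zero coefficients in the
        Laplacian null space (the per-component sum-to-zero constraint).
        """
        t1, t2 = self._totals_eig(state)
        delta = state.delta
        g, V = self.eig_g, self.eig_vec
        sig = state.sigma
        var = {
            "phi_str": sig["phi_str"] ** 2 * g,
            "phi_het": np.full(self.n, sig["phi_het"] ** 2),
            "psi1_str": sig["psi1_str"] ** 2 * g,
            "psi1_het": np.full(self.n, sig["psi1_het"] ** 2),
            "psi2_str": sig["psi2_str"] ** 2 * g,
            "psi2_het": np.full(self.n, sig["psi2_het"] ** 2),
        }
        z = {k: np.sqrt(v) * rng.standard_normal(self.n) for k, v in var.items()}
        # residuals of the two constraints at the prior sample
        r1 = t1 - (delta * (z["phi_str"] + z["phi_het"]) + z["psi1_str"] + z["psi1_het"])
        r2 = t2 - ((z["phi_str"] + z["phi_het"]) / delta + z["psi2_str"] + z["psi2_het"])
        s = var["phi_str"] + var["phi_het"]
        a = delta**2 * s + var["psi1_str"] + var["psi1_het"]
        b = s / delta**2 + var["psi2_str"] + var["psi2_het"]
        det = a * b - s * s
        w1 = (b * r1 - s * r2) / det
        w2 = (a * r2 - s * r1) / det
        shared_w = delta * w1 + w2 / delta
        x = {
            "phi_str": z["phi_str"] + var["phi_str"] * shared_w,
            "phi_het": z["phi_het"] + var["phi_het"] * shared_w,
            "psi1_str": z["psi1_str"] + var["psi1_str"] * w1,
            "psi1_het": z["psi1_het"] + var["psi1_het"] * w1,
            "psi2_str": z["psi2_str"] + var["psi2_str"] * w2,
            "psi2_het": z["psi2_het"] + var["psi2_het"] * w2,
        }
        state.phi_str = V @ x["phi_str"]
        state.phi_het = V @ x["phi_het"]
        state.psi_str = np.stack([V @ x["psi1_str"], V @ x["psi2_str"]])
        state.psi_het = np.stack([V @ x["psi1_het"], V @ x["psi2_het"]])

    # -- remaining blocks ---------------------------------------------- #
    def _recenter(self, state: JointModelState) -> None:
        """Sum-to-zero gauge on the structured fields, absorbed into alpha.

        The allocation redraw already leaves the structured parts centred
        per component; this keeps them centred after the site-wise
        Metropolis updates as well (exact for the global mean; identical
        to the per-component constraint on a connected graph).
        """
        delta = state.delta
        m = state.phi_str.mean()
        state.phi_str -= m
        state.alpha[0] += delta * m
        state.alpha[1] += m / delta
        for k in range(2):
            m = state.psi_str[k].mean()
            state.psi_str[k] -= m
            state.alpha[k] += m

    def _update_alpha(self, state, rng, adapting: bool) -> None:
        d = np.exp(state._scales["alpha"]) * rng.standard_normal(2)
        mu = state._mu
        log_r = sum(
            float(np.sum(_poisson_delta_loglik(self.Y[:, k], mu[:, k], d[k])))
            for k in range(2)
        )
        acc = float(np.exp(min(log_r, 0.0)))
        if np.log(rng.uniform()) < log_r:
            state.alpha += d
            mu *= np.exp(d)[None, :]
        if adapting:
            state._scales["alpha"] = adapt_log_scale(
                state._scales["alpha"], acc, state._t, self.target
            )

    def _update_log_delta(self, state, rng, adapting: bool) -> None:
        """Likelihood-coupled delta step (fields held fixed)."""
        d = np.exp(state._scales["log_delta"]) * rng.standard_normal()
        ld_new = state.log_delta + d
        delta, delta_new = state.delta, float(np.exp(ld_new))
        phi = state.phi
        shift1 = (delta_new - delta) * phi
        shift2 = (1.0 / delta_new - 1.0 / delta) * phi
        mu = state._mu
        log_r = (
            float(np.sum(_poisson_delta_loglik(self.Y[:, 0], mu[:, 0], shift1)))
            + float(np.sum(_poisson_delta_loglik(self.Y[:, 1], mu[:, 1], shift2)))
            - (ld_new**2 - state.log_delta**2) / (2.0 * self.priors.log_delta_sd**2)
        )
        acc = float(np.exp(min(log_r, 0.0)))
        if np.log(rng.uniform()) < log_r:
            state.log_delta = ld_new
            mu[:, 0] *= np.exp(shift1)
            mu[:, 1] *= np.exp(shift2)
        if adapting:
            state._scales["log_delta"] = adapt_log_scale(
                state._scales["log_delta"], acc, state._t, self.target
            )

    def _update_sigmas(self, state, rng) -> None:
        """Conditional (given the fields) exact scale draws."""
        u, v = self.graph.edges[:, 0], self.graph.edges[:, 1]
        fields = {
            "phi_str": (state.phi_str, True),
            "phi_het": (state.phi_het, False),
            "psi1_str": (state.psi_str[0], True),
            "psi1_het": (state.psi_het[0], False),
            "psi2_str": (state.psi_str[1], True),
            "psi2_het": (state.psi_het[1], False),
        }
        for key, (f, structured) in fields.items():
            if structured:
                sum_sq = float(np.sum((f[u] - f[v]) ** 2))
                rank = self.rank
            else:
                sum_sq = float(np.sum(f**2))
                rank = self.n
            state.sigma[key] = _gibbs_sigma(
                state.sigma[key], sum_sq, rank, self.priors.sigma_upper, rng
            )

    # -- outputs ------------------------------------------------------ #
    def tracked(self, state: JointModelState):
        eta1, eta2 = shared_variance_fractions(state)
        out = {
            "alpha1": state.alpha[0],
            "alpha2": state.alpha[1],
            "delta": state.delta,
            "eta1": eta1,
            "eta2": eta2,
        }
        for key in _SIGMA_KEYS:
            out[f"sigma_{key}"] = state.sigma[key]
        if self.track_field:
            out["shared"] = state.phi
        return out

    def log_posterior(self, state: JointModelState) -> float:
        for key in _SIGMA_KEYS:
            if not 0.0 < state.sigma[key] < self.priors.sigma_upper:
                return float("-inf")
        lp = joint_log_likelihood(state, self.data)
        lp += icar_logkernel(state.phi_str, self.graph, state.sigma["phi_str"])
        lp += -0.5 * float(
            np.sum(state.phi_het**2)
        ) / state.sigma["phi_het"] ** 2 - self.n * np.log(state.sigma["phi_het"])
        for k in range(2):
            lp += icar_logkernel(
                state.psi_str[k], self.graph, state.sigma[f"psi{k + 1}_str"]
            )
            s = state.sigma[f"psi{k + 1}_het"]
            lp += -0.5 * float(np.sum(state.psi_het[k] ** 2)) / s**2 - self.n * np.log(s)
        lp += -0.5 * state.log_delta**2 / self.priors.log_delta_sd**2
        return lp


# --------------------------------------------------------------------- #
# estimator
# --------------------------------------------------------------------- #
class SharedComponentModel(BaseEstimator):
    """Bayesian shared-component joint model, fitted by MCMC.

    Parameters mirror :class:`~sharedrisk.mcmc.McmcConfig` and
    :class:`~sharedrisk.mcmc.PriorConfig`.  After :meth:`fit`:

    Attributes
    ----------
    draws_ : dict of arrays
        Retained draws, keyed by parameter name, shape (chains, kept[, n]).
    summary_ : DataFrame
        Mean, SD, 95% CrI, R-hat and ESS for every tracked scalar.
    delta_, eta_, alpha_ : point estimates (posterior means)
    shared_surface_ : DataFrame
        Per-area posterior mean and 95% CrI of the shared field (log
        relative-risk scale, centred within each graph component).
    rhat_max_ : float
    converged_ : bool
        True when every tracked scalar has R-hat < 1.1; a failed check
        emits a ConvergenceWarning rather than raising.
    """

    def __init__(
        self,
        n_iter: int = 6000,
        burn_in: int = 1000,
        thin: int = 5,
        n_chains: int = 4,
        adapt_until: int | None = None,
        target_accept: float = 0.44,
        sigma_upper: float = 2.0,
        log_delta_sd: float = 0.3,
        random_state: int = 0,
        track_fields: bool = True,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.adapt_until = adapt_until
        self.target_accept = target_accept
        self.sigma_upper = sigma_upper
        self.log_delta_sd = log_delta_sd
        self.random_state = random_state
        self.track_fields = track_fields

    def _configs(self) -> tuple[McmcConfig, PriorConfig]:
        mcmc = McmcConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            n_chains=self.n_chains,
            seed=self.random_state,
            adapt_until=self.adapt_until,
            target_accept=self.target_accept,
        )
        priors = PriorConfig(
            sigma_upper=self.sigma_upper, log_delta_sd=self.log_delta_sd
        )
        return mcmc, priors

    def fit(self, data: AreaDataset, graph: AreaGraph) -> "SharedComponentModel":
        if data.area_ids != graph.area_ids:
            raise ValueError("dataset and graph must share the same ordered area ids")
        mcmc, priors = self._configs()
        model = _JointGibbs(
            data, graph, priors, mcmc.target_accept, track_field=self.track_fields
        )
        draws = run_chains(model, mcmc)
        scalars = ["alpha1", "alpha2", "delta", "eta1", "eta2"] + [
            f"sigma_{key}" for key in _SIGMA_KEYS
        ]
        self.draws_ = draws
        self.summary_ = summarize(draws, scalars)
        self.alpha_ = (
            float(self.summary_.loc["alpha1", "mean"]),
            float(self.summary_.loc["alpha2", "mean"]),
        )
        self.delta_ = float(self.summary_.loc["delta", "mean"])
        self.eta_ = (
            float(self.summary_.loc["eta1", "mean"]),
            float(self.summary_.loc["eta2", "mean"]),
        )
        if self.track_fields:
            self.shared_surface_ = self._shared_surface(draws["shared"], graph, data)
        self.rhat_max_ = float(np.nanmax(self.summary_["rhat"]))
        self.converged_ = bool(self.rhat_max_ < 1.1) if np.isfinite(
            self.rhat_max_
        ) else False
        if not self.converged_:
            warnings.warn(
                f"joint model may not have converged: max R-hat = {self.rhat_max_:.3f}",
                ConvergenceWarning,
                stacklevel=2,
            )
        return self

    @staticmethod
    def _shared_surface(
        shared_draws: np.ndarray, graph: AreaGraph, data: AreaDataset
    ) -> pd.DataFrame:
        flat = shared_draws.reshape(-1, shared_draws.shape[-1]).copy()
        for comp in graph.components:  # centre per component for display
            flat[:, comp] -= flat[:, comp].mean(axis=1, keepdims=True)
        return pd.DataFrame(
            {
                "area_id": data.area_ids,
                "shared_mean": flat.mean(axis=0),
                "shared_q2.5": np.percentile(flat, 2.5, axis=0),
                "shared_q97.5": np.percentile(flat, 97.5, axis=0),
            }
        )


def fit_joint(
    data: AreaDataset,
    graph: AreaGraph,
    mcmc: McmcConfig | None = None,
    priors: PriorConfig | None = None,
) -> SharedComponentModel:
    """Fit the shared-component joint model; returns the fitted estimator."""
    mcmc = mcmc or McmcConfig()
    priors = priors or PriorConfig()
    est = SharedComponentModel(
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        n_chains=mcmc.n_chains,
        adapt_until=mcmc.adapt_until,
        target_accept=mcmc.target_accept,
        sigma_upper=priors.sigma_upper,
        log_delta_sd=priors.log_delta_sd,
        random_state=mcmc.seed,
    )
    return est.fit(data, graph)


def export_shared_surface(
    posterior: SharedComponentModel, area_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-area shared-surface records, ordered by area id.

    When ``area_table`` (any DataFrame with an ``area_id`` column) is given
    its extra columns are merged in by id, so the output is invariant to
    the table's row order.
    """
    surface = posterior.shared_surface_
    if area_table is not None:
        extra = area_table.copy()
        extra["area_id"] = extra["area_id"].astype(str)
        missing = set(surface["area_id"]).symmetric_difference(extra["area_id"])
        if missing:
            raise ValueError(f"area table ids do not match the fit: {sorted(missing)}")
        surface = surface.merge(extra, on="area_id", how="left")
    return surface.sort_values("area_id", kind="stable").reset_index(drop=True)
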