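"""Shared MCMC machinery: CAR densities, Metropolis-within-Gibbs, diagnostics.

The two model modules (shared-component joint model, BYM regression) are
both Poisson hierarchical models whose latent fields carry intrinsic CAR
(ICAR) or iid Gaussian priors.  This module holds everything they share:

* the ICAR log-kernel and its single-site full conditional (the textbook
  ``N(mean of neighbours, sigma^2 / n_i)`` form),
* a generic multi-chain runner for models exposing per-sweep block updates,
  with deterministic per-chain seeding and proposal adaptation restricted
  to an initial adaptation window,
* split-R-hat, a simple autocorrelation-based effective sample size, and
  posterior summary tables (mean, SD, equal-tailed 95% interval, R-hat).

Proposal scales adapt by a Robbins-Monro recursion on the log scale toward
a target acceptance rate and are frozen after ``adapt_until`` iterations
(never later than burn-in), so retained draws come from a fixed kernel.
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .graph import AreaGraph

__all__ = [
    "McmcConfig",
    "PriorConfig",
    "McmcInitializationError",
    "icar_logkernel",
    "icar_full_conditional",
    "gibbs_icar_sample",
    "MetropolisModel",
    "run_chains",
    "rhat",
    "effective_sample_size",
    "summarize",
]

#: Canonical acceptance-rate target for scalar / single-site random walks.
DEFAULT_TARGET_ACCEPT = 0.44


class McmcInitializationError(RuntimeError):
    """The log-posterior is not finite at the initial state."""


@dataclass
class McmcConfig:
    """Chain-length and adaptation settings.

    The defaults are a desk-scale configuration (4 chains x 6,000
    iterations, 1,000 burn-in, thin 5) suitable for the bundled synthetic
    scenarios; production-scale runs in the style of classic WinBUGS
    analyses (one run of 100,000 iterations with 10,000 burn-in) are
    available by configuration.
    """

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    n_chains: int = 4
    seed: int = 0
    adapt_until: int | None = None
    target_accept: float = DEFAULT_TARGET_ACCEPT

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.adapt_until is None:
            self.adapt_until = self.burn_in
        if self.adapt_until > self.burn_in:
            raise ValueError("adaptation must stop at or before burn-in")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PriorConfig:
    """Prior and hyperprior settings.

    ``beta_variance`` is the variance of the vague zero-mean Gaussian prior
    on regression coefficients; ``sigma_upper`` the upper bound of the
    U(0, sigma_upper) hyperprior on every field scale; ``log_delta_sd`` the
    SD of the Normal(0, .) prior on the log of the shared-component scaling
    factor (weak shrinkage of delta toward 1).  Intercepts carry improper
    flat priors; posterior propriety comes from the Poisson likelihood with
    positive expected counts.
    """

    beta_variance: float = 1e5
    sigma_upper: float = 2.0
    log_delta_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("beta_variance", "sigma_upper", "log_delta_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# --------------------------------------------------------------------- #
# ICAR density
# --------------------------------------------------------------------- #
def icar_logkernel(field: np.ndarray, graph: AreaGraph, sigma: float) -> float:
    """Log-kernel of the intrinsic CAR field (up to an additive constant).

    ``-(1 / (2 sigma^2)) * sum_{i~j} (f_i - f_j)^2 - (n - C) log sigma``
    where the sum runs over unordered neighbour pairs and ``n - C`` is the
    rank of the graph Laplacian (C connected components).  Translation
    invariant: adding a constant per component leaves the value unchanged.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    f = np.asarray(field, dtype=float)
    if f.shape != (graph.n_areas,):
        raise ValueError("field length must equal the number of areas")
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    ss = float(np.sum((f[u] - f[v]) ** 2))
    rank = graph.n_areas - len(graph.components)
    return -ss / (2.0 * sigma**2) - rank * np.log(sigma)


def icar_full_conditional(
    field: np.ndarray, i: int, graph: AreaGraph, sigma: float
) -> tuple[float, float]:
    """Mean and variance of ``field[i]`` given the rest under the ICAR prior.

    Mean is the average of the neighbours' values, variance ``sigma^2 / n_i``.
    """
    nbrs = graph.neighbors[i]
    mean = float(np.mean(np.asarray(field, dtype=float)[nbrs]))
    return mean, float(sigma**2) / len(nbrs)


def gibbs_icar_sample(
    graph: AreaGraph,
    sigma: float,
    n_draws: int,
    seed,
    thin: int = 5,
    burn_in: int = 500,
) -> np.ndarray:
    """Sample the sum-to-zero ICAR field by single-site Gibbs sweeps.

    Each sweep draws every site from its full conditional (grouped by graph
    colour, which is exact Gibbs since same-colour sites are conditionally
    independent) and then recentres the field within each component.  This
    sampler exists as the conditional-distribution route for cross-checking
    the direct (Cholesky) sampler; it is not used for model fitting.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = graph.n_areas
    W = graph.adjacency_matrix
    n_i = graph.n_neighbors.astype(float)
    field = np.zeros(n)
    out = np.empty((n_draws, n))
    kept = 0
    total = burn_in + n_draws * thin
    for it in range(total):
        for color in graph.coloring:
            means = (W[color] @ field) / n_i[color]
            field[color] = means + (sigma / np.sqrt(n_i[color])) * rng.standard_normal(
                len(color)
            )
        for comp in graph.components:
            field[comp] -= field[comp].mean()
        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept] = field
            kept += 1
    return out


# --------------------------------------------------------------------- #
# adaptation helper
# --------------------------------------------------------------------- #
def adapt_log_scale(
    log_scale: np.ndarray | float,
    accept_prob: np.ndarray | float,
    t: int,
    target: float = DEFAULT_TARGET_ACCEPT,
):
    """One Robbins-Monro step on a log proposal scale.

    The step size decays as ``t**-0.6`` so adaptation is diminishing; callers
    must stop invoking this after the adaptation window.
    """
    gamma = min(0.25, float(t + 1) ** -0.6)
    return log_scale + gamma * (accept_prob - target)


# --------------------------------------------------------------------- #
# vectorised single-site Metropolis updates for latent fields
# --------------------------------------------------------------------- #
def _poisson_delta_loglik(Y, mu, shift):
    """Change in Poisson log-likelihood when log-mean shifts by ``shift``."""
    return Y * shift - mu * np.expm1(shift)


def _mh_structured_field(
    field: np.ndarray,
    mu: np.ndarray,
    Y: np.ndarray,
    coefs,
    sigma: float,
    graph: AreaGraph,
    log_scales: np.ndarray,
    rng: np.random.Generator,
    t: int,
    adapting: bool,
    target: float,
) -> None:
    """Single-site random-walk Metropolis sweep over an ICAR field.

    Sites are updated one graph colour at a time; same-colour sites share
    no edge, so their single-site updates are mutually independent and can
    be vectorised.  ``coefs[k]`` is the multiplier of this field in the
    outcome-k log mean (0 excludes that outcome); ``mu`` is the cached
    (n, K) mean matrix and is kept in sync in place.
    """
    n_i = graph.n_neighbors.astype(float)
    W = graph.adjacency_matrix
    for color in graph.coloring:
        d = np.exp(log_scales[color]) * rng.standard_normal(len(color))
        f = field[color]
        s_nbr = W[color] @ field
        dlp = -(n_i[color] * ((f + d) ** 2 - f**2) - 2.0 * s_nbr * d) / (
            2.0 * sigma**2
        )
        dll = np.zeros(len(color))
        for k, c in enumerate(coefs):
            if c != 0.0:
                dll += _poisson_delta_loglik(Y[color, k], mu[color, k], c * d)
        log_r = dll + dlp
        accept = np.log(rng.uniform(size=len(color))) < log_r
        idx = color[accept]
        field[idx] += d[accept]
        for k, c in enumerate(coefs):
            if c != 0.0:
                mu[idx, k] *= np.exp(c * d[accept])
        if adapting:
            log_scales[color] = adapt_log_scale(
                log_scales[color], np.exp(np.minimum(log_r, 0.0)), t, target
            )


def _mh_het_field(
    field: np.ndarray,
    mu: np.ndarray,
    Y: np.ndarray,
    coefs,
    sigma: float,
    log_scales: np.ndarray,
    rng: np.random.Generator,
    t: int,
    adapting: bool,
    target: float,
) -> None:
    """Vectorised Metropolis sweep over an iid-Gaussian (heterogeneity) field.

    With an iid prior and a site-local likelihood all sites are
    conditionally independent, so one simultaneous proposal per site is a
    valid parallel single-site update.
    """
    n = field.shape[0]
    d = np.exp(log_scales) * rng.standard_normal(n)
    dlp = -((field + d) ** 2 - field**2) / (2.0 * sigma**2)
    dll = np.zeros(n)
    for k, c in enumerate(coefs):
        if c != 0.0:
            dll += _poisson_delta_loglik(Y[:, k], mu[:, k], c * d)
    log_r = dll + dlp
    accept = np.log(rng.uniform(size=n)) < log_r
    field[accept] += d[accept]
    for k, c in enumerate(coefs):
        if c != 0.0:
            mu[accept, k] *= np.exp(c * d[accept])
    if adapting:
        log_scales[:] = adapt_log_scale(
            log_scales, np.exp(np.minimum(log_r, 0.0)), t, target
        )


def _gibbs_sigma(
    current: float,
    sum_sq: float,
    rank: int,
    upper: float,
    rng: np.random.Generator,
) -> float:
    """Exact draw of a field scale from its full conditional.

    The conditional of sigma given a field with quadratic form ``sum_sq``
    and precision rank ``rank`` under the U(0, upper) hyperprior is, in the
    precision ``tau = sigma^-2``, a Gamma((rank - 1)/2, rate sum_sq/2)
    truncated to ``tau > upper^-2``; sampled by inverse-CDF.  Returns the
    current value unchanged in the degenerate all-zero-field case (the
    conditional is then improper at 0).
    """
    from scipy import stats

    if sum_sq <= 0.0 or rank < 2:
        return current
    shape = 0.5 * (rank - 1)
    scale = 2.0 / sum_sq
    lo = stats.gamma.cdf(upper**-2, shape, scale=scale)
    u = rng.uniform(lo, 1.0)
    tau = stats.gamma.ppf(u, shape, scale=scale)
    if not np.isfinite(tau) or tau <= 0:
        return current
    return float(min(tau**-0.5, np.nextafter(upper, 0.0)))


# --------------------------------------------------------------------- #
# generic chain runner
# --------------------------------------------------------------------- #
class MetropolisModel(abc.ABC):
    """A posterior exposed as per-sweep Metropolis-within-Gibbs updates.

    Subclasses implement the three hooks below; :func:`run_chains` supplies
    seeding, burn-in/thinning bookkeeping and adaptation gating.
    """

    @abc.abstractmethod
    def init_state(self, rng: np.random.Generator) -> Any:
        """Deterministic-or-seeded initial state for one chain."""

    @abc.abstractmethod
    def sweep(self, state: Any, rng: np.random.Generator, adapting: bool) -> None:
        """One full update sweep over all parameter blocks (in place)."""

    @abc.abstractmethod
    def tracked(self, state: Any) -> Mapping[str, float | np.ndarray]:
        """Scalars/vectors to record for a retained draw."""

    def log_posterior(self, state: Any) -> float:
        """Joint log-posterior (up to a constant); used for init checks."""
        return 0.0


def run_chains(model: MetropolisModel, config: McmcConfig) -> dict[str, np.ndarray]:
    """Run independent chains and collect retained draws.

    Returns a mapping from tracked-quantity name to an array of shape
    ``(n_chains, n_kept)`` for scalars or ``(n_chains, n_kept, dim)`` for
    vectors.  Per-chain RNGs are spawned deterministically from
    ``config.seed``; identical configs give bit-identical draws.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    draws: dict[str, list] = {}
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        state = model.init_state(rng)
        lp = model.log_posterior(state)
        if not np.isfinite(lp):
            raise McmcInitializationError(
                f"log-posterior not finite at initialization (chain {c}): {lp}"
            )
        chain_draws: dict[str, list] = {}
        for it in range(config.n_iter):
            model.sweep(state, rng, adapting=it < config.adapt_until)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                for name, value in model.tracked(state).items():
                    chain_draws.setdefault(name, []).append(np.copy(value))
        for name, values in chain_draws.items():
            draws.setdefault(name, []).append(np.asarray(values))
    return {name: np.stack(chains) for name, chains in draws.items()}


# --------------------------------------------------------------------- #
# diagnostics and summaries
# --------------------------------------------------------------------- #
def rhat(chains: np.ndarray) -> float:
    """Split-R-hat potential-scale-reduction for one scalar.

    ``chains`` has shape (n_chains, n_draws) with n_chains >= 2 and
    n_draws >= 4; each chain is split in half before computing the
    between/within variance ratio.  Returns NaN (with a warning) when the
    pooled variance is zero, where the diagnostic is undefined.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("rhat needs >= 2 chains with >= 4 draws each")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    within = splits.var(axis=1, ddof=1).mean()
    between = n * chain_means.var(ddof=1)
    if within <= 0 and between <= 0:
        warnings.warn("rhat undefined: zero variance in all chains", stacklevel=2)
        return float("nan")
    if within <= 0:
        return float("inf")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based ESS (Geyer initial-positive-sequence truncation)."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float(m * n)
    centred = x - x.mean(axis=1, keepdims=True)
    if np.allclose(centred, 0):
        return float("nan")
    # FFT autocovariance per chain, averaged
    size = 2 * n
    f = np.fft.rfft(centred, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    rho = acov.mean(axis=0)
    if rho[0] <= 0:
        return float("nan")
    rho = rho / rho[0]
    # sum consecutive pairs until a pair sum goes non-positive
    tau = 1.0
    for lag in range(1, n - 1, 2):
        pair = rho[lag] + rho[lag + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(m * n / tau)


def summarize(
    draws: Mapping[str, np.ndarray], names: list[str] | None = None
) -> pd.DataFrame:
    """Posterior summary table: mean, SD, equal-tailed 95% CrI, R-hat, ESS.

    ``draws`` maps parameter names to arrays of shape (n_chains, n_draws)
    or (n_chains, n_draws, dim); vector parameters are expanded to rows
    named ``name[j]``.  R-hat is reported only when >= 2 chains with >= 4
    draws are available.
    """
    rows = []
    for name in names if names is not None else list(draws):
        arr = np.asarray(draws[name], dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
            labels = [name]
        else:
            labels = [f"{name}[{j}]" for j in range(arr.shape[2])]
        for j, label in enumerate(labels):
            x = arr[:, :, j]
            flat = x.ravel()
            can_rhat = x.shape[0] >= 2 and x.shape[1] >= 4
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = rhat(x) if can_rhat else float("nan")
            rows.append(
                {
                    "parameter": label,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                    "q2.5": float(np.percentile(flat, 2.5)),
                    "q97.5": float(np.percentile(flat, 97.5)),
                    "rhat": r,
                    "ess": effective_sample_size(x),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")
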