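"""Hierarchical Bayes multinomial logit estimation of part-worth utilities.

Respondent-level coefficients beta_i follow a population normal
distribution N(mu, Sigma).  The sampler is a Gibbs scheme with conjugate
updates for mu (normal) and Sigma (inverse-Wishart) and a random-walk
Metropolis step for each respondent's beta_i against the MNL likelihood,
with per-respondent proposal scales adapted toward a target acceptance
rate during burn-in only (so the kept chain is a valid Markov chain).

Priors are weakly informative conjugate defaults: mu ~ N(0, prior_mean_var
x I) and Sigma ~ InvWishart(p + prior_df_extra, prior_scale x I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .attributes import ConfigurationError
from .mnl import ChoiceArrays, per_obs_loglik


@dataclass(frozen=True)
class HBConfig:
    """Sampler settings.  Defaults are desk-scale and conventional."""

    n_burn: int = 10_000
    n_draws: int = 10_000
    thin: int = 10
    target_accept: float = 0.3
    prior_mean_var: float = 100.0
    prior_df_extra: int = 5
    prior_scale: float = 1.0
    initial_step: float = 0.2
    adapt_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_burn, self.n_draws, self.thin, self.adapt_interval) < 1:
            raise ConfigurationError("chain length settings must be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ConfigurationError("target_accept must lie in (0, 1)")
        if min(self.prior_mean_var, self.prior_scale) <= 0 or self.prior_df_extra < 1:
            raise ConfigurationError("prior hyperparameters must be positive")


@dataclass
class PosteriorDraws:
    """Thinned posterior draws from the hierarchical sampler.

    ``mu`` has shape (n_kept, p); ``sigma`` (n_kept, p, p); ``beta``
    (n_kept, n_resp, p).  ``beta_mean`` is the posterior-mean respondent
    coefficient matrix used as the point estimate downstream.
    """

    mu: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    accept_rate: np.ndarray
    respondent_ids: np.ndarray

    @property
    def n_kept(self) -> int:
        return self.mu.shape[0]

    @property
    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    @property
    def mu_mean(self) -> np.ndarray:
        return self.mu.mean(axis=0)

    def split_rhat(self) -> np.ndarray:
        """Split-chain potential-scale-reduction diagnostic on mu, per coordinate."""
        m = self.mu
        half = m.shape[0] // 2
        chains = np.stack([m[:half], m[half : 2 * half]])  # (2, half, p)
        within = chains.var(axis=1, ddof=1).mean(axis=0)
        between = half * chains.mean(axis=1).var(axis=0, ddof=1)
        var_plus = (half - 1) / half * within + between / half
        with np.errstate(divide="ignore", invalid="ignore"):
            rhat = np.sqrt(var_plus / within)
        return np.where(within > 0, rhat, 1.0)


def fit_hb(arrays: ChoiceArrays, config: HBConfig = HBConfig()) -> PosteriorDraws:
    """Run the Gibbs / Metropolis sampler and return thinned kept draws.

    Deterministic for a fixed :attr:`HBConfig.seed`.
    """
    rng = np.random.default_rng(config.seed)
    n, p = arrays.n_resp, arrays.n_params
    if n < 1:
        raise ConfigurationError("no respondents with observed choices")

    # start at the aggregate MNL fit so burn-in spends its time on the
    # respondent-level spread rather than locating the population center
    from .mnl import fit_mnl

    agg = fit_mnl(arrays.X, arrays.chosen, ridge=1e-6)
    mu = agg.beta.copy()
    beta = np.tile(mu, (n, 1))
    sigma = np.eye(p)
    df0 = p + config.prior_df_extra
    scale0 = config.prior_scale * np.eye(p)
    prior_mean_prec = 1.0 / config.prior_mean_var

    log_step = np.full(n, np.log(config.initial_step))
    accept_count = np.zeros(n)
    window_count = np.zeros(n)

    def resp_loglik(B: np.ndarray) -> np.ndarray:
        ll = per_obs_loglik(arrays, B)
        if not np.all(np.isfinite(ll)):
            bad = arrays.respondent_ids[
                np.unique(arrays.resp[~np.isfinite(ll)])
            ]
            raise FloatingPointError(
                f"non-finite likelihood for respondent(s) {bad[:5].tolist()}"
            )
        return np.bincount(arrays.resp, weights=ll, minlength=n)

    cur_ll = resp_loglik(beta)
    n_iter = config.n_burn + config.n_draws
    kept_mu, kept_sigma, kept_beta = [], [], []

    for it in range(n_iter):
        # --- beta_i | mu, sigma: random-walk Metropolis, vectorized over i
        chol = np.linalg.cholesky(sigma)
        prop = beta + np.exp(log_step)[:, None] * (
            rng.standard_normal((n, p)) @ chol.T
        )
        prop_ll = resp_loglik(prop)
        sigma_inv = np.linalg.inv(sigma)
        d_cur = beta - mu
        d_prop = prop - mu
        cur_prior = -0.5 * np.einsum("ip,pq,iq->i", d_cur, sigma_inv, d_cur)
        prop_prior = -0.5 * np.einsum("ip,pq,iq->i", d_prop, sigma_inv, d_prop)
        log_ratio = (prop_ll + prop_prior) - (cur_ll + cur_prior)
        accept = np.log(rng.random(n)) < log_ratio
        beta[accept] = prop[accept]
        cur_ll[accept] = prop_ll[accept]
        accept_count += accept
        window_count += accept

        if it < config.n_burn and (it + 1) % config.adapt_interval == 0:
            rate = window_count / config.adapt_interval
            log_step += 0.5 * (rate - config.target_accept)
            np.clip(log_step, np.log(1e-3), np.log(5.0), out=log_step)
            window_count[:] = 0.0

        # --- mu | beta, sigma (conjugate normal)
        prec = n * sigma_inv + prior_mean_prec * np.eye(p)
        cov_mu = np.linalg.inv(prec)
        mean_mu = cov_mu @ (sigma_inv @ beta.sum(axis=0))
        mu = rng.multivariate_normal(mean_mu, cov_mu, method="cholesky")

        # --- sigma | beta, mu (conjugate inverse-Wishart)
        dev = beta - mu
        scale_post = scale0 + dev.T @ dev
        sigma = stats.invwishart.rvs(df=df0 + n, scale=scale_post, random_state=rng)
        sigma = np.atleast_2d(sigma)

        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0:
            kept_mu.append(mu.copy())
            kept_sigma.append(sigma.copy())
            kept_beta.append(beta.copy())

    return PosteriorDraws(
        mu=np.asarray(kept_mu),
        sigma=np.asarray(kept_sigma),
        beta=np.asarray(kept_beta),
        accept_rate=accept_count / n_iter,
        respondent_ids=arrays.respondent_ids,
    )
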