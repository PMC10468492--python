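"""Latent-class multinomial logit segmentation fitted by EM.

Respondents belong to one of K classes, each with its own MNL coefficient
vector; class membership is probabilistic with shares pi.  The E-step
computes posterior memberships from class shares times respondent-level
likelihoods; the M-step re-estimates shares and per-class coefficients by
membership-weighted Newton MNL maximization (an ECM step: a few Newton
iterations per M-step, which keeps the observed-data log-likelihood
non-decreasing).  Model selection across K uses the consistent Akaike
information criterion CAIC = -2 LL + p (ln N + 1) with N = respondents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .attributes import ConfigurationError
from .coding import CodingMap
from .mnl import ChoiceArrays, fit_mnl, per_obs_loglik


@dataclass
class SegmentModel:
    """A fitted latent-class MNL solution."""

    n_classes: int
    shares: np.ndarray  # (K,)
    coefficients: np.ndarray  # (K, p)
    memberships: np.ndarray  # (n_resp, K), rows sum to 1
    loglik: float
    n_params: int
    n_respondents: int
    converged: bool
    n_iter: int
    respondent_ids: np.ndarray = field(default_factory=lambda: np.empty(0))
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_respondents)

    @property
    def caic(self) -> float:
        return -2.0 * self.loglik + self.n_params * (np.log(self.n_respondents) + 1.0)


def caic(loglik: float, n_params: int, n: int) -> float:
    """Consistent AIC: -2 LL + p (ln N + 1)."""
    return -2.0 * loglik + n_params * (np.log(n) + 1.0)


def _class_logliks(arrays: ChoiceArrays, coefs: np.ndarray) -> np.ndarray:
    """Per-respondent log-likelihood under each class: (n_resp, K)."""
    K = coefs.shape[0]
    out = np.empty((arrays.n_resp, K))
    for k in range(K):
        ll = per_obs_loglik(arrays, coefs[k])
        out[:, k] = np.bincount(arrays.resp, weights=ll, minlength=arrays.n_resp)
    return out


def _observed_loglik(arrays: ChoiceArrays, shares: np.ndarray, coefs: np.ndarray) -> float:
    cl = _class_logliks(arrays, coefs)
    return float(logsumexp(cl + np.log(shares)[None, :], axis=1).sum())


def fit_latent_class(
    arrays: ChoiceArrays,
    K: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    newton_steps: int = 4,
) -> SegmentModel:
    """Fit a K-class latent-class MNL by EM, best of ``n_starts`` starts.

    Starts are perturbations of the aggregate (K=1) Newton fit; K=1 itself
    reduces exactly to that aggregate fit.  The observed-data
    log-likelihood is checked to be non-decreasing at every EM iteration.
    Deterministic given ``seed``.
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if arrays.n_obs == 0:
        raise ConfigurationError("dataset is empty")
    p = arrays.n_params
    agg = fit_mnl(arrays.X, arrays.chosen)
    if K == 1:
        cl = _class_logliks(arrays, agg.beta[None, :])
        return SegmentModel(
            n_classes=1,
            shares=np.ones(1),
            coefficients=agg.beta[None, :],
            memberships=np.ones((arrays.n_resp, 1)),
            loglik=float(cl.sum()),
            n_params=p,
            n_respondents=arrays.n_resp,
            converged=agg.converged,
            n_iter=agg.n_iter,
            respondent_ids=arrays.respondent_ids,
        )

    rng = np.random.default_rng(seed)
    best: SegmentModel | None = None
    for _start in range(n_starts):
        coefs = agg.beta[None, :] + rng.normal(0.0, 1.0, size=(K, p))
        shares = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        converged = False
        it = 0
        restarted = False
        trace = []
        for it in range(1, max_iter + 1):
            # E-step
            cl = _class_logliks(arrays, coefs)
            logpost = cl + np.log(shares)[None, :]
            ll = float(logsumexp(logpost, axis=1).sum())
            trace.append(ll)
            gamma = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
            if ll + 1e-8 * (abs(ll) + 1.0) < prev_ll:
                warnings.warn("EM log-likelihood decreased; stopping this start")
                break
            if abs(ll - prev_ll) < tol * (abs(ll) + 1.0):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
            # M-step
            shares = gamma.mean(axis=0)
            if shares.min() < 1e-6 and not restarted:
                # empty class: re-seed it from a random respondent's perturbation
                k_empty = int(shares.argmin())
                coefs[k_empty] = agg.beta + rng.normal(0.0, 1.5, size=p)
                shares = np.full(K, 1.0 / K)
                restarted = True
                warnings.warn("latent class emptied; re-seeded and restarted shares")
                continue
            shares = np.clip(shares, 1e-10, None)
            shares /= shares.sum()
            for k in range(K):
                w_obs = gamma[arrays.resp, k]
                fit = fit_mnl(
                    arrays.X,
                    arrays.chosen,
                    obs_weights=w_obs,
                    beta0=coefs[k],
                    max_iter=newton_steps,
                )
                coefs[k] = fit.beta
        cl = _class_logliks(arrays, coefs)
        logpost = cl + np.log(shares)[None, :]
        ll = float(logsumexp(logpost, axis=1).sum())
        gamma = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))
        model = SegmentModel(
            n_classes=K,
            shares=shares,
            coefficients=coefs,
            memberships=gamma,
            loglik=ll,
            n_params=K * p + (K - 1),
            n_respondents=arrays.n_resp,
            converged=converged,
            n_iter=it,
            respondent_ids=arrays.respondent_ids,
            ll_trace=np.asarray(trace),
        )
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    if not best.converged:
        warnings.warn("latent-class EM did not converge within the iteration cap")
    return best


def select_K(
    arrays: ChoiceArrays,
    K_range: range | list[int] = range(1, 8),
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[int, pd.DataFrame, dict[int, SegmentModel]]:
    """Fit each K and pick the CAIC-minimizing class count.

    Returns the best K, a criterion table (K, loglik, n_params, AIC, BIC,
    CAIC), and the fitted models.
    """
    Ks = list(K_range)
    if not Ks:
        raise ConfigurationError("K_range is empty")
    rows, models = [], {}
    for K in Ks:
        try:
            model = fit_latent_class(
                arrays, K, n_starts=n_starts, seed=seed + K, tol=tol, max_iter=max_iter
            )
        except Exception as exc:  # propagate per-K failure into the table
            warnings.warn(f"latent-class fit failed for K={K}: {exc}")
            rows.append(
                {"K": K, "loglik": np.nan, "n_params": np.nan, "AIC": np.nan,
                 "BIC": np.nan, "CAIC": np.nan}
            )
            continue
        models[K] = model
        rows.append(
            {
                "K": K,
                "loglik": model.loglik,
                "n_params": model.n_params,
                "AIC": model.aic,
                "BIC": model.bic,
                "CAIC": model.caic,
            }
        )
    table = pd.DataFrame(rows)
    if table["CAIC"].isna().all():
        raise ConfigurationError("all latent-class fits failed")
    best_K = int(table.loc[table["CAIC"].idxmin(), "K"])
    return best_K, table, models


def assign_segments(model: SegmentModel) -> pd.DataFrame:
    """Modal class label per respondent (ties broken by lowest class index).

    Returns a frame with ``respondent_id``, ``segment`` (0-based class
    index), and ``confidence`` (the membership probability of the modal
    class).
    """
    labels = model.memberships.argmax(axis=1)  # argmax takes the first max: lowest index wins ties
    conf = model.memberships[np.arange(len(labels)), labels]
    rid = (
        model.respondent_ids
        if len(model.respondent_ids)
        else np.arange(len(labels))
    )
    return pd.DataFrame(
        {"respondent_id": rid, "segment": labels, "confidence": conf}
    )
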