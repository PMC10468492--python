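"""Multinomial logit core: model-matrix assembly, likelihood, Newton fitting.

All estimation stages (design audit, hierarchical Bayes, latent class) share
this representation: an observation is one choice task with a fixed number of
alternatives (concepts plus, optionally, the opt-out), each encoded as an
effects-coded row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .attributes import ConfigurationError
from .coding import CodingMap
from .dataset import NONE_CHOICE, ChoiceDataset


class DataError(ValueError):
    """Raised for malformed choice records."""


@dataclass
class ChoiceArrays:
    """Stacked model matrices for all observed (answered) tasks.

    Attributes
    ----------
    X
        ``(n_obs, n_alternatives, n_params)`` effects-coded alternatives.
    chosen
        ``(n_obs,)`` chosen alternative index (None mapped to the last slot).
    resp
        ``(n_obs,)`` respondent index in ``0..n_resp-1``.
    respondent_ids
        Original ids, aligned with respondent indices.
    """

    X: np.ndarray
    chosen: np.ndarray
    resp: np.ndarray
    respondent_ids: np.ndarray
    n_resp: int

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_alternatives(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        return self.X.shape[2]

    def tasks_per_respondent(self) -> np.ndarray:
        return np.bincount(self.resp, minlength=self.n_resp)


def build_arrays(dataset: ChoiceDataset, coding: CodingMap) -> ChoiceArrays:
    """Encode a :class:`ChoiceDataset` into stacked MNL model matrices.

    Unanswered tasks (NaN ``chosen``) are dropped; respondents with no
    answered tasks are excluded with a warning.
    """
    if list(coding.space.names) != list(dataset.attr_names):
        raise ConfigurationError(
            "coding attribute order does not match dataset attribute order"
        )
    tasks = dataset.tasks
    answered = tasks["chosen"].notna().to_numpy()
    tasks = tasks.loc[answered]
    levels = dataset.concept_levels()[answered]  # (n_obs, C, A)
    n_obs, C, A = levels.shape
    for ai, attr in enumerate(coding.space):
        bad = (levels[:, :, ai] < 0) | (levels[:, :, ai] >= attr.n_levels)
        if bad.any():
            rows = tasks.index[bad.any(axis=1)].tolist()[:5]
            raise DataError(
                f"invalid level index for attribute {attr.name!r} in task rows {rows}"
            )

    n_alt = C + (1 if dataset.include_none else 0)
    X = np.zeros((n_obs, n_alt, coding.n_params))
    # vectorized effects coding: free level -> +1, reference level -> -1 block
    for ai, (attr, sl) in enumerate(zip(coding.space, coding.attr_slices())):
        lev = levels[:, :, ai]
        free = lev < attr.n_levels - 1
        obs_i, con_i = np.nonzero(free)
        X[obs_i, con_i, sl.start + lev[obs_i, con_i]] = 1.0
        obs_i, con_i = np.nonzero(~free)
        for k in range(sl.start, sl.stop):
            X[obs_i, con_i, k] = -1.0
    if dataset.include_none:
        X[:, -1, coding.none_col] = 1.0

    chosen = tasks["chosen"].to_numpy()
    chosen = np.where(chosen == NONE_CHOICE, n_alt - 1, chosen).astype(int)
    if (chosen < 0).any() or (chosen >= n_alt).any():
        raise DataError("chosen alternative index out of range")

    resp_ids = dataset.respondents["respondent_id"].to_numpy()
    id_to_idx = {rid: i for i, rid in enumerate(resp_ids)}
    resp = tasks["respondent_id"].map(id_to_idx).to_numpy()
    counts = np.bincount(resp, minlength=len(resp_ids))
    if (counts == 0).any():
        silent = resp_ids[counts == 0]
        warnings.warn(
            f"{len(silent)} respondent(s) have no answered tasks and are excluded "
            f"from estimation (e.g. {silent[:3].tolist()})",
            stacklevel=2,
        )
        keep = np.flatnonzero(counts > 0)
        remap = -np.ones(len(resp_ids), dtype=int)
        remap[keep] = np.arange(len(keep))
        resp = remap[resp]
        resp_ids = resp_ids[keep]

    return ChoiceArrays(
        X=X,
        chosen=chosen.astype(int),
        resp=resp.astype(int),
        respondent_ids=np.asarray(resp_ids),
        n_resp=len(resp_ids),
    )


# ---- likelihood ---------------------------------------------------------------


def choice_logprobs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Log choice probabilities per observation and alternative.

    ``beta`` may be a single vector or an ``(n_obs, n_params)`` matrix of
    per-observation coefficients.
    """
    if beta.ndim == 1:
        U = X @ beta
    else:
        U = np.einsum("oap,op->oa", X, beta)
    U = U - U.max(axis=1, keepdims=True)
    return U - np.log(np.exp(U).sum(axis=1, keepdims=True))

def per_obs_loglik(arrays: ChoiceArrays, beta: np.ndarray) -> np.ndarray:
    """Log-likelihood of each observed choice under coefficients ``beta``.

    ``beta`` may be one shared vector, or an ``(n_resp, n_params)`` matrix of
    respondent-level coefficients.
    """
    if beta.ndim == 2:
        beta = beta[arrays.resp]
    lp = choice_logprobs(arrays.X, beta)
    return lp[np.arange(arrays.n_obs), arrays.chosen]


def respondent_loglik(arrays: ChoiceArrays, beta: np.ndarray) -> np.ndarray:
    """Per-respondent log-likelihood under respondent-level coefficients."""
    ll = per_obs_loglik(arrays, beta)
    return np.bincount(arrays.resp, weights=ll, minlength=arrays.n_resp)


def brute_force_loglik(arrays: ChoiceArrays, beta: np.ndarray) -> float:
    """Independent slow oracle: enumerate each task's alternative utilities.

    Used in tests to validate the vectorized likelihood.
    """
    import math

    total = 0.0
    for o in range(arrays.n_obs):
        b = beta if beta.ndim == 1 else beta[arrays.resp[o]]
        utils = [float(np.dot(arrays.X[o, a], b)) for a in range(arrays.n_alternatives)]
        denom = sum(math.exp(u) for u in utils)
        total += math.log(math.exp(utils[arrays.chosen[o]]) / denom)
    return total


# ---- aggregate / weighted Newton fit ------------------------------------------


@dataclass
class MNLFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    singular: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_mnl(
    X: np.ndarray,
    chosen: np.ndarray,
    obs_weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> MNLFit:
    """Maximum-likelihood aggregate MNL fit by Newton-Raphson.

    ``obs_weights`` supports the latent-class M-step (fractional membership
    weights per observation).  ``ridge`` adds a small quadratic penalty used
    only to stabilize degenerate designs; the reported covariance is the
    inverse of the (penalized) observed information.
    """
    n_obs, n_alt, p = X.shape
    w = np.ones(n_obs) if obs_weights is None else np.asarray(obs_weights, float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    Xf = X.reshape(n_obs * n_alt, p)
    rows = np.arange(n_obs)
    x_chosen = X[rows, chosen]

    def negloglik(b: np.ndarray) -> float:
        lp = choice_logprobs(X, b)
        return -float(np.sum(w * lp[rows, chosen])) + 0.5 * ridge * float(b @ b)

    singular = False
    converged = False
    nll = negloglik(beta)
    it = 0
    for it in range(1, max_iter + 1):
        lp = choice_logprobs(X, beta)
        P = np.exp(lp)  # (n_obs, n_alt)
        xbar = np.einsum("oa,oap->op", P, X)
        grad = -(w[:, None] * (x_chosen - xbar)).sum(axis=0) + ridge * beta
        WP = (w[:, None] * P).reshape(n_obs * n_alt)
        H = Xf.T @ (WP[:, None] * Xf) - (np.sqrt(w)[:, None] * xbar).T @ (
            np.sqrt(w)[:, None] * xbar
        )
        H = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            singular = True
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve until improvement
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            cand_nll = negloglik(cand)
            if cand_nll <= nll + 1e-12:
                break
            scale *= 0.5
        if not np.isfinite(cand_nll):
            raise DataError("non-finite likelihood during MNL fit")
        improved = nll - cand_nll
        beta, nll = cand, cand_nll
        if improved < tol * (abs(nll) + 1.0):
            converged = True
            break

    # covariance from final information matrix
    lp = choice_logprobs(X, beta)
    P = np.exp(lp)
    xbar = np.einsum("oa,oap->op", P, X)
    WP = (w[:, None] * P).reshape(n_obs * n_alt)
    H = Xf.T @ (WP[:, None] * Xf) - (np.sqrt(w)[:, None] * xbar).T @ (
        np.sqrt(w)[:, None] * xbar
    )
    H = H + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.linalg.cond(H) > 1e10:
            singular = True
    except np.linalg.LinAlgError:
        singular = True
        cov = np.linalg.pinv(H)
    return MNLFit(
        beta=beta,
        cov=cov,
        loglik=-nll + 0.5 * ridge * float(beta @ beta),
        converged=converged,
        n_iter=it,
        singular=singular,
    )


def level_utility_covariance(cov: np.ndarray, coding: CodingMap) -> np.ndarray:
    """Covariance of all expanded level utilities (plus None) from the coded covariance."""
    p = coding.n_params
    total = coding.space.total_levels + (1 if coding.include_none else 0)
    T = np.zeros((total, p))
    pos = 0
    for attr, sl in zip(coding.space, coding.attr_slices()):
        for j in range(attr.n_levels - 1):
            T[pos + j, sl.start + j] = 1.0
        T[pos + attr.n_levels - 1, sl] = -1.0
        pos += attr.n_levels
    if coding.include_none:
        T[pos, coding.none_col] = 1.0
    return T @ cov @ T.T
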