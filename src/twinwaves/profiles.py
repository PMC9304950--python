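"""Longitudinal latent profile analysis (LPA).

Trajectory subgroups are modelled as a finite Gaussian mixture over the
repeated measures, with diagonal covariance (zero within-class covariances)
and per-wave variances equated across classes — the constrained mixture
conventionally used for longitudinal LPA.  Missing waves are completed once by
single imputation (a conditional draw from an EM-estimated multivariate
normal) before any mixture is fitted; model selection over the class count
uses BIC.

The EM implementation is self-contained: the equal-variances/zero-covariance
constraint is the model, not a library default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "impute_single",
    "fit_lpa",
    "select_k",
    "assign_profiles",
    "LatentProfileModel",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# single imputation
# ---------------------------------------------------------------------------

def _em_mvnorm(X: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """EM estimate of multivariate-normal mean/covariance under missingness."""
    n, w = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    sigma = np.diag(np.maximum(var, 1e-8))
    codes = obs @ (1 << np.arange(w, dtype=np.int64))
    groups = [(codes == c, obs[codes == c][0]) for c in np.unique(codes)]
    last = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(w)
        sum_xx = np.zeros((w, w))
        ll = 0.0
        for rows, mask in groups:
            Xg = X[rows]
            ng = Xg.shape[0]
            o = mask
            m = ~mask
            if not o.any():
                # all-missing rows carry no information
                filled = np.tile(mu, (ng, 1))
                sum_x += filled.sum(axis=0)
                sum_xx += ng * (sigma + np.outer(mu, mu))
                continue
            Soo = sigma[np.ix_(o, o)]
            L = np.linalg.cholesky(Soo)
            diff = Xg[:, o] - mu[o]
            z = np.linalg.solve(L, diff.T)
            ll += -0.5 * (ng * (o.sum() * np.log(2 * np.pi)
                                + 2 * np.log(np.diag(L)).sum())
                          + (z ** 2).sum())
            filled = np.empty((ng, w))
            filled[:, o] = Xg[:, o]
            cond_cov_full = np.zeros((w, w))
            if m.any():
                Smo = sigma[np.ix_(m, o)]
                B = np.linalg.solve(Soo, Smo.T).T  # regression coefs (m x o)
                filled[:, m] = mu[m] + diff @ B.T
                cond = sigma[np.ix_(m, m)] - B @ Smo.T
                cond_cov_full[np.ix_(m, m)] = cond
            sum_x += filled.sum(axis=0)
            sum_xx += filled.T @ filled + ng * cond_cov_full
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2 + 1e-10 * np.eye(w)
        if abs(ll - last) < tol * (1 + abs(ll)):
            break
        last = ll
    return mu, sigma


def impute_single(data, seed: int) -> np.ndarray:
    """Complete a waves matrix by one conditional multivariate-normal draw.

    The mean and covariance are EM maximum-likelihood estimates under the
    observed data; each row's missing cells are then drawn once from their
    conditional normal given the row's observed cells.  A complete matrix is
    returned unchanged; an all-missing row is rejected.
    """
    X = np.array(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be individuals x waves")
    obs = ~np.isnan(X)
    empty = np.where(~obs.any(axis=1))[0]
    if len(empty):
        raise ValueError(f"rows with no observed wave: {empty[:5].tolist()}")
    if obs.all():
        return X
    rng = np.random.default_rng(seed)
    mu, sigma = _em_mvnorm(X)
    out = X.copy()
    w = X.shape[1]
    codes = obs @ (1 << np.arange(w, dtype=np.int64))
    for c in np.unique(codes):
        rows = np.where(codes == c)[0]
        mask = obs[rows[0]]
        m = ~mask
        if not m.any():
            continue
        o = mask
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(m, o)]
        B = np.linalg.solve(Soo, Smo.T).T
        cond_mu = mu[m] + (X[np.ix_(rows, np.where(o)[0])] - mu[o]) @ B.T
        cond_cov = sigma[np.ix_(m, m)] - B @ Smo.T
        cond_cov = (cond_cov + cond_cov.T) / 2
        evals, evecs = np.linalg.eigh(cond_cov)
        root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
        draw = rng.standard_normal((len(rows), int(m.sum()))) @ root.T
        out[np.ix_(rows, np.where(m)[0])] = cond_mu + draw
    return out


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------

@dataclass
class LatentProfileModel:
    """Fitted Gaussian-mixture profile model (shared per-wave variances)."""

    k: int
    means: np.ndarray         # k x waves class mean trajectories
    variances: np.ndarray     # per-wave variances, shared across classes
    mixing: np.ndarray        # k mixing proportions
    log_likelihood: float
    bic: float
    aic: float
    entropy: float
    posterior: np.ndarray     # n x k
    n: int
    n_params: int
    converged: bool
    degenerate: bool = False


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
            n_iter: int = 25) -> np.ndarray:
    """Plain Lloyd's k-means; returns cluster labels (initializer only)."""
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)]
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        if (new == labels).all():
            break
        labels = new
        for j in range(k):
            pts = X[labels == j]
            if len(pts):
                centers[j] = pts.mean(axis=0)
    return labels


def _lpa_em(X: np.ndarray, k: int, resp0: np.ndarray, max_iter: int = 500,
            tol: float = 1e-8):
    n, w = X.shape
    resp = resp0
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # M-step
        nk = resp.sum(axis=0)
        if nk.min() < 1.0:  # degenerate class
            return None
        pi = nk / n
        means = (resp.T @ X) / nk[:, None]
        var = np.zeros(w)
        for j in range(k):
            var += resp[:, j] @ (X - means[j]) ** 2
        var = np.maximum(var / n, 1e-10)
        # E-step
        logp = np.empty((n, k))
        const = -0.5 * (np.log(2 * np.pi * var)).sum()
        for j in range(k):
            logp[:, j] = (np.log(pi[j]) + const
                          - 0.5 * (((X - means[j]) ** 2) / var).sum(axis=1))
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        if ll - ll_prev < tol * (1 + abs(ll)) and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
    return pi, means, var, ll, resp, converged


def fit_lpa(data, k: int, seed: int = 0, n_restarts: int = 20,
            max_iter: int = 500) -> LatentProfileModel:
    """Fit a k-class profile model by EM, best of seeded k-means restarts.

    Variances are free per wave but equated across classes; within-class
    covariances are fixed to zero.  Restarts that collapse a class (expected
    count below 1) are discarded and retried; persistent degeneracy is flagged
    on the returned model.  Classes are canonically ordered by their mean
    trajectory (wave 1 first).
    """
    X = np.asarray(data, dtype=float)
    n, w = X.shape
    if np.isnan(X).any():
        raise ValueError("fit_lpa requires a completed matrix; run impute_single")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k * w:
        raise ValueError("need n > k * waves observations")
    if k == 1:
        # closed form: sample moments
        means = X.mean(axis=0, keepdims=True)
        var = np.maximum(X.var(axis=0), 1e-10)
        ll = float(-0.5 * (n * (np.log(2 * np.pi * var)).sum()
                           + (((X - means) ** 2) / var).sum()))
        p = w + w  # means + variances (k-1 = 0 mixing)
        return LatentProfileModel(
            1, means, var, np.ones(1), ll, -2 * ll + p * np.log(n),
            -2 * ll + 2 * p, 1.0, np.ones((n, 1)), n, p, True)

    rng = np.random.default_rng(seed)
    best = None
    degenerate_runs = 0
    for _ in range(n_restarts):
        labels = _kmeans(X, k, rng)
        resp0 = np.full((n, k), 1e-3)
        resp0[np.arange(n), labels] = 1.0
        resp0 /= resp0.sum(axis=1, keepdims=True)
        out = _lpa_em(X, k, resp0, max_iter=max_iter)
        if out is None:
            degenerate_runs += 1
            continue
        if best is None or out[3] > best[3]:
            best = out
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts degenerated for k={k}")
    pi, means, var, ll, resp, converged = best
    if degenerate_runs == n_restarts - 1:
        log.warning("fit_lpa k=%d: only one non-degenerate restart", k)

    order = np.lexsort(means[:, ::-1].T)  # sort by wave-1 mean, then later waves
    pi, means, resp = pi[order], means[order], resp[:, order]

    p = k * w + w + k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(resp > 0, resp * np.log(resp), 0.0)
    entropy = 1.0 + plogp.sum() / (n * np.log(k))
    return LatentProfileModel(
        k, means, var, pi, ll, -2 * ll + p * np.log(n), -2 * ll + 2 * p,
        float(entropy), resp, n, p, converged,
        degenerate=degenerate_runs == n_restarts)


def select_k(models) -> tuple[LatentProfileModel, pd.DataFrame]:
    """Model-selection table over fitted class counts; best by BIC.

    Ties (within 1e-6) break toward the smaller k.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need >= 2 fitted models to select")
    tab = pd.DataFrame({
        "k": [m.k for m in models],
        "log_likelihood": [m.log_likelihood for m in models],
        "n_params": [m.n_params for m in models],
        "bic": [m.bic for m in models],
        "aic": [m.aic for m in models],
        "entropy": [m.entropy for m in models],
    }).sort_values("k").reset_index(drop=True)
    best_row = min(range(len(tab)),
                   key=lambda i: (round(float(tab.bic[i]), 6), int(tab.k[i])))
    tab["best_bic"] = [i == best_row for i in range(len(tab))]
    best_model = next(m for m in models if m.k == int(tab.k[best_row]))
    return best_model, tab


def assign_profiles(model: LatentProfileModel) -> tuple[np.ndarray, pd.DataFrame]:
    """Modal-posterior class labels plus empirical vs model proportions."""
    labels = model.posterior.argmax(axis=1)
    emp = np.bincount(labels, minlength=model.k) / model.n
    tab = pd.DataFrame({
        "class": np.arange(model.k),
        "mixing_proportion": model.mixing,
        "modal_proportion": emp,
    })
    return labels, tab
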