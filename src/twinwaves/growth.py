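"""Latent growth curve (LGC) models over the five waves.

A random-coefficient model: each individual's trajectory is a polynomial in
fixed time codes with latent intercept/slope (and optionally quadratic)
factors; implied mean is Lambda·alpha and implied covariance
Lambda·Psi·Lambda' + diag(theta).  Fitted by FIML through
:mod:`twinwaves.sem`, so individuals missing waves still contribute.

Default time codes are years since the pre-pandemic baseline for assessments
in 2018, April/July/October 2020 and March 2021: (0, 2.0, 2.25, 2.5, 2.92).
Residual variances are free per wave by default; the abrupt context change at
wave 2 makes homoscedasticity implausible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sem

__all__ = ["fit_lgc", "compare_growth", "GrowthResult", "DEFAULT_TIME_CODES"]

log = logging.getLogger(__name__)

DEFAULT_TIME_CODES = (0.0, 2.0, 2.25, 2.5, 2.92)


def _lgc_model(time_codes: np.ndarray, shape: str,
               homoscedastic: bool = False,
               free_growth_cov: bool = True) -> sem.StructuredModel:
    w = len(time_codes)
    q = {"intercept": 1, "linear": 2, "quadratic": 3}[shape]
    lam = np.column_stack([time_codes ** d for d in range(q)])
    names = [f"alpha{d}" for d in range(q)]
    start = [0.0] * q
    bounds = [(None, None)] * q
    if free_growth_cov:
        tril = list(zip(*np.tril_indices(q)))
    else:
        tril = [(0, 0)]  # intercept variance only
    for r, c in tril:
        names.append(f"psiL{r}{c}")
        start.append(0.7 if r == c else 0.0)
        bounds.append((0.0, None) if r == c else (None, None))
    n_theta = 1 if homoscedastic else w
    for i in range(n_theta):
        names.append(f"theta{i+1}")
        start.append(0.5)
        bounds.append((0.0, None))

    def implied(p):
        alpha = p[:q]
        L = np.zeros((q, q))
        for (r, c), v in zip(tril, p[q:q + len(tril)]):
            L[r, c] = v
        psi = L @ L.T
        theta = p[q + len(tril):]
        theta_full = np.repeat(theta, w) if homoscedastic else theta
        cov = lam @ psi @ lam.T + np.diag(theta_full)
        return {"all": (lam @ alpha, cov)}

    m = sem.StructuredModel(names, np.array(start), bounds, implied)
    m.meta = {"q": q, "tril": tril, "lam": lam, "shape": shape}
    return m


@dataclass
class GrowthResult:
    shape: str
    fixed: dict                # alpha0 (intercept mean), alpha1, [alpha2]
    growth_cov: np.ndarray     # Psi, random intercept/slope (co)variances
    residual_variances: np.ndarray
    deviance: float
    aic: float
    bic: float
    converged: bool
    n: int
    n_free: int
    slope_var_lrt: sem.LRTResult | None = None
    heywood: list = field(default_factory=list)
    time_codes: tuple = DEFAULT_TIME_CODES


def fit_lgc(data, shape: str = "linear", time_codes=None,
            homoscedastic: bool = False, seed: int = 0,
            slope_test: bool = True) -> GrowthResult:
    """Fit an intercept+slope (optionally +quadratic) growth curve by FIML.

    ``data`` is an individuals x waves matrix with NaN for missing waves.
    The slope-variance likelihood-ratio test compares against a model with
    only a random intercept (slope means kept fixed effects); with variance
    components on the boundary the chi-square reference is conservative.
    Residual variances estimated at the zero bound are flagged as Heywood.
    """
    X = np.asarray(data, dtype=float)
    tc = np.asarray(time_codes if time_codes is not None else DEFAULT_TIME_CODES,
                    dtype=float)
    if X.shape[1] != len(tc):
        raise ValueError("time_codes length must match number of waves")
    if shape == "linear" and X.shape[1] < 3:
        raise ValueError("linear growth needs >= 3 waves")
    if shape == "quadratic" and X.shape[1] < 4:
        raise ValueError("quadratic growth needs >= 4 waves")
    model = _lgc_model(tc, shape, homoscedastic)
    fit = sem.fit_ml(model, {"all": X}, seed=seed)
    if not fit.converged:
        log.warning("LGC (%s) fit did not converge", shape)
    q = model.meta["q"]
    tril = model.meta["tril"]
    L = np.zeros((q, q))
    for (r, c), v in zip(tril, fit.params[q:q + len(tril)]):
        L[r, c] = v
    psi = L @ L.T
    theta = fit.params[q + len(tril):]
    heywood = [f"theta{i+1}" for i, t in enumerate(theta) if t < 1e-8]
    lrt_res = None
    if slope_test and q > 1 and fit.converged:
        nested_model = _lgc_model(tc, shape, homoscedastic, free_growth_cov=False)
        nested = sem.fit_ml(nested_model, fit.data, seed=seed)
        if nested.converged:
            lrt_res = sem.lrt(fit, nested, df=len(tril) - 1)
    return GrowthResult(
        shape=shape,
        fixed={f"alpha{d}": fit[f"alpha{d}"] for d in range(q)},
        growth_cov=psi,
        residual_variances=np.asarray(theta),
        deviance=fit.deviance, aic=fit.aic, bic=fit.bic(),
        converged=fit.converged, n=fit.n_per_group["all"],
        n_free=fit.n_free, slope_var_lrt=lrt_res, heywood=heywood,
        time_codes=tuple(tc),
    )


def compare_growth(data, time_codes=None, seed: int = 0) -> pd.DataFrame:
    """Linear vs quadratic growth: AIC/BIC comparison and nested LRT."""
    lin = fit_lgc(data, "linear", time_codes, seed=seed, slope_test=False)
    quad = fit_lgc(data, "quadratic", time_codes, seed=seed, slope_test=False)
    rows = []
    for r in (lin, quad):
        rows.append({"shape": r.shape, "deviance": r.deviance, "aic": r.aic,
                     "bic": r.bic, "n_free": r.n_free, "converged": r.converged})
    tab = pd.DataFrame(rows)
    df = quad.n_free - lin.n_free
    stat = max(lin.deviance - quad.deviance, 0.0)
    from scipy.stats import chi2
    tab.attrs["lrt"] = {"statistic": stat, "df": df,
                        "p_value": float(chi2.sf(stat, df))}
    tab.attrs["preferred_bic"] = tab.loc[tab.bic.idxmin(), "shape"]
    return tab
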