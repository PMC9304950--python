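"""Classical twin-design genetic analyses.

The twin method contrasts MZ pairs (genetically identical) with DZ pairs
(sharing on average half their segregating genes) to decompose phenotypic
variance into additive-genetic (A), shared-environmental (C) and nonshared-
environmental (E, including measurement error) components.  Model-implied
cross-twin covariances are a2+c2 for MZ and 0.5·a2+c2 for DZ; multivariate
extensions add cross-wave factor correlations (correlated-factors solution)
or triangular innovation paths (Cholesky decomposition).  All models are fitted
by FIML through :mod:`twinwaves.sem`, so pairs with one missing co-twin or
missing waves still contribute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sem
from .preprocess import double_enter
from .simulate import TwinCohort, pheno_col

__all__ = [
    "twin_correlations",
    "falconer",
    "fit_univariate_ace",
    "fit_correlated_factors",
    "fit_cholesky",
    "TwinCorrelations",
    "ACEResult",
    "CorrelatedFactorsResult",
    "CholeskyResult",
    "family_table",
]

log = logging.getLogger(__name__)


def family_table(cohort: TwinCohort, measure: str, waves=None) -> dict:
    """Per-zygosity family arrays: one row per family, twin-1 waves then
    twin-2 waves.  Missing cells are NaN; all-missing families are kept (they
    drop out of the likelihood)."""
    waves = list(waves) if waves is not None else list(range(1, cohort.n_waves + 1))
    cols = [pheno_col(measure, w) for w in waves]
    out = {}
    df = cohort.data.sort_values(["family_id", "twin"])
    for grp in ("MZ", "DZ"):
        sub = df[df.zygosity == grp]
        t1 = sub[sub.twin == 1].set_index("family_id")[cols]
        t2 = sub[sub.twin == 2].set_index("family_id")[cols]
        fams = t1.index.union(t2.index)
        X = np.full((len(fams), 2 * len(cols)), np.nan)
        X[:, : len(cols)] = t1.reindex(fams).to_numpy()
        X[:, len(cols):] = t2.reindex(fams).to_numpy()
        out[grp] = X
    return out


# ---------------------------------------------------------------------------
# intraclass correlations and moment estimates
# ---------------------------------------------------------------------------

@dataclass
class TwinCorrelations:
    """Double-entry intraclass correlations per zygosity per measure-wave."""

    table: pd.DataFrame  # measure, wave, zygosity, r, ci_low, ci_high, n_pairs

    def get(self, measure: str, wave: int, zygosity: str) -> float:
        t = self.table
        row = t[(t.measure == measure) & (t.wave == wave) & (t.zygosity == zygosity)]
        return float(row.r.iloc[0])


def twin_correlations(cohort: TwinCohort, level: float = 0.95) -> TwinCorrelations:
    """MZ and DZ intraclass correlations via double-entered Pearson r.

    Confidence intervals are Fisher-z intervals on the number of complete
    pairs (not the doubled record count).  Cells with fewer than 3 complete
    pairs are reported missing.
    """
    de = double_enter(cohort)
    zq = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for m in cohort.measures:
        for w in range(1, cohort.n_waves + 1):
            col = pheno_col(m, w)
            for zyg in ("MZ", "DZ"):
                sub = de[de.zygosity == zyg]
                a = sub[f"{col}_self"].to_numpy(dtype=float)
                b = sub[f"{col}_cotwin"].to_numpy(dtype=float)
                ok = ~np.isnan(a) & ~np.isnan(b)
                n_pairs = int(ok.sum()) // 2
                if n_pairs < 3:
                    rows.append({"measure": m, "wave": w, "zygosity": zyg,
                                 "r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "n_pairs": n_pairs})
                    continue
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
                if n_pairs > 3 and abs(r) < 1:
                    z = np.arctanh(r)
                    half = zq / np.sqrt(n_pairs - 3)
                    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
                else:
                    ci = (np.nan, np.nan)
                rows.append({"measure": m, "wave": w, "zygosity": zyg, "r": r,
                             "ci_low": ci[0], "ci_high": ci[1], "n_pairs": n_pairs})
    return TwinCorrelations(pd.DataFrame(rows))


def falconer(rmz: float, rdz: float) -> tuple[float, float, float]:
    """Falconer moment estimates a2 = 2(rMZ − rDZ), c2 = 2rDZ − rMZ,
    e2 = 1 − rMZ; unconstrained, so negative estimates are returned raw with a
    warning."""
    a2 = 2.0 * (rmz - rdz)
    c2 = 2.0 * rdz - rmz
    e2 = 1.0 - rmz
    if min(a2, c2, e2) < 0:
        warnings.warn(
            f"negative Falconer estimate (a2={a2:.3f}, c2={c2:.3f}, e2={e2:.3f}); "
            "SEM estimates are the constrained authoritative values")
    return (a2, c2, e2)


# ---------------------------------------------------------------------------
# univariate ACE
# ---------------------------------------------------------------------------

@dataclass
class ACEResult:
    """Standardized variance components from a two-group univariate fit."""

    a2: float
    c2: float
    e2: float
    ci: dict  # component -> (low, high); empty unless requested
    paths: dict  # unstandardized parameters
    deviance: float
    converged: bool
    n_per_group: dict
    boundary: list = field(default_factory=list)

    def components(self) -> tuple[float, float, float]:
        return (self.a2, self.c2, self.e2)


def _ace_model(components: str = "ACE") -> sem.StructuredModel:
    """Two-group univariate model parameterized in total variance and
    standardized proportions (profile CIs then apply directly to a2/c2)."""
    has_a = "A" in components
    has_c = "C" in components
    names = ["mu", "V"]
    start = [0.0, 1.0]
    bounds = [(None, None), (1e-6, None)]
    if has_a:
        names.append("a2")
        start.append(0.4)
        bounds.append((0.0, 1.0))
    if has_c:
        names.append("c2")
        start.append(0.1)
        bounds.append((0.0, 1.0))

    def implied(p):
        mu, V = p[0], p[1]
        i = 2
        a2 = p[i] if has_a else 0.0
        i += has_a
        c2 = p[i] if has_c else 0.0
        m = np.array([mu, mu])
        out = {}
        for g, coef in (("MZ", 1.0), ("DZ", 0.5)):
            off = V * (coef * a2 + c2)
            out[g] = (m, np.array([[V, off], [off, V]]))
        return out

    return sem.StructuredModel(names, np.array(start), bounds, implied)


def fit_univariate_ace(cohort: TwinCohort, measure: str, wave: int,
                       ci: bool = False, level: float = 0.95,
                       seed: int = 0) -> ACEResult:
    """Two-group univariate ACE decomposition by FIML.

    The MZ implied cross-twin covariance is V(a2+c2), the DZ one V(0.5·a2+c2);
    pairs with one missing co-twin are retained through FIML.  Standardized
    components are returned; profile-likelihood CIs on a2 and c2 (and e2 via a
    reparameterized refit) when ``ci=True``.  Components whose CI touches 0 or
    1 are listed in ``boundary``.
    """
    data = family_table(cohort, measure, [wave])
    for g in ("MZ", "DZ"):
        if np.isfinite(data[g]).sum() == 0:
            raise ValueError(f"no observed data in {g} group")
    model = _ace_model()
    fit = sem.fit_ml(model, data, seed=seed)
    if not fit.converged:
        log.warning("univariate ACE fit for %s wave %d did not converge",
                    measure, wave)
    a2, c2 = fit["a2"], fit["c2"]
    e2 = 1.0 - a2 - c2
    cis: dict = {}
    boundary = []
    if ci and fit.converged:
        cis["a2"] = sem.profile_ci(fit, "a2", level)
        cis["c2"] = sem.profile_ci(fit, "c2", level)
        # e2 needs its own parameterization: swap the roles of e2 and a2
        e_model = _e2_model()
        e_fit = sem.fit_ml(e_model, fit.data, seed=seed)
        cis["e2"] = (sem.profile_ci(e_fit, "e2", level)
                     if e_fit.converged else (np.nan, np.nan))
        for k, (lo, hi) in cis.items():
            if lo <= 1e-4 or hi >= 1 - 1e-4:
                boundary.append(k)
    return ACEResult(a2, c2, e2, cis,
                     {"mu": fit["mu"], "V": fit["V"]},
                     fit.deviance, fit.converged, fit.n_per_group, boundary)


def _e2_model() -> sem.StructuredModel:
    """Univariate two-group model parameterized (mu, V, e2, c2)."""

    def implied(p):
        mu, V, e2, c2 = p
        a2 = 1.0 - e2 - c2
        m = np.array([mu, mu])
        out = {}
        for g, coef in (("MZ", 1.0), ("DZ", 0.5)):
            off = V * (coef * a2 + c2)
            out[g] = (m, np.array([[V, off], [off, V]]))
        return out

    return sem.StructuredModel(
        ["mu", "V", "e2", "c2"], np.array([0.0, 1.0, 0.5, 0.1]),
        [(None, None), (1e-6, None), (0.0, 1.0), (0.0, 1.0)], implied)


def fit_ace_submodels(cohort: TwinCohort, measure: str, wave: int,
                      seed: int = 0) -> dict:
    """ACE, AE and CE fits with deviances, for nested model comparison."""
    data = family_table(cohort, measure, [wave])
    out = {}
    for comp in ("ACE", "AE", "CE"):
        out[comp] = sem.fit_ml(_ace_model(comp), data, seed=seed)
    return out


# ---------------------------------------------------------------------------
# multivariate: correlated factors and Cholesky
# ---------------------------------------------------------------------------

def _corr_from_params(scales: np.ndarray, rs: np.ndarray, w: int) -> np.ndarray:
    R = np.eye(w)
    iu = np.triu_indices(w, k=1)
    R[iu] = rs
    R[(iu[1], iu[0])] = rs
    return np.diag(scales) @ R @ np.diag(scales)


def _twin_cov(sig_a, sig_c, sig_e, coef: float) -> tuple[np.ndarray, np.ndarray]:
    within = sig_a + sig_c + sig_e
    between = coef * sig_a + sig_c
    return within, between


def _stack(within: np.ndarray, between: np.ndarray) -> np.ndarray:
    return np.block([[within, between], [between.T, within]])


def _cf_model(w: int) -> sem.StructuredModel:
    """Correlated-factors parameterization: per factor, per-wave scale paths
    plus cross-wave factor correlations (PSD enforced via the likelihood
    penalty for non-PD implied covariance)."""
    n_r = w * (w - 1) // 2
    names, start, bounds = [], [], []
    for f, s0 in (("a", 0.57), ("c", 0.26), ("e", 0.77)):
        names += [f"{f}{i+1}" for i in range(w)]
        start += [s0] * w
        bounds += [(0.0, None)] * w
        iu = np.triu_indices(w, k=1)
        names += [f"r{f.upper()}{i+1}{j+1}" for i, j in zip(*iu)]
        start += [0.5] * n_r
        bounds += [(-1.0, 1.0)] * n_r
    names += [f"mu{i+1}" for i in range(w)]
    start += [0.0] * w
    bounds += [(None, None)] * w
    blk = w + n_r

    def implied(p):
        sigs = []
        for k in range(3):
            seg = p[k * blk:(k + 1) * blk]
            sigs.append(_corr_from_params(seg[:w], seg[w:], w))
        mu = np.tile(p[3 * blk:3 * blk + w], 2)
        out = {}
        for g, coef in (("MZ", 1.0), ("DZ", 0.5)):
            within, between = _twin_cov(*sigs, coef)
            out[g] = (mu, _stack(within, between))
        return out

    return sem.StructuredModel(names, np.array(start), bounds, implied)


@dataclass
class CorrelatedFactorsResult:
    rG: np.ndarray
    rC: np.ndarray
    rE: np.ndarray
    ci: dict  # e.g. "rG12" -> (low, high)
    per_wave: pd.DataFrame  # wave, a2, c2, e2
    deviance: float
    converged: bool
    n_per_group: dict
    waves: list


def fit_correlated_factors(cohort: TwinCohort, measure: str, waves=None,
                           ci: bool = False, ci_params: list | None = None,
                           level: float = 0.95,
                           seed: int = 0) -> CorrelatedFactorsResult:
    """Multivariate correlated-factors twin model across waves.

    Cross-twin cross-wave covariances are rA-weighted A terms (x1 for MZ,
    x0.5 for DZ) plus rC-weighted C terms; within-twin cross-wave covariances
    additionally carry the rE terms.  Genetic (rG), shared- (rC) and
    nonshared-environmental (rE) cross-wave correlations are free parameters,
    so profile CIs apply to them directly.  Waves with near-zero A variance
    leave rG boundary-censored rather than dropped.
    """
    waves = list(waves) if waves is not None else list(range(1, cohort.n_waves + 1))
    w = len(waves)
    if w < 2:
        raise ValueError("need >= 2 waves for a correlated-factors model")
    data = family_table(cohort, measure, waves)
    model = _cf_model(w)
    fit = sem.fit_ml(model, data, seed=seed)
    if not fit.converged:
        log.warning("correlated-factors fit for %s did not converge", measure)

    iu = np.triu_indices(w, k=1)
    mats = {}
    per_wave = {f: np.empty(w) for f in "ace"}
    for f in "ace":
        R = np.eye(w)
        R[iu] = [fit[f"r{f.upper()}{i+1}{j+1}"] for i, j in zip(*iu)]
        R[(iu[1], iu[0])] = R[iu]
        mats[f] = R
        per_wave[f] = np.array([fit[f"{f}{i+1}"] for i in range(w)]) ** 2
    total = per_wave["a"] + per_wave["c"] + per_wave["e"]
    pw = pd.DataFrame({
        "wave": waves,
        "a2": per_wave["a"] / total,
        "c2": per_wave["c"] / total,
        "e2": per_wave["e"] / total,
    })
    cis: dict = {}
    if ci and fit.converged:
        targets = ci_params or [f"r{f}{i+1}{j+1}" for f in "ACE"
                                for i, j in zip(*iu)]
        for t in targets:
            cis[t] = sem.profile_ci(fit, t, level)
    return CorrelatedFactorsResult(mats["a"], mats["c"], mats["e"], cis, pw,
                                   fit.deviance, fit.converged,
                                   fit.n_per_group, waves)


def _chol_model(w: int) -> sem.StructuredModel:
    """Triangular-path (Cholesky) parameterization of the same likelihood."""
    tril = list(zip(*np.tril_indices(w)))
    names, start, bounds = [], [], []
    for f, s0 in (("a", 0.57), ("c", 0.26), ("e", 0.77)):
        for r, c in tril:
            names.append(f"{f}{r+1}{c+1}")
            start.append(s0 if r == c else 0.1)
            bounds.append((0.0, None) if r == c else (None, None))
    names += [f"mu{i+1}" for i in range(w)]
    start += [0.0] * w
    bounds += [(None, None)] * w
    blk = len(tril)

    def implied(p):
        sigs = []
        for k in range(3):
            X = np.zeros((w, w))
            X[np.tril_indices(w)] = p[k * blk:(k + 1) * blk]
            sigs.append(X @ X.T)
        mu = np.tile(p[3 * blk:3 * blk + w], 2)
        out = {}
        for g, coef in (("MZ", 1.0), ("DZ", 0.5)):
            within, between = _twin_cov(*sigs, coef)
            out[g] = (mu, _stack(within, between))
        return out

    return sem.StructuredModel(names, np.array(start), bounds, implied)


@dataclass
class CholeskyResult:
    paths_A: np.ndarray
    paths_C: np.ndarray
    paths_E: np.ndarray
    innovation: pd.DataFrame  # wave, A, C, E wave-specific/total variance share
    deviance: float
    converged: bool
    n_per_group: dict
    waves: list

    def factor_cov(self, which: str) -> np.ndarray:
        X = {"A": self.paths_A, "C": self.paths_C, "E": self.paths_E}[which]
        return X @ X.T


def fit_cholesky(cohort: TwinCohort, measure: str, waves=None,
                 seed: int = 0) -> CholeskyResult:
    """Cholesky (triangular innovation) decomposition across waves.

    Each factor's covariance is X·X' with X lower-triangular, so the variance
    at wave j splits into parts transmitted from earlier waves and a
    wave-specific innovation X[j,j]^2; the reported innovation proportion is
    the wave-specific share of that wave's factor variance.  Likelihood-
    equivalent to the correlated-factors model (same implied covariances,
    different parameterization).
    """
    waves = list(waves) if waves is not None else list(range(1, cohort.n_waves + 1))
    w = len(waves)
    if w < 2:
        raise ValueError("need >= 2 waves for a Cholesky model")
    data = family_table(cohort, measure, waves)
    model = _chol_model(w)
    fit = sem.fit_ml(model, data, seed=seed)
    if not fit.converged:
        log.warning("Cholesky fit for %s did not converge", measure)
    tril = np.tril_indices(w)
    blk = len(tril[0])
    Xs = {}
    for k, f in enumerate("ACE"):
        X = np.zeros((w, w))
        X[tril] = fit.params[k * blk:(k + 1) * blk]
        Xs[f] = X
    rows = []
    for j in range(w):
        row = {"wave": waves[j]}
        for f in "ACE":
            tot = float((Xs[f][j] ** 2).sum())
            row[f] = float(Xs[f][j, j] ** 2 / tot) if tot > 1e-12 else np.nan
        rows.append(row)
    return CholeskyResult(Xs["A"], Xs["C"], Xs["E"], pd.DataFrame(rows),
                          fit.deviance, fit.converged, fit.n_per_group, waves)
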