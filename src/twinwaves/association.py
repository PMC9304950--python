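"""General-liability factors, polygenic-score association, and extremes.

Covers the individual-difference analyses downstream of the twin models: the
phenotypic/genomic p-factor (first principal component across measures or
across psychiatric polygenic scores), covariate-adjusted incremental variance
explained by a polygenic score, ±1 s.d. extreme-group trajectory contrasts,
environmental-correlate correlations, and retained-vs-full attrition checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import cohens_d, rm_manova, ManovaResult
from .simulate import TwinCohort, pheno_col

__all__ = [
    "p_factor",
    "gps_regression",
    "extreme_groups",
    "trajectory_contrast",
    "environment_correlates",
    "attrition_check",
    "extremes_analysis",
    "PFactorResult",
    "ExtremeContrast",
]


@dataclass
class PFactorResult:
    loadings: np.ndarray       # unit-norm first principal axis
    scores: np.ndarray         # per individual, mean 0 / s.d. 1 (NaN if incomplete)
    explained_variance: float  # share of total variance in the first component
    columns: list


def p_factor(scores) -> PFactorResult:
    """First principal component of a column-standardized matrix.

    Complete-case: rows with any missing input get an NaN score.  Zero-
    variance columns are dropped with a warning.  The sign is fixed so the
    mean loading is positive (higher score = more symptoms when inputs are
    symptom-coded).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an individuals x variables matrix with >= 2 columns")
    cols = list(range(X.shape[1]))
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    if Xc.shape[0] < X.shape[1]:
        raise ValueError("fewer complete-case rows than variables")
    sd = Xc.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping zero-variance columns {list(np.where(~keep)[0])}")
        cols = [c for c, k in zip(cols, keep) if k]
        Xc = Xc[:, keep]
        sd = sd[keep]
    Z = (Xc - Xc.mean(axis=0)) / sd
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    load = vt[0]
    if load.mean() < 0:
        load = -load
    raw = Z @ load
    scores_out = np.full(X.shape[0], np.nan)
    scores_out[complete] = (raw - raw.mean()) / raw.std()
    ev = float(svals[0] ** 2 / (svals ** 2).sum())
    return PFactorResult(load, scores_out, ev, cols)


def gps_regression(pheno, gps, covariates=None, n_permutations: int = 0,
                   seed: int = 0) -> dict:
    """Incremental variance in a phenotype explained by a polygenic score.

    Delta R^2 between the covariates-only and covariates+GPS ordinary
    least-squares fits on complete cases; equal to the squared partial
    correlation of phenotype and GPS given covariates.  An optional
    permutation p-value shuffles the GPS across individuals.  Callers should
    pass one individual per family (see ``preprocess.select_one_per_pair``).
    """
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(gps, dtype=float)
    C = (np.empty((len(y), 0)) if covariates is None
         else np.asarray(covariates, dtype=float).reshape(len(y), -1))
    ok = ~np.isnan(y) & ~np.isnan(g) & ~np.isnan(C).any(axis=1)
    y, g, C = y[ok], g[ok], C[ok]
    X0 = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        warnings.warn(f"collinear covariates (rank {rank} < {X0.shape[1]})")

    def r2(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    r2_0 = r2(X0)
    r2_1 = r2(np.column_stack([X0, g]))
    delta = max(r2_1 - r2_0, 0.0)
    out = {"delta_r2": float(delta), "r2_covariates": float(r2_0),
           "r2_full": float(r2_1), "n": int(len(y))}
    if n_permutations:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            gp = rng.permutation(g)
            if max(r2(np.column_stack([X0, gp])) - r2_0, 0.0) >= delta:
                count += 1
        out["p_permutation"] = (count + 1) / (n_permutations + 1)
    return out


def extreme_groups(scores, threshold_sd: float = 1.0) -> np.ndarray:
    """Label individuals below −threshold ("low"), above +threshold ("high").

    Scores are standardized internally; boundary values exactly at the
    threshold fall in the excluded middle (strict inequalities).  Returns an
    object array of "low" / "mid" / "high" (NaN scores get "mid").
    """
    z = np.asarray(scores, dtype=float)
    sd = np.nanstd(z)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("constant or empty scores: both extreme groups empty")
        return np.full(z.shape, "mid", dtype=object)
    z = (z - np.nanmean(z)) / sd
    lab = np.full(z.shape, "mid", dtype=object)
    lab[z < -threshold_sd] = "low"
    lab[z > threshold_sd] = "high"
    if (lab == "low").sum() == 0 or (lab == "high").sum() == 0:
        warnings.warn("an extreme group is empty")
    return lab


@dataclass
class ExtremeContrast:
    n_low: int
    n_high: int
    means: pd.DataFrame        # wave, mean_low, mean_high
    d: np.ndarray              # per-wave Cohen's d (high minus low)
    interaction: ManovaResult | None


def trajectory_contrast(waves_matrix, groups) -> ExtremeContrast:
    """Per-wave high-vs-low standardized differences plus group x time MANOVA.

    ``groups`` are the labels from :func:`extreme_groups`; the middle group is
    excluded.  d is computed on the observed samples per wave (pooled s.d.);
    the interaction test is the complete-case contrast-score MANOVA with group
    as the between factor.
    """
    Y = np.asarray(waves_matrix, dtype=float)
    g = np.asarray(groups)
    low, high = g == "low", g == "high"
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError("both extreme groups must be non-empty")
    w = Y.shape[1]
    ds = np.empty(w)
    rows = []
    for j in range(w):
        a = Y[low, j]
        b = Y[high, j]
        ds[j] = cohens_d(a, b)
        rows.append({"wave": j + 1,
                     "mean_low": float(np.nanmean(a)),
                     "mean_high": float(np.nanmean(b))})
    sub = low | high
    inter = None
    try:
        res = rm_manova(Y[sub], sex=g[sub])
        inter = next(r for r in res if r.effect == "time_x_sex")
        inter.effect = "group_x_time"
    except ValueError:
        pass
    return ExtremeContrast(int(low.sum()), int(high.sum()),
                           pd.DataFrame(rows), ds, inter)


def environment_correlates(pheno, env_composite, level: float = 0.95) -> dict:
    """Pearson correlation of a phenotype with an environmental composite,
    with a Fisher-z confidence interval (pairwise complete)."""
    x = np.asarray(pheno, dtype=float)
    y = np.asarray(env_composite, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (np.nan, np.nan)
    return {"r": r, "ci_low": ci[0], "ci_high": ci[1], "n": n}


def attrition_check(full: TwinCohort, retained: TwinCohort,
                    variables) -> pd.DataFrame:
    """Compare descriptives between the full and a retained subsample.

    Standardized difference = (retained mean − full mean) / full s.d.; near
    zero under MCAR attrition, shifted under selective (MAR) attrition.
    """
    rows = []
    for v in variables:
        a = full.data[v].dropna()
        b = retained.data[v].dropna()
        sd = a.std(ddof=1)
        rows.append({
            "variable": v, "n_full": len(a), "n_retained": len(b),
            "mean_full": a.mean(), "mean_retained": b.mean(),
            "sd_full": sd, "sd_retained": b.std(ddof=1),
            "std_difference": (b.mean() - a.mean()) / sd if sd > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def extremes_analysis(df: pd.DataFrame, measures, n_waves: int,
                      threshold_sd: float = 1.0) -> dict:
    """Full extremes pipeline on a table of unrelated individuals.

    Baseline (wave 1) scores across all measures feed a PCA p-factor; groups
    are the ±threshold s.d. tails of the standardized component; each
    measure's trajectory is contrasted between groups.  Returns the p-factor,
    the per-measure contrasts, and the mean d per wave across measures.
    """
    base = np.column_stack([df[pheno_col(m, 1)].to_numpy(dtype=float)
                            for m in measures])
    pf = p_factor(base)
    groups = extreme_groups(pf.scores, threshold_sd)
    contrasts = {}
    dmat = []
    for m in measures:
        Y = np.column_stack([df[pheno_col(m, w)].to_numpy(dtype=float)
                             for w in range(1, n_waves + 1)])
        contrasts[m] = trajectory_contrast(Y, groups)
        dmat.append(contrasts[m].d)
    return {"p_factor": pf, "groups": groups, "contrasts": contrasts,
            "mean_d_per_wave": np.mean(dmat, axis=0)}
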