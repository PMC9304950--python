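"""Descriptive and effect-size analyses of repeated mental-health measures.

Covers the phenotypic mean-level analyses: per-wave descriptive statistics,
standardized mean differences (Cohen's d) between waves, the d-to-variance
conversion, repeated-measures MANOVA on within-person wave contrasts (Wilks'
Lambda, Rao's F, partial eta squared), and pairwise cross-wave correlation
matrices with Fisher-z confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TwinCohort, pheno_col

__all__ = [
    "cohens_d",
    "d_to_variance",
    "rm_manova",
    "crosswave_correlations",
    "describe_effects",
    "ManovaResult",
    "EffectSizeTable",
    "CorrelationMatrix",
]


def cohens_d(sample_a, sample_b) -> float:
    """Standardized mean difference (b minus a) over the pooled s.d.

    The two samples are treated as independent groups (as when comparing the
    observed samples at two waves under attrition); the pooled s.d. is the
    n-weighted two-sample form.  Positive d means an increase from a to b.

    Raises ValueError when either sample has < 2 non-missing values or the
    pooled s.d. is zero.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("cohens_d: each sample needs >= 2 non-missing values")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("cohens_d: zero pooled s.d., d undefined")
    return float((b.mean() - a.mean()) / np.sqrt(sp2))


def d_to_variance(d: float) -> float:
    """Proportion of variance associated with a standardized difference.

    Equal-group point-biserial conversion r^2 = d^2 / (d^2 + 4); e.g. d = 0.35
    corresponds to about 3% of variance.
    """
    d = float(d)
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    return d * d / (d * d + 4.0)


@dataclass
class ManovaResult:
    effect: str  # "time" | "sex" | "time_x_sex"
    wilks: float
    F: float
    df1: float
    df2: float
    p_value: float
    partial_eta_sq: float
    n_used: int
    n_dropped: int


def _wilks_test(E: np.ndarray, H: np.ndarray, df_h: int, df_e: int,
                ) -> tuple[float, float, float, float, float, float]:
    """Wilks' Lambda with Rao's F approximation and partial eta squared."""
    p = E.shape[0]
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    q = df_h
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4) / (p * p + q * q - 5))
    else:
        t = 1.0
    df1 = p * q
    df2 = (df_e + df_h - (p + q + 1) / 2) * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan
    s = min(p, q)
    eta = 1.0 - lam ** (1.0 / s)
    return lam, float(F), float(df1), float(df2), pval, float(eta)


def rm_manova(data, sex=None) -> list[ManovaResult]:
    """Repeated-measures MANOVA on within-person wave contrasts.

    ``data`` is an individuals x waves matrix (NaN = missing); analysis is
    complete-case.  Successive-difference contrast scores carry the
    within-person (time) information; with a binary ``sex`` factor the model
    additionally tests the between-person sex effect (on the person means) and
    the time x sex interaction (sex effect on the contrast scores).  Reported
    per effect: Wilks' Lambda, Rao's F approximation with its degrees of
    freedom, and partial eta squared 1 − Lambda^(1/s) with s = min(p, df_effect).

    Raises ValueError for fewer complete rows than waves + 2 or a singular
    within-group covariance.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("data must be individuals x waves with >= 2 waves")
    n_all = Y.shape[0]
    keep = ~np.isnan(Y).any(axis=1)
    if sex is not None:
        sexv = np.asarray(sex)
        if sexv.shape[0] != n_all:
            raise ValueError("sex length must match data rows")
        keep &= ~pd.isna(sexv)
    Y = Y[keep]
    n = Y.shape[0]
    w = Y.shape[1]
    n_dropped = n_all - n
    if n < w + 2:
        raise ValueError("too few complete-case rows for MANOVA")

    # successive-difference within-person contrasts
    C = np.zeros((w - 1, w))
    for i in range(w - 1):
        C[i, i], C[i, i + 1] = -1.0, 1.0
    D = Y @ C.T  # n x (w-1)
    p = w - 1

    results: list[ManovaResult] = []
    if sex is None:
        X = np.ones((n, 1))
        terms = [("time", D, X, [0])]
    else:
        sv = sexv[keep]
        levels = pd.unique(sv)
        if len(levels) != 2:
            raise ValueError("sex must have exactly 2 levels among complete cases")
        x = np.where(sv == levels[0], -1.0, 1.0)
        X = np.column_stack([np.ones(n), x])
        subj_mean = Y.mean(axis=1, keepdims=True)
        terms = [("time", D, X, [0]), ("time_x_sex", D, X, [1]),
                 ("sex", subj_mean, X, [1])]

    for name, Dm, Xm, test_cols in terms:
        XtX = Xm.T @ Xm
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix") from exc
        beta = XtX_inv @ Xm.T @ Dm
        E = Dm.T @ Dm - beta.T @ XtX @ beta
        rank_e = np.linalg.matrix_rank(E)
        if rank_e < Dm.shape[1]:
            raise ValueError(
                f"singular within-group covariance for effect {name!r} "
                f"(rank {rank_e} < {Dm.shape[1]})"
            )
        L = np.zeros((len(test_cols), Xm.shape[1]))
        for i, c in enumerate(test_cols):
            L[i, c] = 1.0
        Lb = L @ beta
        H = Lb.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ Lb
        df_e = n - Xm.shape[1]
        lam, F, df1, df2, pval, eta = _wilks_test(E, H, len(test_cols), df_e)
        results.append(ManovaResult(name, lam, F, df1, df2, pval, eta, n, n_dropped))
    return results


@dataclass
class CorrelationMatrix:
    r: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray

    def mean_offdiag(self) -> float:
        iu = np.triu_indices_from(self.r, k=1)
        return float(np.nanmean(self.r[iu]))


def crosswave_correlations(data, level: float = 0.95) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between waves with Fisher-z CIs.

    Cells with fewer than 3 pairwise-complete observations are reported as NaN.
    """
    Y = np.asarray(data, dtype=float)
    w = Y.shape[1]
    r = np.eye(w)
    lo = np.eye(w)
    hi = np.eye(w)
    n = np.zeros((w, w), dtype=int)
    zq = stats.norm.ppf(0.5 + level / 2)
    np.fill_diagonal(n, (~np.isnan(Y)).sum(axis=0))
    for i in range(w):
        for j in range(i + 1, w):
            ok = ~np.isnan(Y[:, i]) & ~np.isnan(Y[:, j])
            nij = int(ok.sum())
            n[i, j] = n[j, i] = nij
            if nij < 3:
                r[i, j] = r[j, i] = np.nan
                lo[i, j] = lo[j, i] = hi[i, j] = hi[j, i] = np.nan
                continue
            rij = float(np.corrcoef(Y[ok, i], Y[ok, j])[0, 1])
            r[i, j] = r[j, i] = rij
            if nij > 3 and abs(rij) < 1:
                z = np.arctanh(rij)
                half = zq / np.sqrt(nij - 3)
                lo_ij, hi_ij = np.tanh(z - half), np.tanh(z + half)
            else:
                lo_ij = hi_ij = np.nan
            lo[i, j] = lo[j, i] = lo_ij
            hi[i, j] = hi[j, i] = hi_ij
    return CorrelationMatrix(r, lo, hi, n)


@dataclass
class EffectSizeTable:
    """Per measure-wave descriptives and between-wave Cohen's d."""

    summary: pd.DataFrame  # measure, wave, n, mean, sd, se
    d: pd.DataFrame        # measure, wave_a, wave_b, cohens_d


def describe_effects(cohort: TwinCohort) -> EffectSizeTable:
    """Descriptive statistics per measure-wave plus all between-wave d values."""
    rows, drows = [], []
    for m in cohort.measures:
        samples = {}
        for wv in range(1, cohort.n_waves + 1):
            y = cohort.data[pheno_col(m, wv)].dropna().to_numpy()
            samples[wv] = y
            n = len(y)
            sd = y.std(ddof=1) if n > 1 else np.nan
            rows.append({"measure": m, "wave": wv, "n": n,
                         "mean": y.mean() if n else np.nan, "sd": sd,
                         "se": sd / np.sqrt(n) if n > 1 else np.nan})
        for a in range(1, cohort.n_waves + 1):
            for b in range(a + 1, cohort.n_waves + 1):
                try:
                    dv = cohens_d(samples[a], samples[b])
                except ValueError:
                    dv = np.nan
                drows.append({"measure": m, "wave_a": a, "wave_b": b,
                              "cohens_d": dv})
    return EffectSizeTable(pd.DataFrame(rows), pd.DataFrame(drows))
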