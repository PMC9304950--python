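"""Pre-analysis transformations.

Twin analyses are run on sex- and age-adjusted standardized residuals: co-twins
are identical in age, and MZ co-twins in sex, so uncorrected covariate effects
would inflate shared-environment estimates.  This module also provides the two
standard table reshapes of the twin literature: one-randomly-selected-twin-per-
pair tables (for analyses requiring unrelated individuals) and double-entered
pair tables (for intraclass correlations).
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import TwinCohort

__all__ = ["residualize", "select_one_per_pair", "double_enter"]

log = logging.getLogger(__name__)


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            # binary factor coding; multi-level factors get dummy columns
            levels = sorted(v.dropna().unique())
            for lev in levels[1:]:
                cols.append((v == lev).astype(float).to_numpy())
        else:
            cols.append(pd.to_numeric(v).to_numpy(dtype=float))
    return np.column_stack(cols)


def residualize(cohort: TwinCohort, covariates: Sequence[str] = ("sex", "age")
                ) -> TwinCohort:
    """Replace each phenotype column by standardized OLS residuals.

    Per measure-wave, an ordinary least-squares regression of the phenotype on
    the covariates is fitted on rows observed for both; residuals are then
    standardized to mean 0, s.d. 1 in the estimation sample.  Rows with a
    missing covariate but an observed phenotype receive a residual from the
    fitted model (covariate filled at the sample mean of the design column).
    Missing phenotype cells stay missing.  A constant phenotype column is
    flagged with a warning and returned as all-zero residuals.
    """
    for c in covariates:
        if c not in cohort.data.columns:
            raise ValueError(f"covariate column {c!r} not in cohort")
    out = cohort.copy()
    X_full = _design(out.data, covariates)
    cov_ok = ~np.isnan(X_full).any(axis=1)
    col_means = np.nanmean(np.where(cov_ok[:, None], X_full, np.nan), axis=0)
    X_filled = np.where(np.isnan(X_full), col_means, X_full)

    for m in out.measures:
        for col in out.pheno_cols(m):
            y = out.data[col].to_numpy(dtype=float)
            obs = ~np.isnan(y)
            fit_rows = obs & cov_ok
            if fit_rows.sum() < 3:
                raise ValueError(f"{col}: fewer than 3 complete rows for residualization")
            yf = y[fit_rows]
            if np.std(yf) == 0:
                warnings.warn(f"{col}: constant phenotype; residuals set to 0")
                res = np.where(obs, 0.0, np.nan)
                out.data[col] = res
                continue
            X = X_filled[fit_rows]
            beta, *_ = np.linalg.lstsq(X, yf, rcond=None)
            resid = np.full_like(y, np.nan)
            resid[obs] = y[obs] - X_filled[obs] @ beta
            mu = np.nanmean(resid[fit_rows])
            sd = np.nanstd(resid[fit_rows], ddof=0)
            out.data[col] = (resid - mu) / sd
    return out


def select_one_per_pair(cohort: TwinCohort, seed: int) -> pd.DataFrame:
    """One randomly selected twin per family: a table of unrelated individuals.

    Uniform choice of twin 1 or 2 per family, reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    df = cohort.data
    fams = df["family_id"].unique()
    pick = pd.Series(rng.integers(1, 3, len(fams)), index=fams)
    keep = df["twin"].to_numpy() == pick.loc[df["family_id"]].to_numpy()
    return df.loc[keep].reset_index(drop=True)


def double_enter(cohort: TwinCohort) -> pd.DataFrame:
    """Ordered co-twin pair table: each complete pair contributes twice.

    Returns one record per ordered (self, cotwin) pair with columns
    ``<col>_self`` / ``<col>_cotwin`` for every phenotype and GPS column, plus
    family_id and zygosity.  Families without exactly two rows are dropped
    (count logged).  The double-entered Pearson correlation of a phenotype with
    its co-twin copy is the classical intraclass correlation estimate.
    """
    df = cohort.data
    counts = df.groupby("family_id").size()
    complete = counts[counts == 2].index
    dropped = len(counts) - len(complete)
    if dropped:
        log.info("double_enter: dropped %d incomplete families", dropped)
    sub = df[df["family_id"].isin(complete)].sort_values(["family_id", "twin"])
    t1 = sub[sub["twin"] == 1].set_index("family_id")
    t2 = sub[sub["twin"] == 2].set_index("family_id")
    value_cols = [c for c in df.columns
                  if c not in ("family_id", "twin", "zygosity", "sex", "age")]
    recs = []
    for a, b in ((t1, t2), (t2, t1)):
        rec = pd.DataFrame({"family_id": a.index, "zygosity": a["zygosity"].to_numpy()})
        for c in value_cols:
            rec[f"{c}_self"] = a[c].to_numpy()
            rec[f"{c}_cotwin"] = b[c].to_numpy()
        recs.append(rec)
    return pd.concat(recs, ignore_index=True)
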