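"""Synthetic twin-cohort generator.

Generates wide-format twin cohorts with the covariance structure assumed by the
classical twin design: additive-genetic factors (A) correlated 1.0 within
monozygotic (MZ) pairs and 0.5 within dizygotic (DZ) pairs, shared-environment
factors (C) correlated 1.0 within any pair, and nonshared-environment factors
(E) uncorrelated between co-twins.  Each factor carries its own cross-wave
correlation matrix, so longitudinal stability of genetic and environmental
influences is controlled independently of per-wave variance proportions.

Latent factors are drawn jointly per family from the Kronecker covariance
(pair-relatedness ⊗ cross-wave correlation), which guarantees the exact
within/between-twin covariance by construction.  The phenotype for measure m,
twin t, wave w is

    y = sqrt(a2_w)·A + sqrt(c2_w)·C + sqrt(e2_w)·E + shift_w ± sex_effect/2

so the population variance is 1 per measure-wave before any mean structure.

Generation-time truth (latent additive-genetic scores, latent class labels) is
kept in a sidecar table separate from the analysis-facing phenotype table, so
recovery tests cannot leak it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SimulationConfig",
    "TwinCohort",
    "simulate_cohort",
    "apply_attrition",
    "inject_profiles",
    "simulate_gps",
    "simulate_extremes_sample",
    "pheno_col",
    "compound_symmetric",
]

#: Default per-wave variance proportions: study-average a2/c2/e2.
DEFAULT_ACE = (0.33, 0.07, 0.60)
#: Default cross-wave factor correlations (study averages: genetic effects
#: nearly perfectly stable, nonshared environment moderately stable).
DEFAULT_RA = 0.95
DEFAULT_RC = 0.90
DEFAULT_RE = 0.41


def pheno_col(measure: str, wave: int) -> str:
    """Column name for a measure at a 1-based wave: ``anxiety_t2``."""
    return f"{measure}_t{wave}"


def compound_symmetric(n: int, rho: float) -> np.ndarray:
    """n x n correlation matrix with constant off-diagonal rho."""
    m = np.full((n, n), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


def _check_corr(name: str, m: np.ndarray, n: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"{name}: expected {n}x{n} matrix, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name}: correlation matrix is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError(f"{name}: correlation matrix diagonal must be 1")
    evals = np.linalg.eigvalsh(m)
    if evals.min() < -1e-10:
        raise ValueError(
            f"{name}: correlation matrix is not positive semi-definite "
            f"(min eigenvalue {evals.min():.3g})"
        )
    return m


@dataclass
class SimulationConfig:
    """Parameters of a synthetic twin cohort.

    Variance proportions, factor-correlation matrices and mean structure may be
    given once (applied to every measure) or as a mapping keyed by measure name.
    All phenotypes are on a standardized scale: shifts and sex effects are in
    baseline-s.d. units.
    """

    n_mz_pairs: int = 1501
    n_dz_pairs: int = 2380
    n_waves: int = 5
    measures: Sequence[str] = ("symptom",)
    ace_components: object = DEFAULT_ACE  # (a2,c2,e2) | (waves,3) array | {measure: ...}
    corr_A: object = None  # (w,w) matrix | {measure: matrix}; default CS(0.95)
    corr_C: object = None  # default CS(0.90)
    corr_E: object = None  # default CS(0.41)
    wave_mean_shifts: object = None  # per-wave vector | {measure: vector}; default 0
    sex_effect: object = 0.0  # male-minus-female mean difference, s.d. units
    age_range: tuple = (22.0, 26.0)
    profile_spec: Sequence[tuple] | None = None  # [(proportion, offsets per wave)]
    attrition: Mapping | None = None  # {"retention": [..], "mechanism": "MCAR"|"MAR", "mar_slope": f}
    gps_spec: Sequence[tuple] | None = None  # [(name, corr with baseline A)]
    skew: float = 0.0  # exponential-transform skew; 0 = untransformed (default)
    seed: int = 0

    # -- normalized views -------------------------------------------------

    def _per_measure(self, value, default):
        if isinstance(value, Mapping):
            return {m: value.get(m, default) for m in self.measures}
        if value is None:
            value = default
        return {m: value for m in self.measures}

    def ace_array(self, measure: str) -> np.ndarray:
        """(n_waves, 3) array of (a2, c2, e2) for one measure."""
        spec = self._per_measure(self.ace_components, DEFAULT_ACE)[measure]
        arr = np.asarray(spec, dtype=float)
        if arr.ndim == 1:
            arr = np.tile(arr, (self.n_waves, 1))
        if arr.shape != (self.n_waves, 3):
            raise ValueError(
                f"ace_components[{measure}]: expected shape ({self.n_waves}, 3)"
            )
        if np.any(arr < 0):
            raise ValueError(f"ace_components[{measure}]: negative proportion")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError(
                f"ace_components[{measure}]: a2+c2+e2 must sum to 1 per wave"
            )
        return arr

    def corr_matrix(self, which: str, measure: str) -> np.ndarray:
        defaults = {
            "corr_A": compound_symmetric(self.n_waves, DEFAULT_RA),
            "corr_C": compound_symmetric(self.n_waves, DEFAULT_RC),
            "corr_E": compound_symmetric(self.n_waves, DEFAULT_RE),
        }
        raw = self._per_measure(getattr(self, which), defaults[which])[measure]
        return _check_corr(f"{which}[{measure}]", np.asarray(raw), self.n_waves)

    def shifts(self, measure: str) -> np.ndarray:
        v = self._per_measure(self.wave_mean_shifts, np.zeros(self.n_waves))[measure]
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n_waves,):
            raise ValueError(f"wave_mean_shifts[{measure}]: expected {self.n_waves} values")
        return v

    def sex_effects(self, measure: str) -> float:
        return float(self._per_measure(self.sex_effect, 0.0)[measure])

    def validate(self) -> "SimulationConfig":
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be non-negative")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        for m in self.measures:
            self.ace_array(m)
            for which in ("corr_A", "corr_C", "corr_E"):
                self.corr_matrix(which, m)
            self.shifts(m)
        if self.profile_spec is not None:
            props = np.array([p for p, _ in self.profile_spec], dtype=float)
            if not np.isclose(props.sum(), 1.0, atol=1e-8):
                raise ValueError("profile mixing proportions must sum to 1")
            for _, off in self.profile_spec:
                if len(np.atleast_1d(off)) != self.n_waves:
                    raise ValueError(
                        f"profile offset vector length must equal n_waves={self.n_waves}"
                    )
        if self.attrition is not None:
            ret = np.asarray(self.attrition["retention"], dtype=float)
            if np.any(ret <= 0) or np.any(ret > 1):
                raise ValueError("retention probabilities must lie in (0, 1]")
        if self.gps_spec is not None:
            for name, rho in self.gps_spec:
                if abs(rho) >= 1:
                    raise ValueError(f"gps_spec[{name}]: |correlation| must be < 1")
        return self


@dataclass
class TwinCohort:
    """Wide per-individual twin table plus a generation-truth sidecar.

    ``data`` has one row per individual, keyed by (family_id, twin) with
    zygosity (MZ/DZ), sex (F/M), age, phenotype columns ``<measure>_t<wave>``
    and optional ``gps_<name>`` columns; missing cells are NaN.  ``truth``
    (never written to the analysis CSV) carries latent additive-genetic scores
    and latent class labels.
    """

    data: pd.DataFrame
    truth: pd.DataFrame
    measures: tuple
    n_waves: int

    def pheno_cols(self, measure: str) -> list[str]:
        return [pheno_col(measure, w) for w in range(1, self.n_waves + 1)]

    def copy(self) -> "TwinCohort":
        return TwinCohort(self.data.copy(), self.truth.copy(),
                          tuple(self.measures), self.n_waves)

    def validate_structure(self) -> None:
        """Structural invariants: 2 rows per family, MZ same sex, one zygosity."""
        sizes = self.data.groupby("family_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValueError(f"families without exactly 2 rows: {list(bad.index[:5])}")
        zyg = self.data.groupby("family_id")["zygosity"].nunique()
        if (zyg > 1).any():
            raise ValueError("family with two zygosities")
        mz = self.data[self.data.zygosity == "MZ"]
        nsex = mz.groupby("family_id")["sex"].nunique()
        if (nsex > 1).any():
            raise ValueError("MZ co-twins with different sex")


def _draw_factor(rng: np.random.Generator, n_fam: int, pair_r: float,
                 wave_corr: np.ndarray) -> np.ndarray:
    """Draw (n_fam, 2, n_waves) latent factors with cov = pair ⊗ wave_corr."""
    w = wave_corr.shape[0]
    pair = np.array([[1.0, pair_r], [pair_r, 1.0]])
    cov = np.kron(pair, wave_corr)
    # eigendecomposition: wave_corr may be singular (e.g. all-unit correlations)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.where(evals < 1e-12 * evals.max(), 0.0, evals)  # exact rank deficiency
    root = evecs @ np.diag(np.sqrt(evals))
    z = rng.standard_normal((n_fam, 2 * w)) @ root.T
    return z.reshape(n_fam, 2, w)


def simulate_cohort(config: SimulationConfig) -> TwinCohort:
    """Generate a twin cohort from the configured variance structure.

    Each family draws A (pair correlation 1.0 MZ / 0.5 DZ), C (1.0) and E (0.0)
    factor vectors across waves, combines them with per-wave path weights
    sqrt(a2), sqrt(c2), sqrt(e2), and adds mean structure (wave shifts, sex
    effect).  Profiles, attrition and GPS columns configured on the config are
    applied in that order.  Fully reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_mz, n_dz, w = config.n_mz_pairs, config.n_dz_pairs, config.n_waves
    n_fam = n_mz + n_dz

    fam = np.arange(1, n_fam + 1)
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz)

    # sex: MZ same-sex; DZ same-sex with probability 0.5
    sex1 = rng.integers(0, 2, n_fam)  # 0=F, 1=M
    sex2 = sex1.copy()
    dz = zyg == "DZ"
    flip = rng.random(n_fam) < 0.5
    sex2[dz & flip] = 1 - sex2[dz & flip]
    age = rng.uniform(config.age_range[0], config.age_range[1], n_fam)

    rows = {
        "family_id": np.repeat(fam, 2),
        "twin": np.tile([1, 2], n_fam),
        "zygosity": np.repeat(zyg, 2),
        "sex": np.where(np.stack([sex1, sex2], axis=1).reshape(-1) == 1, "M", "F"),
        "age": np.repeat(np.round(age, 2), 2),
    }
    truth = {
        "family_id": rows["family_id"].copy(),
        "twin": rows["twin"].copy(),
    }

    sex_num = np.stack([sex1, sex2], axis=1).astype(float)  # (n_fam, 2)

    for m in config.measures:
        ace = config.ace_array(m)
        a_path = np.sqrt(ace[:, 0])
        c_path = np.sqrt(ace[:, 1])
        e_path = np.sqrt(ace[:, 2])
        shifts = config.shifts(m)
        sexeff = config.sex_effects(m)

        A = np.empty((n_fam, 2, w))
        C = np.empty((n_fam, 2, w))
        E = np.empty((n_fam, 2, w))
        for grp, pr in (("MZ", 1.0), ("DZ", 0.5)):
            idx = zyg == grp
            n_g = int(idx.sum())
            A[idx] = _draw_factor(rng, n_g, pr, config.corr_matrix("corr_A", m))
            C[idx] = _draw_factor(rng, n_g, 1.0, config.corr_matrix("corr_C", m))
            E[idx] = _draw_factor(rng, n_g, 0.0, config.corr_matrix("corr_E", m))

        y = a_path * A + c_path * C + e_path * E
        y += shifts
        y += sexeff * (sex_num[:, :, None] - 0.5)
        if config.skew:
            # optional positive-skew transform, off by default
            y = (np.exp(config.skew * y) - 1.0) / config.skew

        for wave in range(1, w + 1):
            rows[pheno_col(m, wave)] = y[:, :, wave - 1].reshape(-1)
        truth[f"A_{m}_t1"] = A[:, :, 0].reshape(-1)

    cohort = TwinCohort(pd.DataFrame(rows), pd.DataFrame(truth),
                        tuple(config.measures), w)
    if config.profile_spec is not None:
        cohort = inject_profiles(cohort, config, _rng=rng)
    if config.attrition is not None:
        cohort = apply_attrition(cohort, config, _rng=rng)
    if config.gps_spec is not None:
        cohort = simulate_gps(cohort, config, _rng=rng)
    return cohort


def inject_profiles(cohort: TwinCohort, config: SimulationConfig,
                    _rng: np.random.Generator | None = None) -> TwinCohort:
    """Assign latent trajectory classes and add their mean-offset vectors.

    Each individual independently draws one class from the configured mixing
    proportions; the class offset (per wave, s.d. units) is added to every
    measure's trajectory.  Class labels go to the truth sidecar only.
    """
    if config.profile_spec is None:
        raise ValueError("config.profile_spec is not set")
    config.validate()
    rng = _rng if _rng is not None else np.random.default_rng(config.seed + 1)
    out = cohort.copy()
    props = np.array([p for p, _ in config.profile_spec], dtype=float)
    offsets = np.array([np.atleast_1d(o) for _, o in config.profile_spec], dtype=float)
    n = len(out.data)
    labels = rng.choice(len(props), size=n, p=props)
    for m in out.measures:
        cols = out.pheno_cols(m)
        out.data[cols] = out.data[cols].to_numpy() + offsets[labels]
    out.truth["profile_class"] = labels
    return out


def apply_attrition(cohort: TwinCohort, config: SimulationConfig,
                    _rng: np.random.Generator | None = None) -> TwinCohort:
    """Blank post-baseline waves per individual with the configured retention.

    MCAR drops each individual-wave independently; MAR-on-baseline lowers the
    retention odds with the individual's mean baseline phenotype
    (logit p = logit(retention) − mar_slope · baseline z), so high scorers drop
    out more.  Wave 1 is never deleted.
    """
    if config.attrition is None:
        raise ValueError("config.attrition is not set")
    config.validate()
    rng = _rng if _rng is not None else np.random.default_rng(config.seed + 2)
    spec = config.attrition
    retention = np.asarray(spec["retention"], dtype=float)
    if len(retention) != config.n_waves:
        raise ValueError("retention must list one probability per wave")
    mechanism = spec.get("mechanism", "MCAR").upper()
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError(f"unknown attrition mechanism {mechanism!r}")
    out = cohort.copy()
    n = len(out.data)
    base = np.nanmean(
        np.column_stack([out.data[pheno_col(m, 1)] for m in out.measures]), axis=1
    )
    base_z = (base - np.nanmean(base)) / np.nanstd(base)
    for wave in range(2, config.n_waves + 1):
        p = retention[wave - 1]
        if p >= 1.0:
            continue
        if mechanism == "MCAR":
            keep_p = np.full(n, p)
        else:
            slope = float(spec.get("mar_slope", 0.5))
            keep_p = expit(logit(p) - slope * base_z)
        drop = rng.random(n) >= keep_p
        for m in out.measures:
            out.data.loc[drop, pheno_col(m, wave)] = np.nan
    return out


def simulate_gps(cohort: TwinCohort, config: SimulationConfig,
                 _rng: np.random.Generator | None = None) -> TwinCohort:
    """Add polygenic-score columns with twin-consistent structure.

    GPS = rho·A1 + sqrt(1−rho²)·G, where A1 is the standardized baseline
    additive-genetic factor of the first measure and G an independent
    genetic-type factor (pair correlation 1.0 MZ / 0.5 DZ).  Scores are thus
    identical within MZ pairs, correlated 0.5 between DZ co-twins, and
    correlated rho with the baseline genetic factor.
    """
    if config.gps_spec is None:
        raise ValueError("config.gps_spec is not set")
    config.validate()
    rng = _rng if _rng is not None else np.random.default_rng(config.seed + 3)
    out = cohort.copy()
    a1 = out.truth[f"A_{out.measures[0]}_t1"].to_numpy().reshape(-1, 2)
    zyg = out.data["zygosity"].to_numpy()[::2]
    n_fam = a1.shape[0]
    one = np.ones((1, 1))
    for name, rho in config.gps_spec:
        g = np.empty((n_fam, 2))
        for grp, pr in (("MZ", 1.0), ("DZ", 0.5)):
            idx = zyg == grp
            g[idx] = _draw_factor(rng, int(idx.sum()), pr, one)[:, :, 0]
        score = rho * a1 + np.sqrt(1 - rho**2) * g
        out.data[f"gps_{name}"] = score.reshape(-1)
    return out


def simulate_extremes_sample(n: int = 4000, n_measures: int = 8,
                             n_waves: int = 5, loading: float = 0.6,
                             target_gaps=(0.47, 0.1, 0.1, 0.1),
                             threshold_sd: float = 1.0,
                             seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Unrelated-individuals sample for the extreme-groups analysis.

    A latent baseline liability factor p ~ N(0,1) drives ``n_measures``
    baseline measures (x = loading·p + noise); each post-baseline wave w
    carries a calibrated dependence delta_w on p such that the expected
    standardized high-vs-low gap (groups = ±threshold s.d. tails of the
    baseline first principal component) equals ``target_gaps[w-2]`` at that
    wave.

    The calibration is closed-form from truncated-normal moments: with
    h = 2·phi(t)/(1−Phi(t)) the mean separation of the two tails,
    v = Var(Z | Z > t) the within-tail variance, and r the correlation of the
    component score with p, the gap for y = delta·p + sqrt(1−delta²)·e is
    d = delta·r·h / sqrt(1 − (1−v)·r²·delta²), inverted for delta.

    Returns (wide DataFrame with columns ``m<j>_t<w>``, latent p per row).
    """
    if len(target_gaps) != n_waves - 1:
        raise ValueError("target_gaps must give one gap per post-baseline wave")
    rng = np.random.default_rng(seed)
    from scipy.stats import norm

    t = threshold_sd
    h = 2.0 * norm.pdf(t) / norm.sf(t)          # E[Z|Z>t] − E[Z|Z<−t]
    v = 1.0 + t * norm.pdf(t) / norm.sf(t) - (norm.pdf(t) / norm.sf(t)) ** 2
    # corr(PC1, p) for m equally loaded indicators (PC1 = equal weights)
    r = loading / np.sqrt(loading**2 + (1.0 - loading**2) / n_measures)

    p = rng.standard_normal(n)
    cols = {}
    for j in range(1, n_measures + 1):
        x = loading * p + np.sqrt(1 - loading**2) * rng.standard_normal(n)
        cols[pheno_col(f"m{j}", 1)] = x
        for w, d_target in zip(range(2, n_waves + 1), target_gaps):
            delta = d_target / (r * np.sqrt(h**2 + d_target**2 * (1.0 - v)))
            y = delta * p + np.sqrt(1 - delta**2) * rng.standard_normal(n)
            cols[pheno_col(f"m{j}", w)] = y
    return pd.DataFrame(cols), p
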