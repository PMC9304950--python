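"""Cohort CSV dialect, YAML configuration, and pipeline orchestration.

The on-disk cohort format is a single wide CSV: one row per individual with
columns ``family_id, twin, zygosity, sex, age, <measure>_t<wave>...`` plus
optional ``gps_<name>`` and covariate columns; missing values are empty cells.
The generation-truth sidecar is written as a separate CSV and never read by
any analysis stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, effects, growth, preprocess, profiles, twin
from .simulate import SimulationConfig, TwinCohort, pheno_col, simulate_cohort

__all__ = [
    "read_cohort", "write_cohort", "read_sim_config", "config_hash",
    "RunConfig", "run_pipeline", "write_json",
]

log = logging.getLogger(__name__)

_PHENO_RE = re.compile(r"^(?P<measure>[A-Za-z]\w*?)_t(?P<wave>\d+)$")
_META_COLS = ("family_id", "twin", "zygosity", "sex", "age")

PIPELINE_STAGES = ("simulate", "preprocess", "describe", "ace", "rg",
                   "cholesky", "lpa", "lgc", "extremes")


def write_cohort(cohort: TwinCohort, path, truth_path=None) -> None:
    cohort.data.to_csv(path, index=False, na_rep="")
    if truth_path is not None:
        cohort.truth.to_csv(truth_path, index=False, na_rep="")


def read_cohort(path) -> TwinCohort:
    """Read and validate the wide cohort CSV.

    Hard errors (listing offending family ids / line numbers): duplicate
    (family_id, twin) keys, families without exactly two rows, MZ co-twins
    with different sex, unknown zygosity codes.
    """
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    errors = []
    bad_zyg = df[~df.zygosity.isin(["MZ", "DZ"])]
    if len(bad_zyg):
        errors.append(
            f"unknown zygosity codes at CSV lines "
            f"{(bad_zyg.index + 2).tolist()[:10]}")
    dup = df.duplicated(subset=["family_id", "twin"], keep=False)
    if dup.any():
        errors.append(
            f"duplicate (family_id, twin) keys: "
            f"{sorted(df.loc[dup, 'family_id'].unique())[:10]}")
    sizes = df.groupby("family_id").size()
    odd = sizes[sizes != 2]
    if len(odd):
        errors.append(
            f"families without exactly 2 rows: {list(odd.index[:10])}")
    mz = df[df.zygosity == "MZ"]
    if len(mz):
        nsex = mz.groupby("family_id")["sex"].nunique()
        mism = nsex[nsex > 1]
        if len(mism):
            errors.append(f"MZ pairs with sex mismatch: {list(mism.index[:10])}")
    if errors:
        raise ValueError("invalid cohort CSV: " + "; ".join(errors))

    measures, max_wave = [], 0
    for c in df.columns:
        m = _PHENO_RE.match(c)
        if m and not c.startswith("gps_"):
            name = m.group("measure")
            if name not in measures:
                measures.append(name)
            max_wave = max(max_wave, int(m.group("wave")))
    if not measures:
        raise ValueError("no phenotype columns (<measure>_t<wave>) found")
    truth = df[["family_id", "twin"]].copy()
    return TwinCohort(df, truth, tuple(measures), max_wave)


def read_sim_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a plain-text YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "profile_spec" in raw and raw["profile_spec"] is not None:
        raw["profile_spec"] = [tuple(x) for x in raw["profile_spec"]]
    if "gps_spec" in raw and raw["gps_spec"] is not None:
        raw["gps_spec"] = [tuple(x) for x in raw["gps_spec"]]
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, pd.DataFrame):
        return _jsonable(x.to_dict(orient="records"))
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=False))


@dataclass
class RunConfig:
    """End-to-end pipeline run: simulate (or load) then analyze."""

    simulation: SimulationConfig | None = None
    input_path: str | None = None
    stages: tuple = PIPELINE_STAGES
    seed: int = 0
    out_dir: str = "twinwaves_out"
    log_level: str = "INFO"
    measure: str | None = None          # analysis measure; default first
    rg_waves: tuple = (1, 2)
    lpa_k: tuple = (1, 2, 3)

    def validate(self):
        unknown = [s for s in self.stages if s not in PIPELINE_STAGES]
        if unknown:
            raise ValueError(f"unknown pipeline stages: {unknown}")
        if self.simulation is None and self.input_path is None:
            raise ValueError("either a simulation config or an input path is required")
        return self


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in order, writing per-stage artifacts.

    Every stage's result lands in ``summary`` and in ``<out_dir>/summary.json``;
    a stage failure is recorded and its dependent stages are skipped.  The run
    log records the seed and a configuration hash.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config_hash({
            "sim": (None if config.simulation is None
                    else {**vars(config.simulation), "seed": config.seed}),
            "stages": list(config.stages), "seed": config.seed}),
        "stages": {}, "errors": {},
    }
    log.info("pipeline start: seed=%d hash=%s", config.seed, summary["config_hash"])

    def run_stage(name, fn, *deps):
        if name not in config.stages:
            return None
        if any(d in summary["errors"] for d in deps):
            summary["errors"][name] = "skipped: upstream failure"
            return None
        try:
            res = fn()
            summary["stages"][name] = "ok"
            return res
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            log.exception("stage %s failed", name)
            summary["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None

    # --- data ---------------------------------------------------------
    if config.simulation is not None:
        cfg = config.simulation
        cfg.seed = config.seed
        cohort = run_stage("simulate", lambda: simulate_cohort(cfg))
        if cohort is not None:
            write_cohort(cohort, out / "cohort.csv", out / "cohort_truth.csv")
    else:
        cohort = run_stage("simulate", lambda: read_cohort(config.input_path))
    if cohort is None:
        summary["exit_code"] = 2
        write_json(summary, out / "summary.json")
        return summary

    measure = config.measure or cohort.measures[0]
    resid = run_stage("preprocess",
                      lambda: preprocess.residualize(cohort), "simulate")
    analysis = resid if resid is not None else cohort

    def _describe():
        tab = effects.describe_effects(cohort)
        tab.summary.to_csv(out / "descriptives.csv", index=False)
        tab.d.to_csv(out / "cohens_d.csv", index=False)
        Y = analysis.data[[pheno_col(measure, w)
                           for w in range(1, cohort.n_waves + 1)]].to_numpy()
        corr = effects.crosswave_correlations(Y)
        return {"mean_crosswave_r": corr.mean_offdiag(),
                "d_t1_t2": tab.d.query("wave_a==1 & wave_b==2")
                              .set_index("measure").cohens_d.to_dict()}
    summary["describe"] = run_stage("describe", _describe, "simulate")

    def _ace():
        rows = []
        for w in range(1, cohort.n_waves + 1):
            r = twin.fit_univariate_ace(analysis, measure, w, seed=config.seed)
            rows.append({"wave": w, "a2": r.a2, "c2": r.c2, "e2": r.e2,
                         "converged": r.converged})
        pd.DataFrame(rows).to_csv(out / "ace.csv", index=False)
        return rows
    summary["ace"] = run_stage("ace", _ace, "preprocess")

    def _rg():
        r = twin.fit_correlated_factors(analysis, measure, config.rg_waves,
                                        seed=config.seed)
        return {"rG": r.rG, "rC": r.rC, "rE": r.rE,
                "per_wave": r.per_wave, "converged": r.converged}
    summary["rg"] = run_stage("rg", _rg, "preprocess")

    def _chol():
        r = twin.fit_cholesky(analysis, measure, config.rg_waves,
                              seed=config.seed)
        return {"innovation": r.innovation, "converged": r.converged}
    summary["cholesky"] = run_stage("cholesky", _chol, "preprocess")

    def _lpa():
        cols = [pheno_col(measure, w) for w in range(1, cohort.n_waves + 1)]
        Y = analysis.data[cols].to_numpy(dtype=float)
        Y = Y[~np.isnan(Y).all(axis=1)]
        comp = profiles.impute_single(Y, seed=config.seed)
        fits = [profiles.fit_lpa(comp, k, seed=config.seed)
                for k in config.lpa_k]
        best, tab = profiles.select_k(fits)
        tab.to_csv(out / "lpa_fit.csv", index=False)
        return {"best_k": best.k, "mixing": best.mixing,
                "means": best.means, "fit_table": tab}
    summary["lpa"] = run_stage("lpa", _lpa, "preprocess")

    def _lgc():
        cols = [pheno_col(measure, w) for w in range(1, cohort.n_waves + 1)]
        Y = analysis.data[cols].to_numpy(dtype=float)
        Y = Y[~np.isnan(Y).all(axis=1)]
        tab = growth.compare_growth(Y, seed=config.seed)
        return {"table": tab, "preferred_bic": tab.attrs["preferred_bic"],
                "lrt": tab.attrs["lrt"]}
    summary["lgc"] = run_stage("lgc", _lgc, "preprocess")

    def _extremes():
        if len(cohort.measures) < 2:
            return {"skipped": "needs >= 2 measures"}
        unrel = preprocess.select_one_per_pair(analysis, seed=config.seed)
        res = association.extremes_analysis(unrel, cohort.measures,
                                            cohort.n_waves)
        return {"mean_d_per_wave": res["mean_d_per_wave"],
                "explained_variance": res["p_factor"].explained_variance}
    summary["extremes"] = run_stage("extremes", _extremes, "preprocess")

    summary["exit_code"] = 0 if not summary["errors"] else (
        3 if any("converge" in str(v) for v in summary["errors"].values()) else 2)
    write_json(summary, out / "summary.json")
    return summary
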