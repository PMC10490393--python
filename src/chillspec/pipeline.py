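"""End-to-end pipeline: simulate -> derive indicators -> score -> spectral
features -> inversion, as one reproducible, config-hashed run.

Every artifact written by a run embeds the run's config hash (JSON field, or
a ``# config_hash=...`` comment line on CSVs); loaders reject artifacts from
a different run when given an expected hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import synthetic_cohort as sc
from .cspc_scoring import CSPCModel, fit_cspc
from .fluorescence import derive_fluorescence_params
from .inversion import MODEL_KINDS, SplitSpec, run_inversion
from .photosynthesis import ci_ca_ratio, fit_light_response, water_use_efficiency
from .sif_retrieval import DEFAULT_O2A, DEFAULT_O2B, retrieve_both_bands
from .spectral_features import (FeatureIndex, evaluate_schemes, feature_table,
                                select_feature_set)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "derive_indicator_table",
           "config_hash", "write_csv_artifact", "read_csv_artifact",
           "ArtifactMismatchError"]

logger = logging.getLogger("chillspec")


class ArtifactMismatchError(RuntimeError):
    """An artifact's embedded config hash does not match the active run."""


@dataclass
class RunConfig:
    out_dir: str = "chillspec_run"
    n_replicates: int = 18
    noise_scale: float = 0.5
    seed: int = 0
    variance_threshold: float = 0.85
    fixed_grade_width: float | None = None
    feature_threshold: float = 0.5
    model_kinds: Sequence[str] = MODEL_KINDS
    n_valid: int | None = None  # default: cohort-size-scaled 80/432

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
            "variance_threshold": self.variance_threshold,
            "fixed_grade_width": self.fixed_grade_width,
            "feature_threshold": self.feature_threshold,
            "model_kinds": list(self.model_kinds),
            "n_valid": self.n_valid,
        }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_csv_artifact(df: pd.DataFrame, path: Path, chash: str,
                       index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=index)


def read_csv_artifact(path: Path, expected_hash: str | None = None,
                      **kwargs) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        found = first.strip().split("=", 1)[1]
        if expected_hash is not None and found != expected_hash:
            raise ArtifactMismatchError(
                f"{path} was written by run {found}, expected {expected_hash}")
        return pd.read_csv(path, comment="#", **kwargs)
    if expected_hash is not None:
        raise ArtifactMismatchError(f"{path} carries no config hash")
    return pd.read_csv(path, **kwargs)


# ---------------------------------------------------------------------------
# Indicator derivation
# ---------------------------------------------------------------------------

def derive_indicator_table(records: List[sc.PlantRecord]) -> pd.DataFrame:
    """Derive the 20-indicator table from raw cohort measurements.

    Columns: light-response and gas-exchange indicators (Amax, LCP, LSP,
    AQE, gs, E, ci/ca, WUE), the PAM quenching set, and the four SIF
    retrievals; index = record ids.
    """
    rows = []
    for rec in records:
        fit = fit_light_response(rec.light_response)
        fl = derive_fluorescence_params(rec.pam)
        sif = retrieve_both_bands(rec.sif_spectra, (DEFAULT_O2B, DEFAULT_O2A))
        g = rec.gas_exchange
        rows.append({
            "record_id": rec.label.record_id,
            "Amax": fit.Amax, "LCP": fit.LCP, "LSP": fit.LSP, "AQE": fit.AQE,
            "gs": g.gs, "E": g.E,
            "ci_ca": ci_ca_ratio(g.ci, g.ca),
            "WUE": water_use_efficiency(g.A, g.E),
            "FvFm": fl.FvFm, "FvpFmp": fl.FvpFmp,
            "one_minus_qP": fl.one_minus_qP, "qL": fl.qL, "qN": fl.qN,
            "YII": fl.YII, "YNPQ": fl.YNPQ, "YNO": fl.YNO,
            "SIF_O2B": sif.F_O2B, "SIF_O2A": sif.F_O2A,
            "rSIF_O2B": sif.rSIF_O2B, "rSIF_O2A": sif.rSIF_O2A,
        })
    return pd.DataFrame(rows).set_index("record_id")


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config: RunConfig
    config_hash: str
    n_records: int
    selected_features: List[dict]
    retained_components: int
    grading_width: float
    validation: dict
    stage_seconds: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "n_records": self.n_records,
            "selected_features": self.selected_features,
            "retained_components": self.retained_components,
            "grading_width": self.grading_width,
            "validation": self.validation,
            "stage_seconds": self.stage_seconds,
        }


def _feature_manifest(features: Sequence[FeatureIndex]) -> List[dict]:
    return [{
        "scheme": f.scheme_id, "form": f.form,
        "Ba_nm": list(f.Ba_wavelength), "Bb_nm": list(f.Bb_wavelength),
        "r_with_cspc": f.r_with_cspc,
    } for f in features]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages on one synthetic cohort and write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    timings: Dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t0 = stage("simulate")
    cohort_cfg = sc.CohortConfig(n_replicates=config.n_replicates,
                                 seed=config.seed,
                                 noise_scale=config.noise_scale)
    records = sc.make_cohort(cohort_cfg)
    sc.write_cohort(records, out / "cohort", cohort_cfg)
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulated %d records", len(records))

    t0 = stage("derive")
    indicators = derive_indicator_table(records)
    write_csv_artifact(indicators, out / "indicators.csv", chash, index=True)
    timings["derive"] = time.perf_counter() - t0

    t0 = stage("score")
    model, cspc_result = fit_cspc(indicators,
                                  variance_threshold=config.variance_threshold,
                                  fixed_width=config.fixed_grade_width)
    write_csv_artifact(cspc_result, out / "cspc.csv", chash, index=True)
    _write_scoring_json(out, model, chash)
    timings["score"] = time.perf_counter() - t0

    t0 = stage("features")
    wl = records[0].reflectance.wavelength
    R = np.vstack([r.reflectance.reflectance for r in records])
    cspc = cspc_result["CSPC"].to_numpy()
    schemes = evaluate_schemes(wl, R, cspc)
    selected = select_feature_set(schemes, threshold=config.feature_threshold)
    feats = feature_table(selected, index=indicators.index)
    write_csv_artifact(feats, out / "features.csv", chash, index=True)
    (out / "feature_manifest.json").write_text(json.dumps(
        {"config_hash": chash, "features": _feature_manifest(selected)},
        indent=1))
    corr_rows = []
    for s in schemes:
        for w, rv in zip(wl, s.r):
            corr_rows.append((s.scheme_id, w, rv))
    write_csv_artifact(
        pd.DataFrame(corr_rows, columns=["scheme", "wavelength_nm", "r"]),
        out / "correlograms.csv", chash)
    timings["features"] = time.perf_counter() - t0

    t0 = stage("invert")
    n = len(records)
    n_valid = config.n_valid or max(1, round(n * 80 / 432))
    split_spec = SplitSpec(n_train=n - n_valid, n_valid=n_valid,
                           seed=config.seed)
    report = run_inversion(feats.to_numpy(), cspc, model.scheme,
                           split_spec=split_spec, kinds=config.model_kinds,
                           seed=config.seed)
    (out / "validation_report.json").write_text(json.dumps(
        {"config_hash": chash, **report.to_dict()}, indent=1))
    timings["invert"] = time.perf_counter() - t0

    run_report = RunReport(config=config, config_hash=chash,
                           n_records=len(records),
                           selected_features=_feature_manifest(selected),
                           retained_components=model.retained,
                           grading_width=model.scheme.width,
                           validation=report.to_dict(),
                           stage_seconds=timings)
    (out / "run_report.json").write_text(json.dumps(run_report.to_dict(),
                                                    indent=1))
    return run_report


def _write_scoring_json(out: Path, model: CSPCModel, chash: str) -> None:
    families = {
        fam: {
            "eigenvalues": res.eigenvalues.tolist(),
            "contribution_pct": res.contribution_pct.tolist(),
            "loadings": {c: res.loadings[c].to_dict()
                         for c in res.loadings.columns},
        } for fam, res in model.family_results.items()
    }
    (out / "pca_families.json").write_text(json.dumps(
        {"config_hash": chash, "families": families,
         "selected": model.feature_set.names,
         "composite": {
             "eigenvalues": model.composite.eigenvalues.tolist(),
             "contribution_pct": model.composite.contribution_pct.tolist(),
             "retained": model.retained,
             "weights": model.weights.tolist(),
         },
         "standardization": {
             "convention": model.standardize_params.convention,
             "means": model.standardize_params.means.to_dict(),
             "sds": model.standardize_params.sds.to_dict(),
         }}, indent=1))
    (out / "scheme.json").write_text(json.dumps(
        {"config_hash": chash, "center": model.scheme.center,
         "width": model.scheme.width, "n_levels": model.scheme.n_levels},
        indent=1))
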