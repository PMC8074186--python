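"""End-to-end orchestration: simulate -> calibrate -> validate/predict.

The calibration stage chains outlier screening, replicate averaging, the
spectral filter chain, CV-based selection of the orthogonal component count,
the final OPLS fit, and the full figures-of-merit block (linearity, RMSEE,
RMSECV, LOD/LOQ from blank predictions, precision RSDs from QC spectra,
recovery at spiked QC levels). Validation averages each sample's replicate
spectra, predicts, censors at the calibration LOD/LOQ and compares against
the reference table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, opls
from .dataset import (
    SpectraSet,
    WavelengthGrid,
    make_reference_table,
    reference_from_csv,
    reference_to_csv,
    reference_value,
)
from .merit import (
    FiguresOfMerit,
    ValidationReport,
    censor,
    lod_loq,
    method_comparison,
    precision_rsd,
    recovery,
    regression_line,
    rmse,
)
from .preprocess import (
    PreprocessConfig,
    apply_chain,
    collapse_repositions,
    hotelling_outliers,
)
from .simulate import (
    QC_RECOVERY_LEVELS,
    SimulationConfig,
    generate_blank_set,
    generate_calibration_set,
    generate_qc_set,
    generate_validation_set,
)

__all__ = [
    "RunConfig",
    "CalibrationResult",
    "calibrate",
    "validate",
    "predict_samples",
    "simulate_calibration_files",
    "simulate_validation_files",
    "write_manifest",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data (CLI exit code 3)."""


# -- run configuration --------------------------------------------------------

_KNOWN_SECTIONS = {"simulation", "preprocess", "model", "paths", "matrix_kind"}


@dataclass
class RunConfig:
    """Declarative run configuration (YAML): simulation, preprocessing, model."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    max_orth: int = 6
    folds: int = 7
    seed: int = 42
    matrix_kind: str = "raw"
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(blob) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls()
        sim = blob.get("simulation", {}) or {}
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - sim_fields
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        cfg.simulation = dataclasses.replace(
            SimulationConfig(),
            **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()},
        )
        pre = blob.get("preprocess", {}) or {}
        if set(pre) - {"steps"}:
            raise ValueError("preprocess section accepts only 'steps'")
        if "steps" in pre:
            cfg.preprocess = PreprocessConfig(steps=pre["steps"])
        model = blob.get("model", {}) or {}
        bad = set(model) - {"max_orth", "folds", "seed"}
        if bad:
            raise ValueError(f"unknown model keys: {sorted(bad)}")
        cfg.max_orth = int(model.get("max_orth", cfg.max_orth))
        cfg.folds = int(model.get("folds", cfg.folds))
        cfg.seed = int(model.get("seed", cfg.seed))
        paths = blob.get("paths", {}) or {}
        if set(paths) - {"out_dir"}:
            raise ValueError("paths section accepts only 'out_dir'")
        cfg.out_dir = paths.get("out_dir", cfg.out_dir)
        cfg.matrix_kind = blob.get("matrix_kind", cfg.matrix_kind)
        cfg.simulation.validate()
        cfg.preprocess.validate()
        return cfg


# -- calibration --------------------------------------------------------------


@dataclass
class CalibrationResult:
    model: opls.OPLSModel
    fom: FiguresOfMerit
    outliers: object
    cv_results: list
    n_spectra_kept: int


def _numeric_reference_map(reference: pd.DataFrame) -> dict:
    out = {}
    for row in reference.itertuples():
        value, marker = reference_value(row.histamine_mg_kg)
        if marker is not None:
            raise DataError(
                f"calibration reference for {row.sample_id} is censored ({marker})"
            )
        out[row.sample_id] = value
    return out


def calibrate(
    spectra: SpectraSet,
    reference: pd.DataFrame,
    preprocess: PreprocessConfig | None = None,
    max_orth: int = 6,
    folds: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Run the full calibration stage on a spectra set with design roles.

    Rows with role ``calibration`` build the model (spiking level as the
    response, blanks at level 0 included in the fit); role ``blank`` rows are
    predicted for the LOD/LOQ blank study only; role ``qc`` rows feed the
    precision (sample ids containing ``-QCP-``) and recovery (``-QCR-``)
    metrics.
    """
    preprocess = preprocess or PreprocessConfig()
    ref_map = _numeric_reference_map(reference)

    report = hotelling_outliers(spectra, alpha=alpha)
    keep = np.ones(len(spectra), dtype=bool)
    keep[report.flagged_index] = False
    kept = spectra.select(keep)
    if kept.meta["sample_id"].nunique() < spectra.meta["sample_id"].nunique():
        raise DataError("outlier screen removed every spectrum of some subsample")

    averaged = collapse_repositions(kept)
    processed = apply_chain(averaged, preprocess)
    meta = processed.meta

    cal_mask = (meta["role"] == "calibration").to_numpy()
    cal_ids = meta.loc[cal_mask, "sample_id"]
    missing = [sid for sid in cal_ids if sid not in ref_map]
    if missing:
        raise DataError(f"reference levels missing for: {missing[:5]}")
    y = np.array([ref_map[sid] for sid in cal_ids])
    if len(np.unique(y)) < 5:
        raise DataError("need calibration samples at >= 5 distinct levels")
    X = processed.absorbance[cal_mask]

    best, cv_results = select_components(X, y, max_orth, folds, seed)
    model = opls.fit(X, y, best)
    fitted = opls.predict(model, X)

    r2, slope, intercept = regression_line(y, fitted)
    n_components = 1 + best
    rmsee = rmse(y, fitted, kind="estimation", n_components=n_components)
    rmsecv = cv_results[best].rmsecv

    blank_mask = (meta["role"] == "blank").to_numpy()
    if blank_mask.sum() >= 3:
        blank_preds = opls.predict(model, processed.absorbance[blank_mask])
    else:
        # fall back to the level-0 calibration subsamples
        zero_mask = cal_mask & (np.isclose(meta["level_mg_kg"].to_numpy(float), 0.0))
        if zero_mask.sum() < 3:
            raise DataError("no blank-level subsamples available for LOD")
        blank_preds = opls.predict(model, processed.absorbance[zero_mask])
    lod, loq = lod_loq(blank_preds, slope)

    qc_mask = (meta["role"] == "qc").to_numpy()
    qcp = qc_mask & meta["sample_id"].str.contains("-QCP-").to_numpy()
    qcr = qc_mask & meta["sample_id"].str.contains("-QCR-").to_numpy()

    repeat_rsd = reprod_rsd = None
    if qcp.any():
        preds = opls.predict(model, processed.absorbance[qcp])
        days = meta.loc[qcp, "day"].to_numpy()
        day0 = preds[days == days.min()]
        if day0.size >= 2:
            repeat_rsd = precision_rsd(day0)
        if preds.size >= 2 and len(np.unique(days)) > 1:
            reprod_rsd = precision_rsd(preds)

    recoveries = {}
    if qcr.any():
        preds = opls.predict(model, processed.absorbance[qcr])
        levels = meta.loc[qcr, "level_mg_kg"].to_numpy(float)
        for level in sorted(set(levels)):
            if level > 0:
                recoveries[level] = recovery(float(preds[levels == level].mean()), level)

    fom = FiguresOfMerit(
        r2=r2,
        slope=slope,
        intercept=intercept,
        rmsee=rmsee,
        rmsecv=rmsecv,
        lod=lod,
        loq=loq,
        repeatability_rsd=repeat_rsd,
        reproducibility_rsd=reprod_rsd,
        recovery=recoveries,
        r2x=model.r2x,
        r2y=model.r2y,
        q2=cv_results[best].q2,
        n_orth=best,
    )
    model.metadata = {
        "matrix_kind": str(meta["matrix_kind"].iloc[0]),
        "grid": {
            "start_nm": spectra.grid.start_nm,
            "end_nm": spectra.grid.end_nm,
            "step_nm": spectra.grid.step_nm,
        },
        "preprocess": preprocess.steps,
        "lod_mg_kg": lod,
        "loq_mg_kg": loq,
        "slope": slope,
        "n_calibration_samples": int(cal_mask.sum()),
    }
    return CalibrationResult(model, fom, report, cv_results, int(keep.sum()))


def select_components(X, y, max_orth, folds, seed):
    return opls.select_components(X, y, max_orth, folds=folds, seed=seed)


# -- prediction and validation ------------------------------------------------


def _check_grid(model: opls.OPLSModel, grid: WavelengthGrid) -> None:
    spec = model.metadata.get("grid")
    if spec is None:
        return
    for key, actual in (
        ("start_nm", grid.start_nm),
        ("end_nm", grid.end_nm),
        ("step_nm", grid.step_nm),
    ):
        if spec[key] != actual:
            raise DataError(
                f"wavelength-grid mismatch: model {key}={spec[key]}, data {key}={actual}"
            )


def predict_samples(model: opls.OPLSModel, spectra: SpectraSet) -> pd.DataFrame:
    """One censored prediction per sample (replicates averaged first).

    Returns columns sample_id, prediction_mg_kg (full precision), reported
    (numeric or "<LOD"/"<LOQ" using the calibration-stage limits).
    """
    _check_grid(model, spectra.grid)
    averaged = collapse_repositions(spectra)
    chain = PreprocessConfig(steps=model.metadata.get("preprocess", []))
    processed = apply_chain(averaged, chain)
    preds = opls.predict(model, processed.absorbance)
    lod = model.metadata.get("lod_mg_kg")
    loq = model.metadata.get("loq_mg_kg")
    reported = [
        censor(p, lod, loq) if lod is not None else float(p) for p in preds
    ]
    return pd.DataFrame(
        {
            "sample_id": processed.meta["sample_id"],
            "prediction_mg_kg": preds,
            "reported": reported,
        }
    )


def validate(
    model: opls.OPLSModel, spectra: SpectraSet, reference: pd.DataFrame
) -> tuple[ValidationReport, pd.DataFrame]:
    """Predict a validation set and compare against the reference method."""
    preds = predict_samples(model, spectra)
    common = set(preds["sample_id"]) & set(reference["sample_id"])
    if not common:
        raise DataError("no sample ids in common between spectra and reference")
    nir_table = make_reference_table(
        preds["sample_id"], preds["prediction_mg_kg"], source="nir"
    )
    report = method_comparison(
        nir_table,
        reference,
        lod=model.metadata["lod_mg_kg"],
        loq=model.metadata["loq_mg_kg"],
    )
    return report, preds


# -- simulation entry points and manifests ------------------------------------


def simulate_calibration_files(
    matrix_kind: str, config: SimulationConfig, out_dir: str | Path
) -> dict:
    """Write the calibration spectra/reference CSVs (design + blanks + QC)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cal_s, cal_r = generate_calibration_set(matrix_kind, config)
    blk_s, blk_r = generate_blank_set(matrix_kind, config)
    qc_s, qc_r = generate_qc_set(matrix_kind, config)
    spectra = SpectraSet(
        cal_s.grid,
        np.vstack([cal_s.absorbance, blk_s.absorbance, qc_s.absorbance]),
        pd.concat([cal_s.meta, blk_s.meta, qc_s.meta], ignore_index=True),
    )
    reference = pd.concat([cal_r, blk_r, qc_r], ignore_index=True)
    spectra_path = out_dir / f"{matrix_kind}_calibration_spectra.csv"
    reference_path = out_dir / f"{matrix_kind}_calibration_reference.csv"
    spectra.to_csv(spectra_path)
    reference_to_csv(reference, reference_path)
    return {
        "spectra": str(spectra_path),
        "reference": str(reference_path),
        "n_subsamples": int(reference.shape[0]),
        "n_calibration_subsamples": int(cal_r.shape[0]),
        "n_spectra": len(spectra),
    }


def simulate_validation_files(
    matrix_kind: str,
    config: SimulationConfig,
    out_dir: str | Path,
    n: int = 40,
    sampler: dict | None = None,
) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra, reference = generate_validation_set(matrix_kind, n, sampler, config)
    spectra_path = out_dir / f"{matrix_kind}_validation_spectra.csv"
    reference_path = out_dir / f"{matrix_kind}_validation_reference.csv"
    spectra.to_csv(spectra_path)
    reference_to_csv(reference, reference_path)
    return {
        "spectra": str(spectra_path),
        "reference": str(reference_path),
        "n_samples": n,
        "n_spectra": len(spectra),
    }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path, stage: str, config_echo: dict, files: dict, counts: dict
) -> Path:
    """Emit a JSON run manifest: config echo, version, checksums, counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_echo,
        "files": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()},
        "counts": counts,
    }
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def load_calibration_inputs(spectra_csv, reference_csv):
    spectra = SpectraSet.from_csv(spectra_csv)
    reference = reference_from_csv(reference_csv)
    return spectra, reference
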