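"""Analytical figures of merit for the NIR calibration and validation stages.

Covers linearity (r2, slope, intercept of predicted vs observed), RMSE
variants (estimation with a degrees-of-freedom correction, cross-validation,
prediction), detection limits (3 and 10 times the blank-prediction SD over
the calibration slope), precision as RSD, recovery at spiked QC levels, the
range error ratio with Williams' interpretive intervals, censored reporting
below LOD/LOQ, and the per-sample NIR-vs-reference comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CENSORED_LOD, CENSORED_LOQ, reference_value

__all__ = [
    "FiguresOfMerit",
    "ValidationReport",
    "RER_BOUNDARIES",
    "regression_line",
    "rmse",
    "lod_loq",
    "precision_rsd",
    "recovery",
    "rer",
    "rer_category",
    "censor",
    "method_comparison",
]

#: Williams' interpretive RER boundaries as printed: <7 poor, 7-12 approximate
#: screening, 13-20 screening, >=21 quality control. The printed gaps (12,13)
#: and (20,21) are closed upward so the categories partition (0, inf).
RER_BOUNDARIES = (7.0, 12.0, 13.0, 20.0, 21.0)


@dataclass
class FiguresOfMerit:
    """Calibration metrology bundle (all concentrations in mg/kg)."""

    r2: float
    slope: float
    intercept: float
    rmsee: float
    rmsecv: float
    lod: float
    loq: float
    repeatability_rsd: float | None = None
    reproducibility_rsd: float | None = None
    recovery: dict = field(default_factory=dict)
    r2x: float | None = None
    r2y: float | None = None
    q2: float | None = None
    n_orth: int | None = None

    def to_dict(self) -> dict:
        out = {
            "r2": self.r2,
            "slope": self.slope,
            "intercept": self.intercept,
            "rmsee_mg_kg": self.rmsee,
            "rmsecv_mg_kg": self.rmsecv,
            "lod_mg_kg": self.lod,
            "loq_mg_kg": self.loq,
            "repeatability_rsd_pct": self.repeatability_rsd,
            "reproducibility_rsd_pct": self.reproducibility_rsd,
            "recovery_pct": {str(k): v for k, v in self.recovery.items()},
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
            "n_orthogonal_components": self.n_orth,
        }
        return out


@dataclass
class ValidationReport:
    """Per-sample censored predictions vs reference plus summary metrics."""

    per_sample: pd.DataFrame  # sample_id, nir_reported, reference, abs_error
    rmsep: float | None
    rer: float | None
    rer_category: str | None
    prediction_r2: float | None
    pearson_r: float | None
    n_uncensored: int

    def summary(self) -> dict:
        return {
            "rmsep_mg_kg": self.rmsep,
            "rer": self.rer,
            "rer_category": self.rer_category,
            "prediction_r2": self.prediction_r2,
            "pearson_r": self.pearson_r,
            "n_uncensored_pairs": self.n_uncensored,
        }


def regression_line(observed, predicted):
    """OLS of predicted on observed: returns (r2, slope, intercept)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size != predicted.size:
        raise ValueError("length mismatch")
    if observed.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(observed) == 0:
        raise ValueError("degenerate observed values (zero variance)")
    res = stats.linregress(observed, predicted)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def rmse(observed, predicted, kind: str = "prediction", n_components: int = 0) -> float:
    """Root-mean-square error.

    ``prediction``: sqrt(sum(e^2)/n). ``estimation``: training-set error with
    the chemometric degrees-of-freedom correction sqrt(sum(e^2)/(n - 1 - A)),
    A = total fitted components.
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size != predicted.size:
        raise ValueError("length mismatch")
    errors = observed - predicted
    n = errors.size
    if kind == "prediction":
        return float(np.sqrt(np.sum(errors**2) / n))
    if kind == "estimation":
        dof = n - 1 - n_components
        if dof <= 0:
            raise ValueError("estimation RMSE needs n > n_components + 1")
        return float(np.sqrt(np.sum(errors**2) / dof))
    raise ValueError(f"unknown kind {kind!r}")


def lod_loq(blank_predictions, slope: float):
    """Limits of detection and quantification from repeated blank predictions:
    3 and 10 times the blank SD divided by the calibration slope."""
    blanks = np.asarray(blank_predictions, float)
    if blanks.size < 3:
        raise ValueError("need at least 3 blank predictions")
    if slope == 0:
        raise ValueError("zero slope")
    sd = float(np.std(blanks, ddof=1))
    return 3.0 * sd / abs(slope), 10.0 * sd / abs(slope)


def precision_rsd(measurements) -> float:
    """Relative standard deviation, percent (sd with n-1 over the mean)."""
    x = np.asarray(measurements, float)
    if x.size < 2:
        raise ValueError("need at least 2 measurements")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean; RSD undefined")
    return float(100.0 * np.std(x, ddof=1) / mean)


def recovery(predicted_mean: float, reference_level: float) -> float:
    """Accuracy as percent recovery of the spiked reference level."""
    if reference_level <= 0:
        raise ValueError("reference level must be > 0")
    return float(100.0 * predicted_mean / reference_level)


def rer_category(value: float) -> str:
    if value < RER_BOUNDARIES[0]:
        return "poor"
    if value < RER_BOUNDARIES[2]:
        return "approximate_screening"
    if value < RER_BOUNDARIES[4]:
        return "screening"
    return "quality_control"


def rer(predicted_values, rmsep: float):
    """Range error ratio: spread of predictions over RMSEP, with category."""
    pred = np.asarray(predicted_values, float)
    if pred.size < 2:
        raise ValueError("need at least 2 predicted values")
    if rmsep <= 0:
        raise ValueError("rmsep must be > 0")
    value = float((pred.max() - pred.min()) / rmsep)
    return value, rer_category(value)


def censor(value: float, lod: float, loq: float):
    """Report a prediction, censoring below the limits.

    Values below LOD (including negative predictions) report as ``"<LOD"``,
    values in [LOD, LOQ) as ``"<LOQ"``, others numerically.
    """
    if lod >= loq:
        raise ValueError("need lod < loq")
    if value < lod:
        return CENSORED_LOD
    if value < loq:
        return CENSORED_LOQ
    return float(value)


def method_comparison(
    nir: pd.DataFrame, reference: pd.DataFrame, lod: float, loq: float
) -> ValidationReport:
    """Compare NIR predictions against the reference method sample-by-sample.

    Numeric NIR entries are censored at (lod, loq) before reporting; entries
    already carrying a censored marker pass through. Absolute errors, RMSEP,
    Pearson r, prediction r2 and the RER are computed over the pairs that are
    uncensored on both sides; with fewer than 2 such pairs the summary metrics
    are reported unavailable.
    """
    ref_map = {row.sample_id: row.histamine_mg_kg for row in reference.itertuples()}
    missing = [sid for sid in nir["sample_id"] if sid not in ref_map]
    if missing:
        raise ValueError(f"reference values missing for samples: {missing[:5]}")

    rows = []
    nir_vals, ref_vals = [], []
    for row in nir.itertuples():
        value, marker = reference_value(row.histamine_mg_kg)
        nir_reported = marker if marker else censor(value, lod, loq)
        ref_val, ref_marker = reference_value(ref_map[row.sample_id])
        ref_reported = ref_marker if ref_marker else ref_val
        both_numeric = not isinstance(nir_reported, str) and not isinstance(
            ref_reported, str
        )
        abs_error = abs(nir_reported - ref_reported) if both_numeric else None
        if both_numeric:
            nir_vals.append(nir_reported)
            ref_vals.append(ref_reported)
        rows.append(
            {
                "sample_id": row.sample_id,
                "nir_reported": nir_reported,
                "reference": ref_reported,
                "abs_error": abs_error,
            }
        )
    per_sample = pd.DataFrame(rows, columns=["sample_id", "nir_reported", "reference", "abs_error"])

    n_pairs = len(nir_vals)
    if n_pairs < 2:
        return ValidationReport(per_sample, None, None, None, None, None, n_pairs)
    nir_arr = np.array(nir_vals)
    ref_arr = np.array(ref_vals)
    rmsep_val = rmse(ref_arr, nir_arr, kind="prediction")
    if np.var(ref_arr) > 0 and np.var(nir_arr) > 0:
        pearson = float(stats.pearsonr(nir_arr, ref_arr).statistic)
        pred_r2 = pearson**2
    else:
        pearson, pred_r2 = None, None
    if rmsep_val > 0 and nir_arr.max() > nir_arr.min():
        rer_val, category = rer(nir_arr, rmsep_val)
    else:
        rer_val, category = None, None
    return ValidationReport(
        per_sample=per_sample,
        rmsep=rmsep_val,
        rer=rer_val,
        rer_category=category,
        prediction_r2=pred_r2,
        pearson_r=pearson,
        n_uncensored=n_pairs,
    )
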