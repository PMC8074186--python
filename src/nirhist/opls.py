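"""Orthogonal partial least squares (OPLS) regression, single response.

The model splits spectral variation into components orthogonal to the
response (removed sequentially by deflation) followed by exactly one
predictive component. With zero orthogonal components it reduces to
one-component PLS1. Cross-validation uses stratified venetian-blind folds
over the sorted response so every fold spans the calibration range.

Fit statistics follow the usual chemometric conventions:

* R2X — fraction of (centered) X sum of squares captured by all components,
  orthogonal plus predictive;
* R2Y — fraction of response variance explained by the fitted values;
* Q2  — 1 - PRESS / SS_Y from cross-validation, with centering re-estimated
  inside each training fold to avoid leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OPLSModel",
    "CVResult",
    "fit",
    "predict",
    "cross_validate",
    "select_components",
    "extract_prediction_vector",
    "save_model",
    "load_model",
]

_NORM_TOL = 1e-12


@dataclass
class OPLSModel:
    """Fitted OPLS model: centering vectors, component loadings, statistics."""

    x_mean: np.ndarray
    y_mean: float
    orth_weights: list  # unit vectors w_o
    orth_loadings: list  # loadings p_o
    weight: np.ndarray  # predictive unit weight w
    loading: np.ndarray  # predictive loading p
    q: float  # inner regression coefficient y ~ t
    n_orth: int
    r2x: float
    r2y: float
    prediction_vector: np.ndarray  # net coefficients on centered input
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_mean.size


@dataclass
class CVResult:
    """Cross-validation summary for one orthogonal-component count."""

    n_orth: int
    q2: float
    rmsecv: float
    press: float
    per_fold_press: np.ndarray
    fold_assignment: np.ndarray


def _center(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean


def fit(X: np.ndarray, y: np.ndarray, n_orth: int, metadata: dict | None = None) -> OPLSModel:
    """Fit OPLS with ``n_orth`` orthogonal components and one predictive.

    Centering is estimated from the data and stored on the model (inputs that
    are already centered simply yield zero means). Each orthogonal round
    computes the current predictive weight ``w ~ X'y``, takes the part of the
    X loading orthogonal to it as ``w_o``, and deflates X by the component
    ``t_o p_o'``; the predictive component is then fit on the filtered X.
    """
    Xc, yc, x_mean, y_mean = _center(X, y)
    n, p = Xc.shape
    if n < n_orth + 2:
        raise ValueError(f"need n >= n_orth + 2 samples (n={n}, n_orth={n_orth})")
    ss_y = float(yc @ yc)
    if ss_y <= _NORM_TOL:
        raise ValueError("zero-variance response")
    ss_x = float(np.sum(Xc**2))
    if ss_x <= _NORM_TOL:
        raise ValueError("zero X matrix")

    Xw = Xc
    orth_weights, orth_loadings = [], []
    captured = 0.0
    for _ in range(n_orth):
        w = Xw.T @ yc / ss_y
        norm_w = np.linalg.norm(w)
        if norm_w < _NORM_TOL:
            raise ValueError("predictive direction vanished; n_orth exceeds rank")
        w /= norm_w
        t = Xw @ w
        p_load = Xw.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo < _NORM_TOL:
            raise ValueError("no orthogonal variation left; n_orth exceeds rank")
        w_o /= norm_wo
        t_o = Xw @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < _NORM_TOL:
            raise ValueError("degenerate orthogonal score; n_orth exceeds rank")
        p_o = Xw.T @ t_o / tt_o
        Xw = Xw - np.outer(t_o, p_o)
        captured += tt_o * float(p_o @ p_o)
        orth_weights.append(w_o)
        orth_loadings.append(p_o)

    w = Xw.T @ yc / ss_y
    norm_w = np.linalg.norm(w)
    if norm_w < _NORM_TOL:
        raise ValueError("predictive direction vanished; X carries no y-covariance")
    w /= norm_w
    t = Xw @ w
    tt = float(t @ t)
    if tt < _NORM_TOL:
        raise ValueError("degenerate predictive score")
    p_load = Xw.T @ t / tt
    q = float(yc @ t / tt)
    captured += tt * float(p_load @ p_load)

    resid = yc - q * t
    r2y = 1.0 - float(resid @ resid) / ss_y
    r2x = captured / ss_x

    # net coefficients: sequential orthogonal filtering is linear, so fold it
    # into a single vector b with  yhat = (x - x_mean) . b + y_mean;
    # b = q * F w with F = prod_i (I - w_oi p_oi^T), applied right-to-left
    b = w.copy()
    for w_o, p_o in reversed(list(zip(orth_weights, orth_loadings))):
        b = b - w_o * (p_o @ b)
    b *= q

    return OPLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        orth_weights=orth_weights,
        orth_loadings=orth_loadings,
        weight=w,
        loading=p_load,
        q=q,
        n_orth=n_orth,
        r2x=float(r2x),
        r2y=float(r2y),
        prediction_vector=b,
        metadata=metadata or {},
    )


def predict(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for spectra in the training preprocessing space."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"wavelength-grid mismatch: model has {model.n_features} variables, "
            f"input has {X_new.shape[1]}"
        )
    Xc = X_new - model.x_mean
    for w_o, p_o in zip(model.orth_weights, model.orth_loadings):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
    return model.q * (Xc @ model.weight) + model.y_mean


def _venetian_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified venetian blinds: sort by y (seeded shuffle within ties),
    then deal samples to folds in rotation so each fold spans the range."""
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    jitter = rng.random(y.size)
    order = np.lexsort((jitter, y))
    assignment = np.empty(y.size, dtype=int)
    assignment[order] = np.arange(y.size) % folds + 1
    return assignment


def cross_validate(
    X: np.ndarray, y: np.ndarray, n_orth: int, folds: int = 7, seed: int = 0
) -> CVResult:
    """K-fold cross-validation; centering re-estimated per training fold."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if folds > n:
        raise ValueError(f"folds ({folds}) > n ({n})")
    assignment = _venetian_folds(y, folds, seed)
    per_fold = np.zeros(folds)
    for k in range(1, folds + 1):
        held = assignment == k
        model = fit(X[~held], y[~held], n_orth)
        pred = predict(model, X[held])
        per_fold[k - 1] = float(np.sum((y[held] - pred) ** 2))
    press = float(per_fold.sum())
    ss_y = float(np.sum((y - y.mean()) ** 2))
    return CVResult(
        n_orth=n_orth,
        q2=1.0 - press / ss_y,
        rmsecv=float(np.sqrt(press / n)),
        press=press,
        per_fold_press=per_fold,
        fold_assignment=assignment,
    )


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_orth: int,
    folds: int = 7,
    seed: int = 0,
    tolerance: float = 0.01,
):
    """Evaluate n_orth = 0..max_orth by CV; pick the most parsimonious model.

    Returns ``(best_n_orth, [CVResult, ...])``; best is the smallest count
    whose Q2 comes within ``tolerance`` of the maximum.
    """
    if max_orth < 0:
        raise ValueError("max_orth must be >= 0")
    results = [cross_validate(X, y, k, folds=folds, seed=seed) for k in range(max_orth + 1)]
    best_q2 = max(r.q2 for r in results)
    best = next(r.n_orth for r in results if r.q2 >= best_q2 - tolerance)
    return best, results


def extract_prediction_vector(model: OPLSModel, wavelengths: np.ndarray | None = None):
    """Net regression coefficients, optionally annotated by wavelength.

    Applying the coefficients to a centered, orthogonally *unfiltered*
    spectrum reproduces ``predict`` exactly: the sequential filtering is
    already folded in. With wavelengths given, returns a pandas Series
    indexed by nm — convenient for band-specificity inspection.
    """
    coef = model.prediction_vector.copy()
    if wavelengths is None:
        return coef
    import pandas as pd

    return pd.Series(coef, index=np.asarray(wavelengths, float), name="coefficient")


# -- serialization ------------------------------------------------------------


def _to_jsonable(model: OPLSModel) -> dict:
    return {
        "format": "nirhist-opls-1",
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "orth_weights": [w.tolist() for w in model.orth_weights],
        "orth_loadings": [p.tolist() for p in model.orth_loadings],
        "weight": model.weight.tolist(),
        "loading": model.loading.tolist(),
        "q": model.q,
        "n_orth": model.n_orth,
        "r2x": model.r2x,
        "r2y": model.r2y,
        "prediction_vector": model.prediction_vector.tolist(),
        "metadata": model.metadata,
    }


def save_model(model: OPLSModel, path: str | Path) -> None:
    """Write the model as a key-value JSON text file (lossless round-trip)."""
    Path(path).write_text(json.dumps(_to_jsonable(model), indent=1))


def load_model(path: str | Path) -> OPLSModel:
    blob = json.loads(Path(path).read_text())
    if blob.get("format") != "nirhist-opls-1":
        raise ValueError(f"{path}: not a nirhist OPLS model file")
    return OPLSModel(
        x_mean=np.array(blob["x_mean"], float),
        y_mean=float(blob["y_mean"]),
        orth_weights=[np.array(w, float) for w in blob["orth_weights"]],
        orth_loadings=[np.array(p, float) for p in blob["orth_loadings"]],
        weight=np.array(blob["weight"], float),
        loading=np.array(blob["loading"], float),
        q=float(blob["q"]),
        n_orth=int(blob["n_orth"]),
        r2x=float(blob["r2x"]),
        r2y=float(blob["r2y"]),
        prediction_vector=np.array(blob["prediction_vector"], float),
        metadata=blob.get("metadata", {}),
    )
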