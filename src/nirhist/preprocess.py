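"""Spectral preprocessing: SNV, Savitzky-Golay derivatives, replicate
averaging, and Hotelling T-squared outlier screening.

The winning chain for the histamine models is SNV followed by a 2nd-order
Savitzky-Golay second derivative (quadratic fit to 15 points); mean centering
is applied at model-fit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from scipy import signal, stats

from .dataset import SpectraSet

__all__ = [
    "PreprocessConfig",
    "OutlierReport",
    "snv",
    "savgol_derivative",
    "average_replicates",
    "collapse_repositions",
    "hotelling_outliers",
    "apply_chain",
    "default_chain",
]


def default_chain() -> list[dict]:
    return [
        {"name": "snv"},
        {"name": "savgol", "window": 15, "polyorder": 2, "deriv": 2},
    ]


@dataclass
class PreprocessConfig:
    """Ordered list of per-spectrum filter steps.

    Supported steps: ``{"name": "snv"}``,
    ``{"name": "savgol", "window": w, "polyorder": k, "deriv": d}``,
    ``{"name": "mean_center"}`` (set-level, usually left to model fitting).
    """

    steps: list = field(default_factory=default_chain)

    def validate(self) -> None:
        for i, step in enumerate(self.steps):
            if not isinstance(step, dict) or "name" not in step:
                raise ValueError(f"step {i}: each step needs a 'name'")
            name = step["name"]
            if name == "savgol":
                w = int(step.get("window", 15))
                k = int(step.get("polyorder", 2))
                d = int(step.get("deriv", 2))
                if w % 2 == 0 or w <= k:
                    raise ValueError(f"step {i}: window must be odd and > polyorder")
                if d > k:
                    raise ValueError(f"step {i}: deriv must be <= polyorder")
            elif name not in ("snv", "mean_center"):
                raise ValueError(f"step {i}: unknown step {name!r}")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, sd with n-1.

    Removes multiplicative scatter and additive offsets; output has mean 0
    and unit standard deviation. Works on a single spectrum or row-wise on a
    matrix.
    """
    x = np.asarray(spectrum, float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 points")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for zero-variance spectrum")
    return (x - mean) / sd


def savgol_derivative(
    spectrum: np.ndarray,
    window: int = 15,
    polyorder: int = 2,
    deriv: int = 2,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay derivative preserving the wavelength grid.

    Interior points are the classical convolution (local least-squares
    polynomial); at each of the first/last ``window // 2`` points the
    polynomial is re-fit on the truncated one-sided window actually available,
    so output length equals input length. Units are AU per nm^deriv for the
    default 1 nm spacing.
    """
    x = np.asarray(spectrum, float)
    n = x.shape[-1]
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if n < window:
        raise ValueError(f"spectrum length {n} < window {window}")
    out = signal.savgol_filter(
        x, window, polyorder, deriv=deriv, delta=delta, axis=-1, mode="interp"
    )
    half = window // 2
    flat = x.reshape(-1, n)
    scale = factorial(deriv)
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t = (np.arange(lo, hi) - i) * delta
        vand = np.vander(t, polyorder + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(vand, flat[:, lo:hi].T, rcond=None)
        out.reshape(-1, n)[:, i] = scale * coef[deriv]
    return out


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Average the reposition spectra of one subsample into one spectrum.

    All rows must share a single sample_id; the reposition index is collapsed
    to 0 in the resulting single-row set.
    """
    ids = spectra.meta["sample_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"mixed sample identity: {sorted(ids)}")
    mean = spectra.absorbance.mean(axis=0, keepdims=True)
    meta = spectra.meta.iloc[[0]].copy()
    meta["reposition"] = 0
    return SpectraSet(spectra.grid, mean, meta)


def collapse_repositions(spectra: SpectraSet) -> SpectraSet:
    """Average all spectra sharing a sample_id, preserving first-seen order."""
    order = spectra.meta["sample_id"].drop_duplicates()
    parts = []
    for sid in order:
        mask = (spectra.meta["sample_id"] == sid).to_numpy()
        parts.append(average_replicates(spectra.select(mask)))
    grid = spectra.grid
    import pandas as pd

    return SpectraSet(
        grid,
        np.vstack([p.absorbance for p in parts]),
        pd.concat([p.meta for p in parts], ignore_index=True),
    )


@dataclass
class OutlierReport:
    """Hotelling T-squared screen: per-spectrum statistic vs an F-based limit."""

    t2_values: np.ndarray
    limit: float
    flagged_ids: list
    flagged_index: np.ndarray
    n_components: int
    alpha: float


def hotelling_outliers(
    spectra: SpectraSet | np.ndarray,
    alpha: float = 0.05,
    variance_cutoff: float = 0.95,
) -> OutlierReport:
    """Flag spectra whose PCA scores lie outside the T-squared control limit.

    Scores come from a PCA of the mean-centered absorbance matrix; the number
    of components A is the smallest count explaining at least
    ``variance_cutoff`` of the variance. The limit is
    ``A (n-1) / (n-A) * F^{-1}(1 - alpha; A, n-A)``.
    """
    if isinstance(spectra, SpectraSet):
        X = spectra.absorbance
        ids = spectra.meta["sample_id"].tolist()
    else:
        X = np.asarray(spectra, float)
        ids = list(range(X.shape[0]))
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    total = float(np.sum(Xc**2))
    if total <= 0:
        raise ValueError("no spectral variance: degenerate set")
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ratio = s**2 / np.sum(s**2)
    n_components = int(np.searchsorted(np.cumsum(ratio), variance_cutoff) + 1)
    n_components = min(n_components, n - 2)  # keep the F limit defined
    if n < n_components + 2:
        raise ValueError("need n >= n_components + 2 spectra")
    scores = u[:, :n_components] * s[:n_components]
    score_var = s[:n_components] ** 2 / (n - 1)
    t2 = np.sum(scores**2 / score_var, axis=1)
    limit = (
        n_components
        * (n - 1)
        / (n - n_components)
        * stats.f.ppf(1 - alpha, n_components, n - n_components)
    )
    flagged_index = np.flatnonzero(t2 > limit)
    return OutlierReport(
        t2_values=t2,
        limit=float(limit),
        flagged_ids=[ids[i] for i in flagged_index],
        flagged_index=flagged_index,
        n_components=n_components,
        alpha=alpha,
    )


def apply_chain(spectra: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """Apply the configured filter steps in order; metadata and grid untouched."""
    config.validate()
    X = spectra.absorbance.copy()
    for i, step in enumerate(config.steps):
        try:
            name = step["name"]
            if name == "snv":
                X = snv(X)
            elif name == "savgol":
                X = savgol_derivative(
                    X,
                    window=int(step.get("window", 15)),
                    polyorder=int(step.get("polyorder", 2)),
                    deriv=int(step.get("deriv", 2)),
                    delta=float(step.get("delta", 1.0)),
                )
            elif name == "mean_center":
                X = X - X.mean(axis=0)
        except Exception as exc:
            raise type(exc)(f"preprocess step {i} ({step.get('name')}): {exc}") from exc
    return SpectraSet(spectra.grid, X, spectra.meta.copy())
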