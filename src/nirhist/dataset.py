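"""Core containers for NIR spectra and reference concentrations.

Spectra are absorbance (log10(1/R), AU) sampled on a fixed integer-nanometre
grid; each spectrum carries design metadata (pool, spiking level, replicate,
cuvette reposition, day, role) describing its place in the calibration or
validation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata columns of a SpectraSet, in canonical order
META_COLUMNS = [
    "sample_id",
    "matrix_kind",
    "pool",
    "level_mg_kg",
    "replicate",
    "reposition",
    "day",
    "role",
]

MATRIX_KINDS = ("raw", "processed")
ROLES = ("calibration", "validation", "qc", "blank")

#: censored-result markers used in reference tables and reports
CENSORED_LOD = "<LOD"
CENSORED_LOQ = "<LOQ"


@dataclass(frozen=True)
class WavelengthGrid:
    """Integer-nm acquisition grid, 1000-2500 nm at 1 nm by default."""

    start_nm: int = 1000
    end_nm: int = 2500
    step_nm: int = 1

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.end_nm <= self.start_nm:
            raise ValueError("grid must be strictly increasing")
        if (self.end_nm - self.start_nm) % self.step_nm != 0:
            raise ValueError("grid span must be a multiple of step_nm")

    def __len__(self) -> int:
        return (self.end_nm - self.start_nm) // self.step_nm + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1, self.step_nm, dtype=float)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class SpectraSet:
    """An n x p absorbance matrix with row-aligned design metadata."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns, "
                f"grid has {len(self.grid)} points"
            )
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("meta length must match number of spectra")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def select(self, mask) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(self.grid, self.absorbance[idx], self.meta.iloc[idx])

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.grid, self.absorbance.copy(), self.meta.copy())

    # -- wide-CSV dialect: meta columns then one column per wavelength --------

    def to_csv(self, path: str | Path) -> None:
        wl_cols = [str(int(w)) for w in self.grid.wavelengths]
        frame = pd.concat(
            [
                self.meta[META_COLUMNS].reset_index(drop=True),
                pd.DataFrame(self.absorbance, columns=wl_cols),
            ],
            axis=1,
        )
        frame.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        frame = pd.read_csv(path)
        wl_cols = [c for c in frame.columns if c not in META_COLUMNS]
        wavelengths = np.array([int(c) for c in wl_cols])
        if len(wavelengths) < 2:
            raise ValueError("spectra CSV has no wavelength columns")
        step = int(wavelengths[1] - wavelengths[0])
        grid = WavelengthGrid(int(wavelengths[0]), int(wavelengths[-1]), step)
        if not np.array_equal(grid.wavelengths, wavelengths.astype(float)):
            raise ValueError("wavelength columns are not an even integer grid")
        return cls(grid, frame[wl_cols].to_numpy(float), frame[META_COLUMNS].copy())


def make_meta(rows: list[dict]) -> pd.DataFrame:
    """Build a metadata frame from per-spectrum dicts, in canonical column order."""
    meta = pd.DataFrame(rows)
    return meta[META_COLUMNS]


# -- reference tables ---------------------------------------------------------


def make_reference_table(
    sample_ids, values, source: str, censored=None
) -> pd.DataFrame:
    """Reference-concentration table: sample_id, histamine_mg_kg, source.

    ``values`` are numeric mg/kg; entries of ``censored`` (aligned, optional)
    may override them with the literal markers ``"<LOD"`` / ``"<LOQ"``.
    """
    out = []
    for i, (sid, val) in enumerate(zip(sample_ids, values)):
        cell = censored[i] if censored is not None and censored[i] else val
        out.append({"sample_id": sid, "histamine_mg_kg": cell, "source": source})
    return pd.DataFrame(out, columns=["sample_id", "histamine_mg_kg", "source"])


def reference_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def reference_from_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"histamine_mg_kg": str})
    return table[["sample_id", "histamine_mg_kg", "source"]]


def reference_value(cell) -> tuple[float | None, str | None]:
    """Split a reference cell into (numeric value, censored marker).

    Exactly one of the two is non-None.
    """
    if isinstance(cell, str):
        text = cell.strip()
        if text in (CENSORED_LOD, CENSORED_LOQ):
            return None, text
        return float(text), None
    return float(cell), None
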