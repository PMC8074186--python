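"""Synthetic NIR calibration and validation data for spiked tuna matrices.

The generator reproduces the statistical structure the downstream chemometric
analysis assumes: a smooth matrix baseline (water/protein/lipid Gaussian
bands), a histamine signature growing linearly with concentration
(Beer-Lambert additivity) at its characteristic N-H / C-N-C bands
(2180, 2240, 2475 nm), multiplicative scatter, additive offset and linear
tilt artefacts, white instrument noise, pool-to-pool compositional offsets,
day-to-day drift, and a noisy HPLC-like reference-value generator.

The calibration design is 4 pools x 7 spiking levels
{0, 10, 50, 100, 200, 400, 1000} mg/kg x 5 replicates, each subsample scanned
at 4 cuvette repositions (140 subsamples, 560 spectra per matrix kind).

Everything is reproducible from ``SimulationConfig.seed``; independent RNG
streams are derived per (purpose, matrix kind) so that, e.g., regenerating a
calibration set never perturbs the validation draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .dataset import (
    MATRIX_KINDS,
    SpectraSet,
    WavelengthGrid,
    make_meta,
    make_reference_table,
)

__all__ = [
    "SimulationConfig",
    "matrix_baseline",
    "histamine_signature",
    "generate_calibration_set",
    "generate_blank_set",
    "generate_qc_set",
    "generate_validation_set",
    "generate_storage_scenario",
    "default_validation_sampler",
    "draw_concentrations",
    "load_table2_fixture",
    "Table2Fixture",
]

#: calibration spiking levels, mg/kg (nominal labels taken at face value)
CALIBRATION_LEVELS = (0.0, 10.0, 50.0, 100.0, 200.0, 400.0, 1000.0)

# RNG stream codes, combined with the seed as default_rng([seed, code, ...])
_STREAM_POOL = 1
_STREAM_CALIBRATION = 2
_STREAM_BLANK = 3
_STREAM_QC = 4
_STREAM_VALIDATION = 5
_STREAM_DAY = 6
_STREAM_STORAGE = 7

_MATRIX_CODE = {"raw": 0, "processed": 1}


def _default_band_table() -> dict:
    # Broad background bands: water (1450, 1940), protein/CH combination
    # regions. The processed matrix adds a lipid/aromatic C-H band at 1650 nm
    # (residual packing oil), absent from the raw matrix.
    raw = [
        (1200.0, 70.0, 0.15),
        (1450.0, 60.0, 0.45),
        (1790.0, 60.0, 0.20),
        (1940.0, 70.0, 0.65),
        (2100.0, 90.0, 0.30),
        (2300.0, 80.0, 0.18),
    ]
    processed = raw + [(1650.0, 30.0, 0.12)]
    return {"raw": raw, "processed": processed}


@dataclass
class SimulationConfig:
    """Knobs of the spectral simulator; defaults are the study conditions."""

    band_centers_nm: tuple = (2180.0, 2240.0, 2475.0)
    band_widths_nm: tuple = (25.0, 25.0, 25.0)
    band_amplitude_AU_per_100mgkg: float = 1e-3
    matrix_band_table: dict = field(default_factory=_default_band_table)
    scatter_mult_range: tuple = (0.97, 1.03)
    offset_sd_AU: float = 2e-3
    tilt_sd_AU_per_1000nm: float = 1e-3
    noise_sd_AU: float = 1e-4
    day_drift_sd_AU: float = 2e-3
    hplc_rel_sd: float = 0.05
    pool_scale_sd: float = 0.02
    pool_offset_sd_AU: float = 1e-3
    n_pools: int = 4
    levels: tuple = CALIBRATION_LEVELS
    n_replicates: int = 5
    n_repositions: int = 4
    seed: int = 42
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def validate(self) -> None:
        if len(self.band_centers_nm) != len(self.band_widths_nm):
            raise ValueError("band centers and widths must align")
        for c in self.band_centers_nm:
            if not (self.grid.start_nm <= c <= self.grid.end_nm):
                raise ValueError(f"band center {c} nm outside grid")
        for name in (
            "offset_sd_AU",
            "tilt_sd_AU_per_1000nm",
            "noise_sd_AU",
            "day_drift_sd_AU",
            "hplc_rel_sd",
            "pool_scale_sd",
            "pool_offset_sd_AU",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.band_amplitude_AU_per_100mgkg < 0:
            raise ValueError("band amplitude must be >= 0")
        if any(w <= 0 for w in self.band_widths_nm):
            raise ValueError("band widths must be > 0")
        lo, hi = self.scatter_mult_range
        if lo > hi:
            raise ValueError("scatter_mult_range must be (low, high)")
        if set(self.matrix_band_table) - set(MATRIX_KINDS):
            raise ValueError("matrix_band_table keys must be matrix kinds")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _check_matrix_kind(matrix_kind: str) -> None:
    if matrix_kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix_kind {matrix_kind!r}; expected raw/processed")


def _rng(config: SimulationConfig, *codes: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed)] + [int(c) for c in codes])


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def matrix_baseline(matrix_kind: str, grid: WavelengthGrid, config: SimulationConfig) -> np.ndarray:
    """Deterministic smooth matrix background: sum of configured Gaussian bands."""
    _check_matrix_kind(matrix_kind)
    config.validate()
    wl = grid.wavelengths
    out = np.zeros_like(wl)
    for center, width, amplitude in config.matrix_band_table.get(matrix_kind, []):
        out += amplitude * _gaussian(wl, center, width)
    return out


def histamine_signature(concentration: float, grid: WavelengthGrid, config: SimulationConfig) -> np.ndarray:
    """Histamine absorbance contribution at ``concentration`` mg/kg.

    Linear in concentration (Beer-Lambert): each configured band contributes
    ``amplitude * concentration / 100`` AU at its center. The 2475 nm band is
    the strongest (C-N-C symmetric stretch), so the signature's maximum beyond
    2400 nm sits on that band.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    wl = grid.wavelengths
    out = np.zeros_like(wl)
    scale = concentration * config.band_amplitude_AU_per_100mgkg / 100.0
    # relative band strengths: 2475 dominant, 2240 and 2180 progressively weaker
    strengths = _band_strengths(config)
    for (center, width), strength in zip(
        zip(config.band_centers_nm, config.band_widths_nm), strengths
    ):
        out += scale * strength * _gaussian(wl, center, width)
    return out


def _band_strengths(config: SimulationConfig) -> np.ndarray:
    n = len(config.band_centers_nm)
    if n == 3:
        return np.array([0.6, 0.8, 1.0])
    return np.ones(n)


def _pool_effect(config: SimulationConfig, matrix_kind: str, pool: int) -> tuple[float, float]:
    """Per-pool compositional deviation: (baseline scale, constant offset)."""
    rng = _rng(config, _STREAM_POOL, _MATRIX_CODE[matrix_kind], pool)
    scale = 1.0 + config.pool_scale_sd * rng.standard_normal()
    offset = config.pool_offset_sd_AU * rng.standard_normal()
    return scale, offset


def _day_drift(config: SimulationConfig, matrix_kind: str, day: int) -> np.ndarray:
    """Smooth seeded baseline drift for measurement day > 0 (zeros at day 0)."""
    wl = config.grid.wavelengths
    if day == 0 or config.day_drift_sd_AU == 0:
        return np.zeros_like(wl)
    rng = _rng(config, _STREAM_DAY, _MATRIX_CODE[matrix_kind], day)
    drift = np.zeros_like(wl)
    for _ in range(3):
        amp = config.day_drift_sd_AU * rng.standard_normal()
        center = rng.uniform(1100.0, 2400.0)
        width = rng.uniform(30.0, 80.0)
        drift += amp * _gaussian(wl, center, width)
    return drift


def _acquire(
    clean: np.ndarray,
    n_spectra: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    drift: np.ndarray | None = None,
) -> np.ndarray:
    """Instrumental distortions: scatter, offset, tilt, white noise."""
    wl = config.grid.wavelengths
    tilt_basis = (wl - 1750.0) / 1000.0
    lo, hi = config.scatter_mult_range
    rows = np.empty((n_spectra, wl.size))
    base = clean if drift is None else clean + drift
    for i in range(n_spectra):
        scatter = rng.uniform(lo, hi)
        offset = rng.normal(0.0, config.offset_sd_AU) if config.offset_sd_AU else 0.0
        tilt = (
            rng.normal(0.0, config.tilt_sd_AU_per_1000nm)
            if config.tilt_sd_AU_per_1000nm
            else 0.0
        )
        noise = (
            rng.normal(0.0, config.noise_sd_AU, wl.size)
            if config.noise_sd_AU
            else 0.0
        )
        rows[i] = scatter * base + offset + tilt * tilt_basis + noise
    return rows


def generate_calibration_set(matrix_kind: str, config: SimulationConfig):
    """The full spiked-pool calibration design for one matrix kind.

    Returns ``(SpectraSet, ReferenceTable)`` with one reference row per
    subsample (nominal spiking level) and ``n_repositions`` spectra per
    subsample.
    """
    _check_matrix_kind(matrix_kind)
    config.validate()
    base = matrix_baseline(matrix_kind, config.grid, config)
    rng = _rng(config, _STREAM_CALIBRATION, _MATRIX_CODE[matrix_kind])
    rows, meta, ref_ids, ref_levels = [], [], [], []
    for pool in range(1, config.n_pools + 1):
        scale, offset = _pool_effect(config, matrix_kind, pool)
        pool_base = base * scale + offset
        for level in config.levels:
            clean = pool_base + histamine_signature(level, config.grid, config)
            for rep in range(1, config.n_replicates + 1):
                sid = f"{matrix_kind}-P{pool}-L{level:g}-R{rep}"
                rows.append(_acquire(clean, config.n_repositions, config, rng))
                for repos in range(1, config.n_repositions + 1):
                    meta.append(
                        dict(
                            sample_id=sid,
                            matrix_kind=matrix_kind,
                            pool=pool,
                            level_mg_kg=level,
                            replicate=rep,
                            reposition=repos,
                            day=0,
                            role="calibration",
                        )
                    )
                ref_ids.append(sid)
                ref_levels.append(level)
    spectra = SpectraSet(config.grid, np.vstack(rows), make_meta(meta))
    reference = make_reference_table(ref_ids, ref_levels, source="nominal")
    return spectra, reference


def generate_blank_set(matrix_kind: str, config: SimulationConfig, n_blanks: int = 10):
    """Unspiked subsamples used for the limit-of-detection blank study."""
    _check_matrix_kind(matrix_kind)
    config.validate()
    base = matrix_baseline(matrix_kind, config.grid, config)
    rng = _rng(config, _STREAM_BLANK, _MATRIX_CODE[matrix_kind])
    rows, meta, ref_ids = [], [], []
    for i in range(1, n_blanks + 1):
        pool = (i - 1) % config.n_pools + 1
        scale, offset = _pool_effect(config, matrix_kind, pool)
        clean = base * scale + offset
        sid = f"{matrix_kind}-BLK{i:02d}"
        rows.append(_acquire(clean, config.n_repositions, config, rng))
        for repos in range(1, config.n_repositions + 1):
            meta.append(
                dict(
                    sample_id=sid,
                    matrix_kind=matrix_kind,
                    pool=pool,
                    level_mg_kg=0.0,
                    replicate=1,
                    reposition=repos,
                    day=0,
                    role="blank",
                )
            )
        ref_ids.append(sid)
    spectra = SpectraSet(config.grid, np.vstack(rows), make_meta(meta))
    reference = make_reference_table(ref_ids, [0.0] * len(ref_ids), source="nominal")
    return spectra, reference


#: QC design: precision level and repeated-measurement counts
QC_PRECISION_LEVEL = 50.0
QC_PRECISION_PER_DAY = 6
QC_PRECISION_DAYS = (0, 1, 2)
QC_RECOVERY_LEVELS = (10.0, 50.0, 100.0)
QC_RECOVERY_REPLICATES = 5


def generate_qc_set(matrix_kind: str, config: SimulationConfig):
    """Quality-control spectra for precision and recovery studies.

    Precision: one pool-1 subsample spiked at 50 mg/kg, measured 6 times per
    day on 3 days (each measurement a full ``n_repositions`` acquisition;
    repeatability = day 0, reproducibility = all 18). Recovery: 5 subsamples
    at each of 10/50/100
    mg/kg, scanned like calibration subsamples. Sample ids are prefixed
    ``<matrix>-QCP-`` (precision) and ``<matrix>-QCR-`` (recovery).
    """
    _check_matrix_kind(matrix_kind)
    config.validate()
    base = matrix_baseline(matrix_kind, config.grid, config)
    rng = _rng(config, _STREAM_QC, _MATRIX_CODE[matrix_kind])
    rows, meta, ref_ids, ref_levels = [], [], [], []

    scale, offset = _pool_effect(config, matrix_kind, 1)
    clean_prec = base * scale + offset + histamine_signature(
        QC_PRECISION_LEVEL, config.grid, config
    )
    for day in QC_PRECISION_DAYS:
        drift = _day_drift(config, matrix_kind, day)
        for m in range(1, QC_PRECISION_PER_DAY + 1):
            sid = f"{matrix_kind}-QCP-D{day}-M{m}"
            rows.append(_acquire(clean_prec, config.n_repositions, config, rng, drift=drift))
            for repos in range(1, config.n_repositions + 1):
                meta.append(
                    dict(
                        sample_id=sid,
                        matrix_kind=matrix_kind,
                        pool=1,
                        level_mg_kg=QC_PRECISION_LEVEL,
                        replicate=m,
                        reposition=repos,
                        day=day,
                        role="qc",
                    )
                )
            ref_ids.append(sid)
            ref_levels.append(QC_PRECISION_LEVEL)

    for level in QC_RECOVERY_LEVELS:
        for s in range(1, QC_RECOVERY_REPLICATES + 1):
            pool = (s - 1) % config.n_pools + 1
            scale, offset = _pool_effect(config, matrix_kind, pool)
            clean = base * scale + offset + histamine_signature(level, config.grid, config)
            sid = f"{matrix_kind}-QCR-L{level:g}-S{s}"
            rows.append(_acquire(clean, config.n_repositions, config, rng))
            for repos in range(1, config.n_repositions + 1):
                meta.append(
                    dict(
                        sample_id=sid,
                        matrix_kind=matrix_kind,
                        pool=pool,
                        level_mg_kg=level,
                        replicate=s,
                        reposition=repos,
                        day=0,
                        role="qc",
                    )
                )
            ref_ids.append(sid)
            ref_levels.append(level)

    spectra = SpectraSet(config.grid, np.vstack(rows), make_meta(meta))
    reference = make_reference_table(ref_ids, ref_levels, source="nominal")
    return spectra, reference


# -- validation samples -------------------------------------------------------


def default_validation_sampler() -> dict:
    """Concentration mixture mirroring the market-sample distribution:
    mostly blank-like, some mid-range, a few strongly contaminated."""
    return {
        "kind": "mixture",
        "weights": [0.60, 0.35, 0.05],
        "components": [
            {"kind": "uniform", "low": 0.0, "high": 10.0},
            {"kind": "uniform", "low": 10.0, "high": 100.0},
            {"kind": "uniform", "low": 100.0, "high": 1700.0},
        ],
    }


def draw_concentrations(sampler: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` true concentrations from a declarative sampler spec."""
    if not isinstance(sampler, dict) or "kind" not in sampler:
        raise ValueError("sampler spec must be a dict with a 'kind' key")
    kind = sampler["kind"]
    if kind == "constant":
        return np.full(n, float(sampler["value"]))
    if kind == "uniform":
        return rng.uniform(float(sampler["low"]), float(sampler["high"]), n)
    if kind == "mixture":
        weights = np.asarray(sampler["weights"], float)
        if len(weights) != len(sampler["components"]) or weights.sum() <= 0:
            raise ValueError("mixture weights must align with components")
        weights = weights / weights.sum()
        choice = rng.choice(len(weights), size=n, p=weights)
        out = np.empty(n)
        for i, c in enumerate(choice):
            out[i] = draw_concentrations(sampler["components"][c], 1, rng)[0]
        return out
    raise ValueError(f"unknown sampler kind {kind!r}")


def generate_validation_set(
    matrix_kind: str,
    n: int,
    sampler: dict | None,
    config: SimulationConfig,
    n_duplicates: int = 2,
):
    """Market-style validation samples with an HPLC-like noisy reference.

    Each sample is measured in duplicate with ``n_repositions`` spectra per
    replicate (8 spectra by default). The reference value is
    ``true * (1 + N(0, hplc_rel_sd))`` floored at zero, source ``hplc_sim``.
    """
    _check_matrix_kind(matrix_kind)
    config.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if sampler is None:
        sampler = default_validation_sampler()
    base = matrix_baseline(matrix_kind, config.grid, config)
    rng = _rng(config, _STREAM_VALIDATION, _MATRIX_CODE[matrix_kind])
    true = draw_concentrations(sampler, n, rng)
    rows, meta, ref_ids, ref_vals = [], [], [], []
    for i in range(n):
        # each market sample carries its own compositional deviation
        scale = 1.0 + config.pool_scale_sd * rng.standard_normal()
        offset = config.pool_offset_sd_AU * rng.standard_normal()
        clean = base * scale + offset + histamine_signature(true[i], config.grid, config)
        sid = f"{matrix_kind}-V{i + 1:03d}"
        for rep in range(1, n_duplicates + 1):
            rows.append(_acquire(clean, config.n_repositions, config, rng))
            for repos in range(1, config.n_repositions + 1):
                meta.append(
                    dict(
                        sample_id=sid,
                        matrix_kind=matrix_kind,
                        pool=0,
                        level_mg_kg=true[i],
                        replicate=rep,
                        reposition=repos,
                        day=0,
                        role="validation",
                    )
                )
        hplc = true[i] * (1.0 + config.hplc_rel_sd * rng.standard_normal())
        ref_ids.append(sid)
        ref_vals.append(max(0.0, hplc))
    spectra = SpectraSet(config.grid, np.vstack(rows), make_meta(meta))
    reference = make_reference_table(ref_ids, ref_vals, source="hplc_sim")
    return spectra, reference


def generate_storage_scenario(
    spectra: SpectraSet,
    reference: pd.DataFrame,
    days: int,
    config: SimulationConfig,
    n_increases: int = 2,
    increase_range: tuple = (100.0, 600.0),
):
    """Room-temperature storage: day drift for all, histamine growth in a few.

    Most samples stay stable; a seeded minority (``n_increases``) develop a
    substantial concentration increase. ``days=0`` returns unchanged copies.
    """
    config.validate()
    if days < 0:
        raise ValueError("days must be >= 0")
    out_spectra = spectra.copy()
    out_ref = reference.copy()
    if days == 0:
        return out_spectra, out_ref
    matrix_kind = str(spectra.meta["matrix_kind"].iloc[0])
    rng = _rng(config, _STREAM_STORAGE, _MATRIX_CODE[matrix_kind], days)
    sample_ids = list(dict.fromkeys(spectra.meta["sample_id"]))
    n_increases = min(n_increases, len(sample_ids))
    raised = set(rng.choice(sample_ids, size=n_increases, replace=False))
    drift = _day_drift(config, matrix_kind, days)
    out_spectra.absorbance += drift
    out_spectra.meta["day"] = days
    ref_idx = out_ref.set_index("sample_id")
    for sid in raised:
        delta = rng.uniform(*increase_range)
        mask = (out_spectra.meta["sample_id"] == sid).to_numpy()
        out_spectra.absorbance[mask] += histamine_signature(delta, config.grid, config)
        new_true = float(out_spectra.meta.loc[mask, "level_mg_kg"].iloc[0]) + delta
        out_spectra.meta.loc[mask, "level_mg_kg"] = new_true
        hplc = max(0.0, new_true * (1.0 + config.hplc_rel_sd * rng.standard_normal()))
        ref_idx.loc[sid, "histamine_mg_kg"] = hplc
        ref_idx.loc[sid, "source"] = "hplc_sim"
    out_ref = ref_idx.reset_index()[["sample_id", "histamine_mg_kg", "source"]]
    return out_spectra, out_ref


# -- printed validation-table fixture -----------------------------------------

#: calibration-stage detection/quantification limits printed with the table
TABLE2_LIMITS = {
    "raw": {"lod": 3.5, "loq": 11.6},
    "processed": {"lod": 2.4, "loq": 8.6},
}


@dataclass
class Table2Fixture:
    """Printed per-sample NIR vs HPLC validation results (40 rows per matrix)."""

    frame: pd.DataFrame
    limits: dict

    def rows(self, matrix_kind: str) -> pd.DataFrame:
        _check_matrix_kind(matrix_kind)
        sub = self.frame[self.frame["matrix_kind"] == matrix_kind]
        return sub.reset_index(drop=True)

    def reference_tables(self, matrix_kind: str):
        """The printed columns as (nir ReferenceTable, hplc ReferenceTable)."""
        sub = self.rows(matrix_kind)
        ids = [f"{matrix_kind}-T2-{i:02d}" for i in sub["sample_index"]]
        nir = make_reference_table(
            ids,
            [_cell_value(v) for v in sub["nir"]],
            source="nir",
            censored=[_cell_marker(v) for v in sub["nir"]],
        )
        hplc = make_reference_table(
            ids,
            [_cell_value(v) for v in sub["hplc"]],
            source="hplc_printed",
            censored=[_cell_marker(v) for v in sub["hplc"]],
        )
        return nir, hplc


def _cell_value(cell: str):
    return None if cell.startswith("<") else float(cell)


def _cell_marker(cell: str):
    return cell if cell.startswith("<") else None


def _fixture_bytes() -> bytes:
    return resources.files("nirhist").joinpath("data/table2.csv").read_bytes()


def table2_checksum() -> str:
    """SHA-256 of the shipped fixture file, for integrity pinning."""
    return hashlib.sha256(_fixture_bytes()).hexdigest()


def load_table2_fixture() -> Table2Fixture:
    """Load the printed NIR/HPLC comparison table shipped with the package."""
    import io

    frame = pd.read_csv(
        io.BytesIO(_fixture_bytes()),
        dtype={"nir": str, "hplc": str},
    )
    frame["printed_abs_error"] = pd.to_numeric(
        frame["printed_abs_error"], errors="coerce"
    )
    return Table2Fixture(frame=frame, limits={k: dict(v) for k, v in TABLE2_LIMITS.items()})
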