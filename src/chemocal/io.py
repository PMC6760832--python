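"""Core containers and CSV interchange for spectra and concentration designs.

A :class:`SpectraMatrix` holds a samples × wavelengths absorbance block on a
strictly increasing, uniformly spaced nm grid; a :class:`ConcentrationDesign`
holds per-sample analyte concentrations (μg mL⁻¹), optionally with the coded
factor levels of the experimental design.

CSV layouts
-----------
Spectra:  ``wavelength_nm,<id1>,<id2>,...`` — one row per wavelength.
Design:   ``sample_id,<analyte1>,<analyte2>,...`` — one row per sample.

Both are comma-separated, ``.`` decimal, UTF-8, header mandatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    GridError,
    ParameterError,
    ParseError,
    ShapeMismatchError,
    ValidationError,
)

#: absolute tolerance (nm) for uniform-spacing and grid-matching checks
GRID_ATOL = 1e-9

_VALID_CODES = (-2, -1, 1, 2)


@dataclass
class SpectraMatrix:
    """Absorbance block (AU): rows are samples, columns are wavelengths."""

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float).ravel()
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.ndim == 1:
            ab = ab.reshape(1, -1)
        self.absorbance = ab
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise ShapeMismatchError(
                f"{len(self.sample_ids)} sample ids for {n} absorbance rows"
            )
        if p != self.wavelengths_nm.size:
            raise ShapeMismatchError(
                f"{self.wavelengths_nm.size} wavelengths for {p} absorbance columns"
            )
        if self.wavelengths_nm.size >= 2:
            d = np.diff(self.wavelengths_nm)
            if np.any(d <= 0):
                bad = self.wavelengths_nm[1:][d <= 0][0]
                raise GridError(f"wavelengths must be strictly increasing (at {bad} nm)")
            if np.ptp(d) > GRID_ATOL:
                raise GridError(
                    "non-uniform wavelength spacing: steps range "
                    f"{d.min():.12g}–{d.max():.12g} nm"
                )
        if self.absorbance.size and not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths_nm.size

    @property
    def step_nm(self) -> float:
        if self.n_wavelengths < 2:
            raise GridError("grid step undefined for fewer than 2 wavelengths")
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.wavelengths_nm.copy(), self.absorbance.copy(), list(self.sample_ids)
        )


@dataclass
class ConcentrationDesign:
    """Per-sample analyte concentrations (μg mL⁻¹) with optional coded levels."""

    analyte_names: list[str]
    concentrations: np.ndarray
    sample_ids: list[str]
    coded_levels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.analyte_names = [str(a) for a in self.analyte_names]
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim == 1:
            c = c.reshape(-1, 1)
        self.concentrations = c
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, k = self.concentrations.shape
        if len(self.sample_ids) != n:
            raise ShapeMismatchError(f"{len(self.sample_ids)} ids for {n} design rows")
        if len(self.analyte_names) != k:
            raise ShapeMismatchError(
                f"{len(self.analyte_names)} analyte names for {k} columns"
            )
        if not np.all(np.isfinite(self.concentrations)):
            raise ValidationError("concentrations contain non-finite values")
        if np.any(self.concentrations <= 0):
            i, j = np.argwhere(self.concentrations <= 0)[0]
            raise ValidationError(
                f"non-positive concentration for sample {self.sample_ids[i]!r}, "
                f"analyte {self.analyte_names[j]!r}"
            )
        if self.coded_levels is not None:
            lv = np.asarray(self.coded_levels, dtype=int)
            if lv.shape != self.concentrations.shape:
                raise ShapeMismatchError("coded_levels shape differs from concentrations")
            if not np.isin(lv, _VALID_CODES).all():
                raise ValidationError(f"coded levels must lie in {_VALID_CODES}")
            # each code must map to exactly one concentration per analyte (and back)
            for j, name in enumerate(self.analyte_names):
                pairs = {(int(a), float(b)) for a, b in zip(lv[:, j], c[:, j])}
                codes = [p[0] for p in pairs]
                concs = [p[1] for p in pairs]
                if len(set(codes)) != len(pairs) or len(set(concs)) != len(pairs):
                    raise ValidationError(
                        f"coded levels of analyte {name!r} do not map one-to-one "
                        "onto concentrations"
                    )
            self.coded_levels = lv

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        """Concentration vector of one analyte."""
        if analyte not in self.analyte_names:
            raise ValidationError(f"unknown analyte {analyte!r}; have {self.analyte_names}")
        return self.concentrations[:, self.analyte_names.index(analyte)].copy()


def _numeric_block(df: pd.DataFrame, what: str) -> np.ndarray:
    """Convert a string DataFrame to floats, reporting the first bad cell."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric {what} cell at data row {i + 1}, column {col!r}: "
                f"{df[col].iloc[i]!r}"
            )
        out[:, j] = converted.to_numpy(dtype=float)
    return out


def read_spectra_csv(path) -> SpectraMatrix:
    """Read a wavelength-by-sample spectra CSV into a :class:`SpectraMatrix`.

    The first column must be ``wavelength_nm``; remaining headers are sample
    ids, whose order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 1 or df.columns[0] != "wavelength_nm":
        raise ParseError(
            f"first column of {path} must be 'wavelength_nm', got {df.columns[0]!r}"
        )
    sample_ids = [str(c) for c in df.columns[1:]]
    values = _numeric_block(df, "spectra")
    wavelengths = values[:, 0]
    absorbance = values[:, 1:].T  # file rows = wavelengths → container rows = samples
    return SpectraMatrix(wavelengths, absorbance, sample_ids)


def write_spectra_csv(spectra: SpectraMatrix, path) -> None:
    """Write a :class:`SpectraMatrix` to CSV with ≥9 significant digits."""
    if spectra.n_samples == 0:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("wavelength_nm\n")
        return
    df = pd.DataFrame(
        {"wavelength_nm": spectra.wavelengths_nm}
        | {sid: spectra.absorbance[i] for i, sid in enumerate(spectra.sample_ids)}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_design_csv(path) -> ConcentrationDesign:
    """Read a sample-by-analyte concentration design CSV."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise ParseError(
            f"first column of {path} must be 'sample_id', got {df.columns[0]!r}"
        )
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    analytes = [str(c) for c in df.columns[1:]]
    conc = _numeric_block(df.iloc[:, 1:], "design")
    return ConcentrationDesign(analytes, conc, sample_ids)


def write_design_csv(design: ConcentrationDesign, path) -> None:
    """Write a :class:`ConcentrationDesign` to CSV."""
    df = pd.DataFrame(design.concentrations, columns=design.analyte_names)
    df.insert(0, "sample_id", design.sample_ids)
    df.to_csv(path, index=False, float_format="%.10g")


def validate_grid(
    spectra: SpectraMatrix, start_nm: float, end_nm: float, step_nm: float
) -> int:
    """Check the spectra grid equals ``start..end`` by ``step`` and return its size.

    The expected point count is ``floor((end - start)/step) + 1``; every stored
    wavelength must match its expected value within ``GRID_ATOL``.
    """
    if step_nm <= 0:
        raise ParameterError(f"step_nm must be positive, got {step_nm}")
    n_expected = int(math.floor((end_nm - start_nm) / step_nm + GRID_ATOL)) + 1
    expected = start_nm + step_nm * np.arange(n_expected)
    if spectra.n_wavelengths != n_expected:
        raise GridError(
            f"grid has {spectra.n_wavelengths} points; expected {n_expected} for "
            f"{start_nm}–{end_nm} nm at {step_nm} nm"
        )
    mismatch = np.abs(spectra.wavelengths_nm - expected) > GRID_ATOL
    if mismatch.any():
        i = int(np.flatnonzero(mismatch)[0])
        raise GridError(
            f"wavelength {spectra.wavelengths_nm[i]!r} nm at index {i} does not match "
            f"expected {expected[i]!r} nm"
        )
    return n_expected
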