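"""Synthetic UV mixture spectra for pyridostigmine bromide and its impurities.

The instrument data behind the six-model comparison are not deposited, so this
module emulates them: three overlapping UV absorbers — the drug (PR, λmax
270 nm) and its two related substances (IMPA, λmax 262 nm; IMPB, λmax 329 nm)
— modelled as sums of Gaussian bands on the 200–350 nm working grid, mixed by
Beer–Lambert additivity and perturbed with additive Gaussian noise.

The concentration layouts are the published 4-level 3-factor calibration
design (16 training mixtures) and its 9-mixture independent test set, exactly
as printed, in μg mL⁻¹.

Only the band positions (λmax) and the overlap structure of the real spectra
are emulated; absolute absorptivities and band shapes are package choices
scaled so that 10 μg mL⁻¹ of a pure component peaks at roughly 0.3–0.4 AU,
inside the Beer–Lambert validity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import ConcentrationDesign, SpectraMatrix

ANALYTES = ("PR", "IMPA", "IMPB")

# 4-level 3-factor training design: each analyte takes each of its 4 coded
# levels (−2, −1, +1, +2) in exactly 4 of the 16 mixtures.
_TRAIN_ROWS = (
    (20, 0.4, 0.5),
    (20, 0.6, 0.7),
    (30, 0.6, 1.3),
    (30, 1.2, 0.7),
    (60, 0.6, 0.5),
    (30, 0.4, 1.1),
    (20, 1.0, 1.1),
    (50, 1.0, 0.7),
    (50, 0.6, 1.1),
    (30, 1.0, 0.5),
    (50, 0.4, 1.3),
    (20, 1.2, 1.3),
    (60, 1.2, 1.1),
    (60, 1.0, 1.3),
    (50, 1.2, 0.5),
    (60, 0.4, 0.7),
)

_TEST_ROWS = (
    (20, 0.6, 0.7),
    (50, 1.0, 0.7),
    (50, 0.6, 1.1),
    (20, 0.4, 0.5),
    (30, 1.0, 0.5),
    (45, 0.5, 0.8),
    (25, 0.7, 0.5),
    (30, 0.8, 0.5),
    (25, 0.5, 0.6),
)

# concentration (μg mL⁻¹) → coded level, per analyte
_LEVEL_MAPS = (
    {20.0: -2, 30.0: -1, 50.0: 1, 60.0: 2},       # PR
    {0.4: -2, 0.6: -1, 1.0: 1, 1.2: 2},           # IMPA
    {0.5: -2, 0.7: -1, 1.1: 1, 1.3: 2},           # IMPB
)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise (AU) driven by one integer seed."""

    sigma_au: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_au < 0:
            raise ValidationError(f"sigma_au must be ≥ 0, got {self.sigma_au}")


@dataclass
class ComponentBandModel:
    """Pure-component UV spectrum modelled as a sum of Gaussian bands.

    ``bands`` is a list of ``(center_nm, width_nm, peak_absorptivity)`` with
    absorptivity in AU·mL·μg⁻¹; ``lambda_max_nm`` designates the band centre
    that must be the global maximum of the modelled pure spectrum on the
    working grid.
    """

    name: str
    bands: list[tuple[float, float, float]]
    lambda_max_nm: float

    def __post_init__(self) -> None:
        for c, w, a in self.bands:
            if w <= 0:
                raise ValidationError(f"band width must be > 0 (component {self.name})")
            if a < 0:
                raise ValidationError(
                    f"peak absorptivity must be ≥ 0 (component {self.name})"
                )

    def pure_spectrum(self, grid_nm: np.ndarray) -> np.ndarray:
        """Absorptivity spectrum (AU·mL·μg⁻¹) of the pure component on ``grid_nm``."""
        g = np.asarray(grid_nm, dtype=float)
        out = np.zeros_like(g)
        for c, w, a in self.bands:
            out += a * np.exp(-0.5 * ((g - c) / w) ** 2)
        return out

    def validate_on_grid(self, grid_nm: np.ndarray) -> None:
        """Check the designated λmax is the argmax of the modelled spectrum."""
        g = np.asarray(grid_nm, dtype=float)
        s = self.pure_spectrum(g)
        peak = g[int(np.argmax(s))]
        if abs(peak - self.lambda_max_nm) > 1e-9:
            raise ConfigurationError(
                f"component {self.name!r}: modelled spectrum peaks at {peak} nm, "
                f"designated λmax is {self.lambda_max_nm} nm"
            )


def default_grid() -> np.ndarray:
    """The 200–350 nm, 1 nm working grid (151 points)."""
    return np.arange(200.0, 351.0)


def default_components() -> list[ComponentBandModel]:
    """Band models for PR, IMPA and IMPB peaking at 270, 262 and 329 nm.

    PR and IMPA are deliberately near-degenerate (peaks 8 nm apart, similar
    widths) so their pure spectra overlap strongly, reproducing the spectral
    interference that motivates multivariate calibration.
    """
    return [
        ComponentBandModel("PR", [(270.0, 18.0, 0.035), (215.0, 12.0, 0.020)], 270.0),
        ComponentBandModel("IMPA", [(262.0, 16.0, 0.030), (210.0, 10.0, 0.015)], 262.0),
        ComponentBandModel("IMPB", [(329.0, 20.0, 0.040), (248.0, 14.0, 0.018)], 329.0),
    ]


def _design(rows, prefix: str, coded: bool) -> ConcentrationDesign:
    conc = np.array(rows, dtype=float)
    ids = [f"{prefix}{i + 1:02d}" for i in range(len(rows))]
    levels = None
    if coded:
        levels = np.array(
            [[_LEVEL_MAPS[j][row[j]] for j in range(3)] for row in rows], dtype=int
        )
    return ConcentrationDesign(list(ANALYTES), conc, ids, levels)


def build_calibration_design() -> ConcentrationDesign:
    """The 16-mixture 4-level 3-factor training design, in printed order."""
    return _design(_TRAIN_ROWS, "train_", coded=True)


def build_test_design() -> ConcentrationDesign:
    """The 9-mixture independent test design, in printed order."""
    return _design(_TEST_ROWS, "test_", coded=False)


def generate_mixture_spectra(
    design: ConcentrationDesign,
    components: list[ComponentBandModel] | None = None,
    grid_nm: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> SpectraMatrix:
    """Beer–Lambert mixture spectra: A(s, λ) = Σₖ cₛₖ·εₖ(λ) + N(0, σ²).

    Component names must match the design's analyte names in order.  Output is
    bit-reproducible for a given :class:`NoiseModel` seed.
    """
    components = default_components() if components is None else components
    grid = default_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    noise = NoiseModel() if noise is None else noise
    names = [c.name for c in components]
    if names != design.analyte_names:
        raise ConfigurationError(
            f"component names {names} do not match design analytes {design.analyte_names}"
        )
    for comp in components:
        comp.validate_on_grid(grid)
    basis = np.stack([c.pure_spectrum(grid) for c in components])  # k × p
    absorbance = design.concentrations @ basis
    if noise.sigma_au > 0:
        rng = np.random.default_rng(noise.seed)
        absorbance = absorbance + rng.normal(0.0, noise.sigma_au, absorbance.shape)
    return SpectraMatrix(grid, absorbance, design.sample_ids)
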