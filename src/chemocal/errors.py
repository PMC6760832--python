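"""Exception hierarchy.

All chemocal-specific failures derive from :class:`ChemocalError` so callers
can catch the whole family; each subclass also derives from the matching
builtin (ValueError / RuntimeError) for idiomatic handling.
"""


class ChemocalError(Exception):
    """Base class for all chemocal errors."""


class GridError(ChemocalError, ValueError):
    """Wavelength grid is non-uniform, non-increasing, or does not match a request."""


class ParseError(ChemocalError, ValueError):
    """A CSV cell or header could not be interpreted."""


class ValidationError(ChemocalError, ValueError):
    """A domain invariant is violated (non-positive concentration, non-finite absorbance, ...)."""


class ShapeMismatchError(ChemocalError, ValueError):
    """Array dimensions are inconsistent with the fitted model or container."""


class ParameterError(ChemocalError, ValueError):
    """A tuning parameter is out of its feasible range."""


class RankDeficiencyError(ChemocalError, ValueError):
    """More latent variables requested than the data support."""


class DegenerateDataError(ChemocalError, ValueError):
    """Input carries no usable variation (single sample, all-zero response, ...)."""


class SolverError(ChemocalError, RuntimeError):
    """Iterative optimisation failed to reach its tolerance."""


class ConfigurationError(ChemocalError, ValueError):
    """Inconsistent configuration (mismatched component/analyte names, unknown variant, ...)."""
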