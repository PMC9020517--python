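"""Exception hierarchy shared across the package."""


class PhosphoUblError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhosphoUblError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PhosphoUblError):
    """A domain object violates one of its invariants."""


class ParameterError(PhosphoUblError):
    """An operation was called with an out-of-range parameter."""


class EmptyProfileError(PhosphoUblError):
    """No overlapping residues between two spectra -> no CSP profile."""


class MissingResidueError(PhosphoUblError):
    """A residue required by a residue set has no conformer pair."""


class UndefinedFractionError(PhosphoUblError):
    """Both conformer peak heights are zero; f_n is undefined."""


class ExchangeFitError(PhosphoUblError):
    """A ZZ-exchange series cannot be fitted (no usable timepoints)."""


class ImputationError(PhosphoUblError):
    """A column has too few observed values to parameterize imputation."""


class ZScoreError(PhosphoUblError):
    """A constant row cannot be z-scored."""
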