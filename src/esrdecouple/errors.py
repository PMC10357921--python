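"""Typed exceptions raised by the esrdecouple pipeline."""


class EsrDecoupleError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EsrDecoupleError, ValueError):
    """An input value violates a precondition (non-finite, non-positive, ...)."""


class LevelOverflowError(EsrDecoupleError, ValueError):
    """A requested decomposition level exceeds the maximum for the signal length."""


class SelectionError(EsrDecoupleError, ValueError):
    """A wavelet-component selection is inconsistent (overlap, out of range)."""


class CombinatorialOverflowError(EsrDecoupleError, ValueError):
    """The multiplet of a spin system has more lines than the configured cap."""


class UnsupportedSymmetryError(EsrDecoupleError, ValueError):
    """A tensor shape other than isotropic/axial was supplied."""


class GridSpanError(EsrDecoupleError, ValueError):
    """The field grid does not span the resonance positions plus margin."""


class InsufficientLinesError(EsrDecoupleError, ValueError):
    """Fewer resonance lines were detected than the operation requires."""


class SpectrumFormatError(EsrDecoupleError, ValueError):
    """A spectrum file could not be parsed."""
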