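"""Typed errors raised across the package."""


class BatFruitNetError(Exception):
    """Base class for all package errors."""


class MatrixFormatError(BatFruitNetError):
    """A matrix or metadata file could not be parsed or violates an invariant."""


class DegenerateMatrixError(BatFruitNetError):
    """A matrix is too small (A < 2 or P < 2) for structural metrics."""


class NotComputableError(BatFruitNetError):
    """A metric is undefined for this input (e.g. H2' on binary-only data)."""
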