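"""Exception hierarchy for npfp.

Every error raised by the library derives from :class:`NpfpError` so callers
can catch broadly; the leaf classes signal the specific contract violated.
"""


class NpfpError(Exception):
    """Base class for all npfp errors."""


class ParseError(NpfpError):
    """A SMILES string could not be parsed into a valid molecule."""


class DescriptorError(NpfpError):
    """A molecular descriptor could not be computed; names the descriptor."""


class LengthMismatchError(NpfpError):
    """Two fingerprints of different lengths were compared."""


class ZeroVectorError(NpfpError):
    """Cosine similarity requested for an all-zero vector."""


class EmptyReferenceError(NpfpError):
    """A fragment-frequency table was requested from an empty reference set."""


class ScoreUndefinedError(NpfpError):
    """A molecule yielded no fragments, so its NP-likeness is undefined."""


class EmptyDatasetError(NpfpError):
    """Dataset curation ended with an empty class."""


class SpecError(NpfpError):
    """A model specification is internally inconsistent."""


class ShapeError(NpfpError):
    """Network outputs and targets disagree in shape."""


class TrainingDivergedError(NpfpError):
    """Training produced a non-finite loss."""


class DimMismatchError(NpfpError):
    """Input dimensionality does not match the model's expectation."""


class DegenerateLabelsError(NpfpError):
    """A ranking metric needs at least one example of each class."""


class NoActivesError(NpfpError):
    """Enrichment requested for a ranking without any active molecule."""


class TargetTooSmallError(NpfpError):
    """A screening target has too few actives for query-wise evaluation."""
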