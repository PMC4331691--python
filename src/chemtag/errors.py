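"""Exception hierarchy."""


class ChemtagError(Exception):
    """Base class for all package-specific errors."""


class CorpusFormatError(ChemtagError):
    """A corpus, annotation, or prediction file violates its TSV dialect."""


class AnnotationMismatchError(CorpusFormatError):
    """An annotation's surface string does not match the referenced span."""


class InvalidIOBError(ChemtagError):
    """A label sequence violates the IOB transition rules."""


class OverlapError(ChemtagError):
    """Mentions overlap where a non-overlapping set is required."""


class ModelFormatError(ChemtagError):
    """A persisted CRF model file is corrupt or has an unknown version."""


class ResourceError(ChemtagError):
    """A required resource file (dictionary, word list, pattern set) is missing."""
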