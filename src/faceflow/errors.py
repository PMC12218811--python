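"""Exception types shared across the package."""


class FaceflowError(Exception):
    """Base class for all faceflow errors."""


class SchemaError(FaceflowError):
    """A file's structure does not match the expected schema."""


class MalformedInputError(FaceflowError):
    """Structurally valid file with semantically invalid content."""


class VocabularyError(FaceflowError):
    """A name falls outside a controlled vocabulary (region, category, label)."""


class ParameterError(FaceflowError):
    """An argument violates a documented precondition."""


class DataLeakError(FaceflowError):
    """Training data overlaps evaluation ground truth."""
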