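"""Named error conditions raised across the pipeline.

Each exception carries a stable machine-readable ``code`` so callers (and
the CLI) can dispatch on the condition without string-matching messages.
"""


class MecphageError(ValueError):
    code = "error"


class InfeasibleConfigError(MecphageError):
    """Synthetic config under which planted structures cannot fit."""

    code = "infeasible-config"


class TooShortError(MecphageError):
    """Sequence shorter than the k-mer size."""

    code = "too-short"


class IncompatibleSketchesError(MecphageError):
    """Sketches built with different k or sketch size."""

    code = "incompatible-sketches"


class EmptySampleError(MecphageError):
    """Sample column with zero total counts."""

    code = "empty-sample"


class InvalidInputError(MecphageError):
    """Abundance vector that cannot be normalized, or q < 0."""

    code = "invalid-input"


class InsufficientSamplesError(MecphageError):
    """Fewer samples than the statistic requires."""

    code = "insufficient-samples"


class DanglingReferenceError(MecphageError):
    """Record referencing an id absent from the dataset."""

    code = "dangling-reference"


class DuplicateIdError(MecphageError):
    code = "duplicate-id"


class ValidationError(MecphageError):
    """Input table failing schema validation (missing columns etc.)."""

    code = "validation"
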