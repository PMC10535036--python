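"""Exception hierarchy for the metabolodiv pipeline."""


class MetabolodivError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MetabolodivError):
    """A file does not conform to the expected table format."""


class ValidationError(MetabolodivError):
    """A data structure violates one of its invariants."""


class MergeError(MetabolodivError):
    """Feature tables cannot be merged (e.g. mismatched sample sets)."""


class ContrastError(MetabolodivError):
    """A pairwise contrast cannot be constructed or evaluated."""


class GenerationError(MetabolodivError):
    """Synthetic-data generation is infeasible under the given parameters."""


class UsageError(MetabolodivError):
    """The API was called in a way the analysis protocol forbids."""


class IntegrityError(MetabolodivError):
    """A summary report failed its internal bookkeeping checks."""
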