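"""Exception hierarchy shared across the package."""


class IntronRankError(Exception):
    """Base class for all package errors."""


class NotFoundError(IntronRankError):
    """Requested gene/transcript (or reference construct) absent from input."""


class UnusableModelError(IntronRankError):
    """Gene model cannot support intron analysis (e.g. single exon)."""


class MalformedAnnotationError(IntronRankError):
    """Annotation violates structural assumptions (e.g. overlapping exons)."""


class BuildMismatchError(IntronRankError):
    """Inputs disagree on genome build; no silent liftover is performed."""


class FormatError(IntronRankError):
    """Tabular input does not match the expected layout."""


class EmptyAnalysisError(IntronRankError):
    """No scored intronic variants remain; nothing to test."""


class DegenerateAnalysisError(IntronRankError):
    """Data admit no informative test (e.g. zero pooled variance)."""
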