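"""Exception hierarchy shared across the pipeline.

``ValidationError`` marks bad user input (malformed files, invariant
violations, impossible configurations) and maps to CLI exit code 1;
anything else escaping a stage is a runtime error (exit code 2).
"""


class TrimsigError(Exception):
    """Base class for all package errors."""


class ValidationError(TrimsigError):
    """Invalid input data or configuration."""


class RefMismatchError(ValidationError):
    """A mutation's stated reference base disagrees with the genome."""


class ContextUndefined(TrimsigError):
    """Trinucleotide context unavailable (contig edge or N base).

    This is a *skip signal*, not a hard error: callers count and report
    skipped records rather than aborting.
    """


class UndefinedStatistic(TrimsigError):
    """A statistic has no defined value on this input (e.g. no C→A
    mutations in a cohort, or an all-zero margin)."""
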