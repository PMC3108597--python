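"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`MthapError`
so callers can distinguish bad input from bugs.
"""


class MthapError(Exception):
    """Base class for all package errors."""


class InputError(MthapError):
    """Empty or unreadable input."""


class AlignmentError(MthapError):
    """Sequences do not form a valid alignment (length mismatch, bad alphabet)."""


class MetadataError(MthapError):
    """Sample metadata missing or inconsistent with the sequence file."""


class CollapsingError(MthapError):
    """A sequence cannot be assigned to a haplotype (e.g. fully ambiguous)."""


class SampleSizeError(MthapError):
    """A statistic was requested for too few individuals."""


class SaturationError(MthapError):
    """A model-corrected distance is undefined (log of a non-positive number)."""


class DesignError(MthapError):
    """The hierarchical design is degenerate (a level with a single unit, empty unit)."""


class UndefinedStatisticError(MthapError):
    """The requested statistic is undefined for this input (e.g. no variation)."""


class ParameterError(MthapError):
    """An invalid tuning parameter was supplied."""


class ConfigError(MthapError):
    """An invalid simulation configuration."""
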