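"""Exception hierarchy shared across the package."""


class DroughtRankError(Exception):
    """Base class for all droughtrank errors."""


class FormatError(DroughtRankError):
    """Input file is structurally malformed (missing columns, bad header)."""


class ParseError(DroughtRankError):
    """A cell could not be parsed; the message carries the offending row."""


class IntegrityError(DroughtRankError):
    """Duplicate keys or other violations of table uniqueness constraints."""


class SpecError(DroughtRankError):
    """An index appears in the data but is absent from the index spec."""


class DomainError(DroughtRankError, ValueError):
    """A formula was evaluated outside its mathematical domain."""


class DegenerateRangeError(DroughtRankError):
    """min == max: a membership transform has no range to normalize over."""


class DegenerateInputError(DroughtRankError):
    """Constant column or otherwise rank-deficient input to PCA."""


class ParameterError(DroughtRankError, ValueError):
    """An argument is outside its documented range."""


class InsufficientDataError(DroughtRankError):
    """Too few observations for the requested statistic."""


class ConfigError(DroughtRankError):
    """Invalid pipeline or simulation configuration."""


class PipelineError(DroughtRankError):
    """A pipeline stage failed; the message names the stage and context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
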