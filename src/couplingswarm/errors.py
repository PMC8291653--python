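"""Exception hierarchy for the competition-analysis toolkit."""


class CouplingSwarmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CouplingSwarmError):
    """Invalid generator or pipeline configuration."""


class FormatError(CouplingSwarmError):
    """Malformed input file (missing column, duplicate id, bad number)."""


class IncompleteSubmissionError(CouplingSwarmError):
    """A submission does not cover exactly the expected record ids."""


class InvalidSubmissionError(CouplingSwarmError):
    """A submission contains non-finite predicted values."""


class ScoringError(CouplingSwarmError):
    """The score is undefined for the requested selection."""


class DegenerateInputError(CouplingSwarmError):
    """An input is degenerate for the requested analysis (e.g. zero variance)."""


class InsufficientDataError(CouplingSwarmError):
    """Too few observations for the requested fit."""
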