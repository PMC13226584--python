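"""Exception hierarchy.

Config problems (bad designs, bad parameter values) and data problems
(malformed inputs, undefined distances) are kept distinct so the CLI can
map them to separate exit codes.
"""


class KmerBetaError(Exception):
    """Base class for all package errors."""


class ConfigError(KmerBetaError):
    """Invalid configuration or design parameters (CLI exit code 2)."""


class InvalidDesignError(ConfigError):
    """A CommunityDesign or ExperimentConfig violates its invariants."""


class DataError(KmerBetaError):
    """Malformed or unusable input data (CLI exit code 3)."""


class FormatError(DataError):
    """A file does not conform to its expected format."""


class UndefinedDistanceError(DataError):
    """A pairwise dissimilarity is undefined (e.g. both samples empty)."""


class UndefinedCorrelationError(DataError):
    """Correlation is undefined (zero variance in one of the vectors)."""
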