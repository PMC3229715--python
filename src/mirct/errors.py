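"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, statistical degeneracies exit 4.
"""


class MirctError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(MirctError):
    """Invalid parameter or configuration value."""


class ParseError(MirctError):
    """Malformed input table; the message names the offending location."""


class DataError(MirctError):
    """Structurally valid input that violates a pipeline precondition."""


class DegenerateStatisticError(MirctError):
    """A statistic could not be computed (e.g. zero variance everywhere)."""
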