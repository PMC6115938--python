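"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration problems exit 2, malformed
or inconsistent data exit 3, a stage failing mid-run exits 4.
"""


class EnsipipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EnsipipeError):
    """Invalid configuration: bad threshold, unknown key, malformed spec."""


class DataError(EnsipipeError):
    """Malformed or inconsistent input data."""


class StageError(EnsipipeError):
    """A pipeline stage failed during execution."""


class NoOrthologsError(StageError):
    """No ortholog pair survived the thresholds; a mean identity is undefined."""


class UnmappableError(StageError):
    """No genome fragment mapped to the reference at the identity cutoff."""


class GprParseError(DataError):
    """Malformed gene-protein-reaction boolean expression."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position
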