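"""Exception hierarchy.

Config errors (bad dictionaries, malformed term sets, invalid simulation
parameters) are distinguished from data errors (unparseable report files,
empty inputs, zero contingency cells) so the command line can map them to
distinct exit codes.
"""


class PvSignalError(Exception):
    """Base class for all package errors."""


class ConfigError(PvSignalError):
    """Invalid configuration: term set, dictionary, stratum spec or sim config."""


class DataError(PvSignalError):
    """Invalid or insufficient data."""


class ReportFormatError(DataError):
    """A report file does not parse in the declared dialect."""

    def __init__(self, path, message):
        self.path = path
        super().__init__(f"{path}: {message}")


class EmptyInputError(DataError):
    """No valid reports (or no analysable records) after ingestion."""


class ZeroCellError(DataError):
    """A contingency cell is zero and no continuity correction was requested."""
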