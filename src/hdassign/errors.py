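"""Exception hierarchy for hdassign.

All data-dependent failures derive from :class:`DataError` so the CLI can map
them to a single exit code, distinct from usage errors.
"""


class DataError(Exception):
    """A problem with input data (format, consistency, or geometry)."""


class FormatError(DataError):
    """A file is missing or does not parse as its declared format."""


class ConsistencyError(DataError):
    """Files parse individually but disagree with each other."""


class ConfigError(DataError):
    """A configuration value is invalid or unknown."""
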