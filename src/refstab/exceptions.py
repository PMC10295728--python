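"""Exception hierarchy.

``RefstabError`` is the base for everything the library raises on bad input
or bad data; the CLI maps it to exit status 1 (usage errors are handled by
click and exit 2).
"""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class ConfigError(RefstabError):
    """A configuration value is invalid; the message names the field."""


class DataError(RefstabError):
    """Input data violates a structural contract (missing column, duplicate
    key, unmapped sample, gene-set mismatch, ...)."""


class InsufficientDataError(DataError):
    """Too few genes, samples or groups for the requested computation."""
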