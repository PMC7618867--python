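"""Exception hierarchy.

Two failure families matter operationally: malformed *data* (exit code 1 from
the CLI) and malformed *configuration* (exit code 2). Everything raised by
this package derives from :class:`GazehabError`.
"""


class GazehabError(Exception):
    """Base class for all gazehab errors."""

    exit_code = 1


class DataError(GazehabError):
    """Input data violates a stated invariant (overlap, off-grid bound, ...)."""

    exit_code = 1


class ConfigError(GazehabError):
    """A configuration value or column mapping is invalid or missing."""

    exit_code = 2
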