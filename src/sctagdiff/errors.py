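"""Exception types shared across the package."""


class SctagdiffError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SctagdiffError):
    """A line of an on-disk file could not be parsed or violates an invariant."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class FormatError(SctagdiffError):
    """A multi-file on-disk representation is incomplete or inconsistent."""


class ConfigurationError(SctagdiffError):
    """Parameters are mutually inconsistent or outside their valid domain."""


class PipelineError(SctagdiffError):
    """An operation was applied to data in the wrong state (e.g. re-scaling)."""
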