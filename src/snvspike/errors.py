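"""Exception types raised across the package."""

from __future__ import annotations


class SnvSpikeError(ValueError):
    """Base class for all package-specific errors."""


class ConfigError(SnvSpikeError):
    """Invalid simulator or pipeline configuration."""


class FormatError(SnvSpikeError):
    """Malformed input file; carries the path and 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where += ": "
        super().__init__(where + message)
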