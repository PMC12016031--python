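"""Exception hierarchy shared across the package."""


class IslandmapError(Exception):
    """Base class for all islandmap errors."""


class FormatError(IslandmapError):
    """An input file violates its format contract.

    Carries the offending path and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class BoundsError(IslandmapError):
    """An interval lies outside its chromosome."""


class ConfigError(IslandmapError):
    """A configuration value is invalid or inconsistent."""


class UndefinedContentError(IslandmapError):
    """GC content is undefined (no non-N bases)."""


class UndefinedRatioError(IslandmapError):
    """O/E ratio is undefined (no C or no G in the sequence)."""
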