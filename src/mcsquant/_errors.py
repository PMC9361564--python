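"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: ConfigError -> 2, IOFormatError -> 3,
ConsistencyError -> 4 (see cli.main).
"""


class MCSQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(MCSQuantError):
    """Invalid or incomplete run configuration."""


class IOFormatError(MCSQuantError):
    """Unreadable or wrongly-typed input file."""


class ShapeMismatchError(MCSQuantError):
    """Operands that must share a pixel grid do not."""


class ConsistencyError(MCSQuantError):
    """Inputs that must agree (threshold, image id, bin count) do not."""


class TooSmallError(MCSQuantError):
    """Image smaller than the requested patch size."""

    def __init__(self, axis: str, size: int, needed: int):
        self.axis = axis
        super().__init__(
            f"image {axis} axis is {size} px, smaller than the required {needed} px"
        )


class UndefinedRatioError(MCSQuantError):
    """Contact ratio requested for a scene with no mitochondria boundary."""
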