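"""Exception hierarchy shared across the package."""


class SardasError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(SardasError, ValueError):
    """A geometric constraint was violated (tumor outside breast, antenna inside phantom, ...)."""


class InputError(SardasError, ValueError):
    """Invalid input data (non-uniform time grid, mismatched records, empty grids, ...)."""
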