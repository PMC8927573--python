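"""Exception hierarchy shared across the package."""


class SilmotifError(Exception):
    """Base class for all package errors."""


class TopologyError(SilmotifError):
    """Transmembrane-segment annotations are inconsistent with the sequence."""


class InputError(SilmotifError):
    """Malformed or contradictory user input (files, offsets, pair selectors)."""


class GeometryError(SilmotifError):
    """Degenerate 3D geometry (collinear points, zero-length bonds, bad angles)."""
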