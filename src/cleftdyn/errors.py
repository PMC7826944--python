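"""Exception hierarchy.

Everything raised on purpose by this package derives from CleftdynError so
pipeline drivers can catch one type at the stage boundary.
"""


class CleftdynError(Exception):
    """Base class for all package errors."""


class PDBParseError(CleftdynError):
    """An ATOM/HETATM record could not be parsed; message names the line."""


class PDBFormatError(CleftdynError):
    """Structurally invalid PDB (e.g. inconsistent atom counts across models)."""


class TrajectoryFormatError(CleftdynError):
    """Unreadable or empty coordinate file."""


class TopologyError(CleftdynError):
    """Coordinate file does not match the supplied topology."""


class SelectionError(CleftdynError):
    """Malformed selection expression; message carries the token position."""


class MappingError(CleftdynError):
    """A selection cannot be resolved in a reference structure."""


class FitError(CleftdynError):
    """Superposition is underdetermined (too few or degenerate points)."""


class LayoutError(CleftdynError):
    """Synthetic system geometry cannot realise the requested distance."""
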