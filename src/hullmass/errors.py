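"""Exception hierarchy for hullmass.

All errors derive from :class:`HullmassError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest builtin (ValueError/OSError) for idiomatic handling.
"""


class HullmassError(Exception):
    """Base class for all hullmass errors."""


class MeshFormatError(HullmassError, ValueError):
    """A mesh file could not be parsed under its declared format."""


class DegenerateMeshError(HullmassError, ValueError):
    """A mesh is unusable for volumetrics (no faces, < 4 vertices, ...)."""


class DegenerateInputError(HullmassError, ValueError):
    """Hull input is coplanar/collinear; the enclosed volume is undefined."""


class TopologyError(HullmassError, ValueError):
    """A surface expected to be closed has unpaired edges."""


class ManifestError(HullmassError, ValueError):
    """A segment manifest is malformed or references missing files."""


class MissingUnitError(HullmassError, KeyError):
    """A functional unit required by the analysis is absent from a pose."""


class InsufficientDataError(HullmassError, ValueError):
    """Too few calibration rows to fit (n < 3)."""


class DomainError(HullmassError, ValueError):
    """A numeric argument is outside its physical domain (<= 0 mass, ...)."""


class RegistryError(HullmassError, KeyError):
    """A limb-equation id is unknown or its coefficients are unconfigured."""
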