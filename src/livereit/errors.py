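"""Exception hierarchy for livereit.

All package-specific failures derive from :class:`LiverEITError` so callers
can catch one base class at pipeline boundaries.
"""


class LiverEITError(Exception):
    """Base class for all livereit errors."""


class GeometryError(LiverEITError):
    """Invalid phantom geometry (self-intersection, region outside outline...)."""


class ResolutionError(LiverEITError):
    """Mesh too coarse to resolve a requested geometric feature."""


class PatternError(LiverEITError):
    """Invalid stimulation pattern parameters."""


class AssemblyError(LiverEITError):
    """FEM system could not be assembled or is singular after grounding."""


class ParameterError(LiverEITError):
    """Invalid numeric parameter (negative noise SD, non-positive sigma...)."""


class ConditioningError(LiverEITError):
    """Normal-equations solve failed; raise the regularization parameter."""


class DegenerateDataError(LiverEITError):
    """Statistical input is degenerate (zero variance, too few points)."""


class PlacementError(LiverEITError):
    """A region of interest falls outside the allowed anatomical region."""


class SchemaError(LiverEITError):
    """A table or file is missing required columns or rows."""


class InputError(LiverEITError):
    """A data file is malformed or inconsistent with the requested pattern."""
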