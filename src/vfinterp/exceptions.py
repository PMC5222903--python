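"""Exception hierarchy for vfinterp."""


class VfinterpError(Exception):
    """Base class for all vfinterp errors."""


class GridConstructionError(VfinterpError):
    """Requested grid cannot be built under the symmetry constraints."""


class DegenerateGeometryError(VfinterpError):
    """Collinear, duplicate, or otherwise degenerate point configuration."""


class InsufficientDataError(VfinterpError):
    """Too few points/values for the requested operation."""


class InsufficientStructureError(VfinterpError):
    """Spatial structure too degenerate to estimate (e.g. all lags equal)."""


class SolverFailureError(VfinterpError):
    """A linear system remained singular after regularization attempts."""


class AlignmentError(VfinterpError):
    """Examinations or truth fields do not share the same location set."""


class SchemaError(VfinterpError):
    """A delimited file is missing required columns."""


class ValidationError(VfinterpError):
    """File contents violate a value constraint (e.g. negative dB)."""


class PairingError(VfinterpError):
    """Metric records cannot be paired exam-by-exam across methods."""
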