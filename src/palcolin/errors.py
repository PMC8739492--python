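"""Exception hierarchy shared across the package."""


class PalcolinError(Exception):
    """Base class for all palcolin errors."""


class ParseError(PalcolinError):
    """A fixture or input file could not be parsed."""


class ValidationError(PalcolinError):
    """An input violated a structural invariant."""


class SegmentationError(PalcolinError):
    """Module segmentation could not be performed."""


class InputSequenceError(PalcolinError):
    """A protein sequence contained illegal characters or was empty."""


class AssemblyError(PalcolinError):
    """Forward assembly failed (state, role, substrate or termination error)."""


class TailoringError(PalcolinError):
    """A tailoring enzyme was applied to an ineligible target."""


class StructureError(PalcolinError):
    """A structure feature table is internally inconsistent."""


class PhyloError(PalcolinError):
    """Distance, tree building or classification failed."""


class SaturationError(PhyloError):
    """Observed divergence at or beyond the distance-correction singularity."""


class SimulationError(PalcolinError):
    """A synthetic-data generator was mis-configured."""
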