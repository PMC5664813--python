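"""Exception hierarchy for the spikect pipeline.

Every failure mode a caller may want to catch separately gets its own
class; :class:`StageError` wraps a failure inside the composed
segmentation chain with the name of the stage that raised it.
"""


class SpikeCTError(Exception):
    """Base class for all spikect errors."""


class VolumeFormatError(SpikeCTError):
    """A scan file is missing, malformed, or in an unsupported format."""


class ParameterError(SpikeCTError):
    """A parameter violates its documented constraints."""


class NoBimodalityError(SpikeCTError):
    """The grey-value histogram has no two separated modes (bad scan)."""


class EmptyMaskError(SpikeCTError):
    """An operation that needs foreground voxels received an empty mask."""


class NoMaterialError(SpikeCTError):
    """No plant material detected above the (relaxed) threshold."""


class DegenerateShapeError(SpikeCTError):
    """A voxel set is too small or too flat for 3D axis fitting."""


class MeasurementError(SpikeCTError):
    """A per-grain measurement could not be taken (e.g. empty cross-section)."""


class PortionMismatchError(SpikeCTError):
    """Two scan portions cannot be rejoined (pitch/id/role conflict)."""


class PlacementError(SpikeCTError):
    """Phantom generation could not place all grains without overlap."""


class StageError(SpikeCTError):
    """A stage of a composed pipeline failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
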