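"""Exception hierarchy for the anthromesh pipeline.

Every stage raises a subclass of :class:`AnthromeshError` so callers (and the
CLI) can report which stage failed without string matching.
"""


class AnthromeshError(Exception):
    """Base class for all anthromesh errors."""


class MeshFormatError(AnthromeshError):
    """A mesh file is malformed (bad facet block, truncated record, bad index)."""


class EmptyMeshError(AnthromeshError):
    """A mesh has no faces where geometry is required."""


class ParameterError(AnthromeshError):
    """An argument is outside its documented domain."""


class DetectionError(AnthromeshError):
    """A landmark rule failed to fire on the given silhouette."""

    def __init__(self, landmark: str, message: str):
        self.landmark = landmark
        super().__init__(f"{landmark}: {message}")


class SegmentationError(AnthromeshError):
    """Seed points violate the vertical-ordering invariant."""


class MeasurementError(AnthromeshError):
    """A girth/volume could not be derived (empty section, bad plane)."""


class UndefinedLossError(AnthromeshError):
    """No probe plane intersected both meshes; information loss is undefined."""
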