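"""Exception hierarchy for the EDNN VBM pipeline."""


class EDNNError(Exception):
    """Base class for all pipeline errors."""


class VolumeFileMissingError(EDNNError):
    """A referenced NIfTI file does not exist."""


class NonVolumeError(EDNNError):
    """The image on disk is not a 3-D scalar volume."""


class VolumeHeaderError(EDNNError):
    """The NIfTI header could not be parsed."""


class NaNVolumeError(EDNNError):
    """A loaded volume contains NaN and the NaN policy is 'error'."""


class GridMismatchError(EDNNError):
    """Two objects that must share a voxel grid do not."""


class EmptyMaskError(EDNNError):
    """Mask construction retained zero voxels."""


class ManifestError(EDNNError):
    """A cohort manifest violates its contract (duplicate ids, bad labels, missing paths)."""


class FeatureMismatchError(EDNNError):
    """A matrix was offered to a model trained on different feature columns."""


class DegenerateClassError(EDNNError):
    """An operation requiring both (or >=2 per) classes got a degenerate label vector."""
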