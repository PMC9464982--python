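"""Exception hierarchy shared across the toolkit."""


class RTCurateError(Exception):
    """Base class for all toolkit errors."""


class FormatError(RTCurateError):
    """A file is not DICOM, or is not the expected DICOM modality."""


class ValidationError(RTCurateError):
    """Input violates a structural contract (duplicate labels, bad config...)."""


class GridMismatchError(RTCurateError):
    """Two volume masks do not share the same image grid."""


class ContourPlaneError(RTCurateError):
    """A contour plane cannot be assigned to any CT slice within tolerance."""


class MidlineError(RTCurateError):
    """No midline-defining structure is available; sidedness must be N/A."""


class CompletenessError(RTCurateError):
    """A required DICOM object is missing from a curated dataset."""


class IntegrityError(RTCurateError):
    """An internal DICOM reference cannot be resolved within a dataset."""


class NotFoundError(RTCurateError):
    """A lookup key (e.g. an MRN) is unknown to the store."""
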