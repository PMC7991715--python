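"""Exception types raised across the package."""


class RTClearError(Exception):
    """Base class for all package errors."""


class MachineSpecError(RTClearError):
    """Invalid or incomplete machine description file."""


class TravelLimitError(RTClearError):
    """Requested machine state is outside the machine's travel limits."""


class CTSeriesError(RTClearError):
    """Problem ingesting a CT series (mixed series, slice gaps, tags)."""


class ContourError(RTClearError):
    """Contour extraction or contour-stack validation failure."""


class MeshBuildError(RTClearError):
    """Lofting / triangulation failure."""
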