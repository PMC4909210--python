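"""Exception hierarchy for the choroid quantification pipeline."""


class ChorobinError(Exception):
    """Base class for all package-specific errors."""


class TraceError(ChorobinError):
    """Boundary traces are malformed (crossing, folded, or incomplete)."""


class PlacementError(ChorobinError):
    """Phantom lumen placement could not reach the target luminal fraction.

    Raised after a bounded number of rejection attempts; signals an
    over-dense configuration (target fraction unreachable for the
    configured band geometry and lumen sizes).
    """


class InsufficientLumensError(ChorobinError):
    """Fewer qualifying lumens than required for vessel sampling or
    layer segmentation; the scan is too thin or noisy to process."""


class SegmentationError(ChorobinError):
    """Inner/outer layer segmentation failed or is degenerate."""


class RoiError(ChorobinError):
    """Requested region of interest does not fit inside the image."""
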