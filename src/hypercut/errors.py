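"""Exception hierarchy shared across the pipeline stages."""


class HypercutError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HypercutError, ValueError):
    """A file on disk does not match the expected layout (page count, dtype, sidecar)."""


class ContractError(HypercutError, ValueError):
    """An operation precondition was violated by the caller."""


class CalibrationError(HypercutError, ValueError):
    """White/dark calibration is degenerate (e.g. an all-zero denominator plane)."""


class DegenerateGeometryError(HypercutError, ValueError):
    """Landmark geometry cannot define a line ROI (anchor points coincide)."""


class DegenerateDataError(HypercutError, ValueError):
    """Score populations carry no usable signal (e.g. all distances zero)."""


class CapabilityError(HypercutError, RuntimeError):
    """A delegated backend (t-SNE/UMAP) is not available in this environment."""
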