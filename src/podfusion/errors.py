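"""Exception hierarchy shared across the pipeline."""


class PodfusionError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(PodfusionError):
    """Array dimensions do not match a contract (e.g. band count vs plane size)."""


class EmptyROIError(PodfusionError):
    """A region-of-interest mask selects no pixels."""


class DegenerateInputError(PodfusionError):
    """Input has no variation where the operation requires some
    (constant spectrum, constant ideal reference, single-class labels)."""


class InvalidClassError(PodfusionError):
    """Freshness class code outside {0, 1, 2, 3}."""


class ManifestError(PodfusionError):
    """Dataset manifest is inconsistent with the files it points to."""
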