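"""Exception hierarchy shared across the pipeline stages."""


class NaadiffError(Exception):
    """Base class for all pipeline errors."""


class FormatError(NaadiffError):
    """A file or container does not conform to the expected on-disk layout."""


class ConsistencyError(NaadiffError):
    """Internally inconsistent dataset (e.g. transient referencing an undeclared condition)."""


class CorrectionError(NaadiffError):
    """A transient-level correction could not be estimated (e.g. water peak below SNR floor)."""


class FitError(NaadiffError):
    """A model fit failed to converge or the input is unusable for fitting."""


class GeometryError(NaadiffError):
    """Invalid fiber geometry input (e.g. empty VOI mask)."""


class DesignError(NaadiffError):
    """Degenerate experimental design (e.g. rank-deficient diffusion direction set)."""
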