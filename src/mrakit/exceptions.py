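"""Exception hierarchy for mrakit.

All package errors derive from :class:`MraError` so callers can catch one
base class at CLI or pipeline boundaries.
"""


class MraError(Exception):
    """Base class for all mrakit errors."""


class DataError(MraError):
    """Invalid or incomplete measurement data (non-positive values, missing cells...)."""


class DesignError(MraError):
    """Inconsistent experimental design (perturbation map, replicate structure...)."""


class InferenceError(MraError):
    """Network inference failed (singular or ill-conditioned response matrix)."""


class SaturationError(MraError):
    """A predicted relative change left the (-2, 2) range representable by the
    symmetric relative difference, so no abundance can be reconstructed."""


class InstabilityError(MraError):
    """Too few bootstrap draws produced an invertible response matrix for
    percentile confidence intervals to be meaningful."""


class ParseError(MraError):
    """Malformed input file (condition map, measurement table...)."""


class UnscreenableError(MraError):
    """A candidate gene yields a singular response matrix and cannot be screened."""
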