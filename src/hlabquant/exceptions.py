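"""Exception hierarchy for hlabquant.

All package-specific errors derive from :class:`HlabError` so callers can
catch pipeline failures with a single except clause while still letting
programming errors (TypeError etc.) propagate.
"""


class HlabError(Exception):
    """Base class for all hlabquant errors."""


class DesignError(HlabError, ValueError):
    """A synthetic-data design violates its invariants."""


class CalibrationError(HlabError, ValueError):
    """A bead standard set or fitted curve is unusable (too few standards,
    non-positive MFI in log-log mode, non-increasing signal)."""


class RangeError(HlabError, ValueError):
    """An MFI falls outside the calibrated range under policy='error'."""


class PairingError(HlabError, ValueError):
    """A specific stain record lacks its matched isotype control."""


class FitError(HlabError, RuntimeError):
    """A nonlinear fit failed to converge."""


class DomainError(HlabError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (e.g. non-positive decay rate, non-positive ratio denominator)."""


class ScanError(HlabError, ValueError):
    """A heavy-chain sequence cannot be scanned for an epitope motif
    (too short, or non-standard residue in the 77-83 window)."""


class DegenerateDataError(HlabError, ValueError):
    """Input data are degenerate for the requested statistic
    (e.g. zero within-group variance in every group)."""


class InsufficientDataError(HlabError, ValueError):
    """Fewer observations than the operation requires."""
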