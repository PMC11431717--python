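"""Exception hierarchy for platequant.

All package-specific failures derive from :class:`PlateQuantError` so callers
(and the CLI) can catch one base class.  Distinct subclasses separate
recoverable analysis outcomes (e.g. a well that never grew) from malformed
input.
"""


class PlateQuantError(Exception):
    """Base class for all platequant errors."""


class FormatError(PlateQuantError):
    """Input file does not match any supported dialect (missing columns etc.)."""


class DataError(PlateQuantError):
    """Input parsed but violates a data invariant (ragged wells, duplicate
    readings, non-monotone time, non-finite OD)."""


class LayoutError(PlateQuantError):
    """Plate-layout table violates its schema (duplicate well, bad role,
    positive dilution exponent, empty table)."""


class NoGrowthError(PlateQuantError):
    """No exponential-phase window could be found in a well; distinct from a
    censored threshold crossing (a well may cross late yet have a fit, or
    never leave baseline at all)."""


class UndefinedRatioError(PlateQuantError):
    """A ratio of crossing times was requested but one crossing is censored."""


class CalibrationError(PlateQuantError):
    """No contiguous dilution run satisfied the linear-range acceptance rule.

    Carries per-candidate diagnostics in ``self.diagnostics`` (list of dicts
    with run, slope and R^2) so the failure is inspectable.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class DomainError(PlateQuantError):
    """Argument outside its mathematical domain (non-positive counts, p0 not
    in (0,1), zero sectors, ...)."""
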