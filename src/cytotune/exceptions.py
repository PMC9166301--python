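"""Exception hierarchy for cytotune.

Every error raised on purpose by the toolkit derives from :class:`CytotuneError`
so callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class CytotuneError(Exception):
    """Base class for all cytotune errors."""


class ConfigError(CytotuneError):
    """Invalid configuration value (frequencies, cofactors, counts, ...)."""


class FcsParseError(CytotuneError):
    """Malformed FCS file; the message names the offending segment/keyword."""


class UnsupportedFcsVersionError(FcsParseError):
    """File is FCS but not a supported 3.x dialect."""


class InvalidTableError(CytotuneError):
    """An EventTable violates its invariants (e.g. no channels on write)."""


class IncompatibleChannelsError(CytotuneError):
    """Tables with differing channel definitions cannot be combined."""


class EmptyInputError(CytotuneError):
    """An operation received an empty value list."""


class InsufficientDataError(CytotuneError):
    """Too few events / points / voltages for the requested statistic."""


class UnseparablePopulationsError(CytotuneError):
    """A positive/negative split could not be established."""


class PeakMergeError(CytotuneError):
    """Fewer separable bead peaks than requested; names colliding labels."""


class NoValidRangeError(CytotuneError):
    """Gain-range tool found no voltage satisfying its criteria."""


class UnusableControlError(CytotuneError):
    """A single-stain control has no usable positive signal."""


class NonInvertibleError(CytotuneError):
    """Spillover matrix is singular and cannot be used for compensation."""


class UnresolvableDetectorError(CytotuneError):
    """No grid voltage passes the on-scale criteria for a detector."""


class TitrationFailedError(CytotuneError):
    """No dilution in a titration series yielded separable populations."""


class PanelSpecError(CytotuneError):
    """Panel specification is internally inconsistent."""
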