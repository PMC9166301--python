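"""Central registry of the toolkit's decision thresholds.

The published workflow relies on visual judgments ("the SI curve flattens",
"the plateau of the titration", "the negative is fully resolved").  Every such
judgment is operationalized here as one named number so that each report can
echo the exact thresholds it used.  All values are overridable per call.
"""

from __future__ import annotations

#: Relative SI gain per 25 V step below which the curve counts as flat
#: (the knee / inflection rule of the voltage titration).
KNEE_REL_GAIN: float = 0.10

#: A knee additionally requires a steep phase: some earlier step with relative
#: gain at least ``KNEE_STEEP_FACTOR * KNEE_REL_GAIN``; otherwise the curve is
#: judged to have no evident inflection (criterion (v) fallback) or to be flat.
KNEE_STEEP_FACTOR: float = 2.0

#: Moving-median window applied to SI curves before knee detection.
KNEE_SMOOTHING_WINDOW: int = 3

#: Minimum fraction of negative events strictly above the scale floor for the
#: negative population to count as fully resolved.
NEG_RESOLVED_MIN: float = 0.99

#: Maximum fraction of positive events piled up at the ADC ceiling for the
#: positive signal to count as on scale.
PILEUP_MAX: float = 0.001

#: Tolerance of the bead gain-range tool: separation distance within this
#: fraction of its maximum, and linearity distance varying at most this
#: fraction across the selected range.
LINEARITY_TOLERANCE: float = 0.05

#: Titration plateau: any concentration whose SI is within this fraction of
#: the maximum competes, and the lowest wins.
PLATEAU_TOLERANCE: float = 0.05

#: Percentage of events censored by the density correction.
CENSOR_FRACTION: float = 3.0

#: Neighbor count for the k-NN density estimate used by the censoring step.
DENSITY_K: int = 30

#: Default arcsinh cofactor for fluorescence channels.
ARCSINH_COFACTOR: float = 150.0

#: Reference brightness (primary-channel positive-negative median difference)
#: to which spread values are normalized.
SPREAD_REFERENCE_BRIGHTNESS: float = 10_000.0

#: Spread magnitude (in channel intensity units at reference brightness) above
#: which a detector is no longer considered "spread free" for panel checks.
SPREAD_WARN_SIGMA: float = 50.0

#: Detector full scale, 18-bit convention.
ADC_MAX: float = 262_144.0

#: Robust SD convention: half the 15.87-84.13 inter-percentile distance.
RSD_METHOD: str = "percentile"


def as_dict() -> dict:
    """All defaults as a plain dict, for echoing into reports."""
    return {
        k: v
        for k, v in globals().items()
        if k.isupper() and not k.startswith("_")
    }
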