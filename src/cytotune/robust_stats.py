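"""Core descriptive statistics: percentiles, robust SD, stain index, splits.

The stain index

    SI = (median_pos - median_neg) / (2 * rSD_neg)

is the resolution figure of merit used throughout the toolkit: it measures how
far a stained population sits above the unstained one in units of the spread
of the unstained population.  ``rSD`` is the Gaussian-equivalent robust
standard deviation, half the distance between the 15.87th and 84.13th
percentiles (so it equals sigma for normal data); a MAD-based convention is
selectable for cross-checking against other software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .exceptions import (
    ConfigError,
    EmptyInputError,
    InsufficientDataError,
    UnseparablePopulationsError,
)

__all__ = [
    "StainIndexResult",
    "PopulationSplit",
    "percentile",
    "robust_sd",
    "stain_index",
    "split_pos_neg",
]

# percentile anchors whose half-distance equals sigma in the Gaussian limit
_RSD_LO = 15.87
_RSD_HI = 84.13


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile with (i-1)/(n-1) anchoring.

    This is the convention where the sorted order statistics are placed at
    probabilities (i-1)/(n-1) and intermediate quantiles are linearly
    interpolated; q=50 is the median.  Bead peak ratios depend on this exact
    convention, so it is fixed here rather than configurable.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("percentile of an empty value list")
    if not np.all(np.isfinite(arr)):
        raise ConfigError("percentile requires finite values")
    if not 0.0 <= q <= 100.0:
        raise ConfigError(f"percentile q={q} outside [0, 100]")
    return float(np.percentile(arr, q, method="linear"))


def robust_sd(values, method: str = defaults.RSD_METHOD) -> float:
    """Robust standard deviation of a value list.

    method="percentile" (default): (P84.13 - P15.87) / 2.
    method="mad": 1.4826 * median(|x - median(x)|).

    Both equal sigma in the Gaussian limit.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"robust_sd needs at least 2 values, got {arr.size}"
        )
    if method == "percentile":
        lo, hi = np.percentile(arr, [_RSD_LO, _RSD_HI], method="linear")
        return float(hi - lo) / 2.0
    if method == "mad":
        med = np.median(arr)
        return float(1.4826 * np.median(np.abs(arr - med)))
    raise ConfigError(f"unknown robust_sd method {method!r}")


@dataclass(frozen=True)
class StainIndexResult:
    """Stain index together with all of its ingredients.

    ``degenerate`` is set when the negative population has zero robust SD
    (noise-free simulations); the SI is then reported as +inf rather than
    raising, so voltage curves remain computable.
    """

    si: float
    median_pos: float
    median_neg: float
    rsd_neg: float
    n_pos: int
    n_neg: int
    degenerate: bool = False

    def __post_init__(self):
        if self.rsd_neg < 0:
            raise ConfigError("rsd_neg must be non-negative")


def stain_index(pos, neg, rsd_method: str = defaults.RSD_METHOD) -> StainIndexResult:
    """Stain index of a positive vs a negative population.

    Returns a :class:`StainIndexResult` carrying medians, the robust SD of the
    negative and both population sizes for auditability.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EmptyInputError("stain_index requires non-empty populations")
    med_pos = float(np.median(pos))
    med_neg = float(np.median(neg))
    rsd = robust_sd(neg, method=rsd_method) if neg.size >= 2 else 0.0
    if rsd > 0:
        si = (med_pos - med_neg) / (2.0 * rsd)
        degenerate = False
    else:
        si = float("inf") if med_pos > med_neg else (
            float("-inf") if med_pos < med_neg else 0.0
        )
        degenerate = True
    return StainIndexResult(
        si=si,
        median_pos=med_pos,
        median_neg=med_neg,
        rsd_neg=rsd,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        degenerate=degenerate,
    )


@dataclass
class PopulationSplit:
    """Per-event positive/negative assignment.

    ``labels`` holds one of {"positive", "negative", "excluded"} per event;
    ``threshold`` is the linear-scale intensity cut used (None for truth
    passthrough).
    """

    labels: np.ndarray
    method: str
    threshold: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def positive(self) -> np.ndarray:
        return self.labels == "positive"

    @property
    def negative(self) -> np.ndarray:
        return self.labels == "negative"


def _mixture_split(values: np.ndarray, cofactor: float) -> tuple[np.ndarray, float]:
    """Two-component 1-D location split via k-means on the arcsinh scale."""
    from sklearn.cluster import KMeans

    t = np.arcsinh(values / cofactor).reshape(-1, 1)
    # deterministic quantile initialisation
    init = np.percentile(t, [25, 75]).reshape(-1, 1)
    if init[0, 0] == init[1, 0]:
        raise UnseparablePopulationsError(
            "mixture split: value distribution has no spread"
        )
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=100)
    lab = km.fit_predict(t)
    med0, med1 = np.median(t[lab == 0]), np.median(t[lab == 1])
    if med0 > med1:  # relabel so cluster 1 is the high one
        lab = 1 - lab
        med0, med1 = med1, med0
    pooled = 0.5 * (robust_sd(t[lab == 0].ravel()) + robust_sd(t[lab == 1].ravel()))
    # a single Gaussian split in half yields gap ~2.2x the pooled rSD of the
    # halves, so genuine bimodality needs a wider gap than that
    if (med1 - med0) < 2.5 * pooled:
        raise UnseparablePopulationsError(
            "mixture split: component medians too close relative to their "
            f"pooled rSD ({med1 - med0:.3g} < 2.5 x {pooled:.3g} on the "
            "arcsinh scale)"
        )
    thr_t = 0.5 * (med0 + med1)
    thr = float(np.sinh(thr_t) * cofactor)
    return (values > thr), thr


def split_pos_neg(
    values,
    method: str = "mixture",
    truth=None,
    threshold: float | None = None,
    cofactor: float = defaults.ARCSINH_COFACTOR,
) -> PopulationSplit:
    """Split events into positive and negative populations.

    method="truth" passes provided boolean/str truth labels through,
    method="threshold" cuts at a fixed intensity, and method="mixture" fits a
    two-component one-dimensional location model (k-means on the arcsinh
    scale) and cuts at the midpoint of the component medians.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise EmptyInputError("split_pos_neg on an empty value list")
    if method == "truth":
        if truth is None:
            raise ConfigError("method='truth' requires truth labels")
        truth = np.asarray(truth)
        if truth.size != n:
            raise ConfigError("truth labels length does not match event count")
        if truth.dtype == bool:
            pos_mask = truth
        else:
            pos_mask = np.asarray(
                [str(t) in ("positive", "pos", "1", "True") for t in truth]
            )
        labels = np.where(pos_mask, "positive", "negative")
        return PopulationSplit(labels=labels, method="truth")
    if method == "threshold":
        if threshold is None:
            raise ConfigError("method='threshold' requires a threshold")
        labels = np.where(values > threshold, "positive", "negative")
        return PopulationSplit(labels=labels, method="threshold",
                               threshold=float(threshold))
    if method == "mixture":
        pos_mask, thr = _mixture_split(values, cofactor)
        labels = np.where(pos_mask, "positive", "negative")
        return PopulationSplit(labels=labels, method="mixture", threshold=thr)
    raise ConfigError(f"unknown split method {method!r}")
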