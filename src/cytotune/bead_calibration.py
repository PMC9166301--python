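"""Bead-based voltage optimization: gain-range tool and QSBC ratio refinement.

Two bead reagents drive this protocol.  A broad-spectrum multi-level ladder
(negative + five geometric intensity levels in every detector) is acquired
across a coarse voltage grid; per voltage the *separation distance* (log10
from the negative peak to the first positive peak) and the *linearity
distance* (log10 from the first to the second positive peak) are measured,
and the optimal range is where separation is maximal while linearity stays
constant.  Antibody-capture beads (QSBC, peaks M1 blank .. M5 brightest)
stained with the panel fluorochrome then refine the choice inside that range
via the ratios

    M2 ratio = MFI(M2) / p90(M1),     M5 ratio = MFI(M5) / p90(M1),

the highest ratios marking the optimal voltage.

Two conventions are fixed here and documented in the methods note: the
separation distance is anchored at the 90th percentile of the negative peak
(the same anchor the QSBC ratios use — a median anchor would be blind to the
electronic noise floor and the distance would never saturate), and voltages
whose brightest peak piles up at the ADC ceiling are excluded from both the
gain range and the QSBC refinement ("unless the signal was out of scale").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .exceptions import (
    ConfigError,
    InsufficientDataError,
    NoValidRangeError,
    PeakMergeError,
)
from .fcs_io import EventTable
from .robust_stats import percentile, robust_sd

__all__ = [
    "BeadPeak",
    "PeakLadder",
    "GainRangeResult",
    "QsbcRatios",
    "RefineResult",
    "detect_peaks",
    "gain_range_tool",
    "qsbc_ratios",
    "refine_voltage",
]


@dataclass(frozen=True)
class BeadPeak:
    label: str
    mfi: float
    p90: float
    rsd: float
    n: int
    clip_frac: float = 0.0


@dataclass
class PeakLadder:
    """Ordered bead peaks of one detector at one voltage."""

    detector: str
    voltage: float
    peaks: list[BeadPeak]

    def __post_init__(self):
        mfis = [p.mfi for p in self.peaks]
        if mfis != sorted(mfis):
            raise ConfigError("peaks must be ordered by increasing MFI")
        labels = [p.label for p in self.peaks]
        if len(set(labels)) != len(labels):
            raise ConfigError("peak labels must be unique")

    def peak(self, label: str) -> BeadPeak:
        for p in self.peaks:
            if p.label == label:
                return p
        raise KeyError(f"no peak labeled {label!r}")


def detect_peaks(
    table: EventTable,
    detector: str,
    n_peaks: int,
    label_style: str = "L0",
    cofactor: float = defaults.ARCSINH_COFACTOR,
) -> PeakLadder:
    """Partition one detector's events into ``n_peaks`` intensity peaks.

    One-dimensional k-means on the arcsinh scale, clusters relabeled by
    increasing median; MFI, 90th percentile and robust SD are computed on
    the linear values.  ``label_style`` "L0" labels peaks L0..L(n-1)
    (broad-ladder convention, negative = L0); "M1" labels them M1..Mn (QSBC
    convention, negative = M1).
    """
    from sklearn.cluster import KMeans

    if n_peaks < 2:
        raise ConfigError("n_peaks must be at least 2")
    values = table.column(detector)
    if values.size < 50 * n_peaks:
        raise InsufficientDataError(
            f"peak detection wants >= {50 * n_peaks} events, "
            f"got {values.size}")
    t = np.arcsinh(values / cofactor).reshape(-1, 1)
    init = np.percentile(
        t, np.linspace(100 / (2 * n_peaks), 100 - 100 / (2 * n_peaks),
                       n_peaks)).reshape(-1, 1)
    if np.unique(init).size < n_peaks:
        raise PeakMergeError(
            f"distribution supports fewer than {n_peaks} modes")
    km = KMeans(n_clusters=n_peaks, init=init, n_init=1, max_iter=200)
    lab = km.fit_predict(t)

    order = np.argsort([np.median(t[lab == k]) for k in range(n_peaks)])
    _check_mode_count(t.ravel(), lab, order, n_peaks, label_style)
    if label_style == "M1":
        labels = [f"M{i + 1}" for i in range(n_peaks)]
    else:
        labels = [f"L{i}" for i in range(n_peaks)]
    adc = table.channel(detector).adc_max
    peaks = []
    for rank, k in enumerate(order):
        vals = values[lab == k]
        peaks.append(BeadPeak(
            label=labels[rank],
            mfi=float(np.median(vals)),
            p90=percentile(vals, 90),
            rsd=robust_sd(vals),
            n=int(vals.size),
            clip_frac=float(np.mean(vals >= adc)),
        ))
    return PeakLadder(detector=detector,
                      voltage=float(table.meta.get("voltage")
                                    or table.channel(detector).pmt_voltage),
                      peaks=peaks)


def _check_mode_count(t: np.ndarray, lab: np.ndarray, order: np.ndarray,
                      n_peaks: int, label_style: str) -> None:
    """Reject partitions of distributions with fewer than n_peaks modes.

    A k-means partition always returns k clusters, even on a unimodal blob;
    genuine bead peaks must show up as distinct modes of the (smoothed)
    intensity histogram on the arcsinh scale.  The bin width follows the
    median within-cluster robust SD.
    """
    from scipy.signal import find_peaks

    rsds = [robust_sd(t[lab == k]) for k in range(n_peaks)
            if (lab == k).sum() > 1]
    bw = max(float(np.median(rsds)), 1e-3)
    nbins = int(np.clip((t.max() - t.min()) / (0.6 * bw), 10, 300))
    hist, _ = np.histogram(t, bins=nbins)
    smoothed = np.convolve(hist, np.ones(3) / 3, mode="same")
    modes, _ = find_peaks(smoothed, prominence=0.05 * smoothed.max())
    if len(modes) < n_peaks:
        meds = [np.median(t[lab == k]) for k in order]
        gaps = np.diff(meds)
        i = int(np.argmin(gaps))
        if label_style == "M1":
            a, b = f"M{i + 1}", f"M{i + 2}"
        else:
            a, b = f"L{i}", f"L{i + 1}"
        raise PeakMergeError(
            f"only {len(modes)} separable modes for {n_peaks} requested "
            f"peaks; closest colliding labels: {a} and {b}")


@dataclass
class GainRangeResult:
    """Per-voltage separation/linearity distances and the selected range."""

    detector: str
    voltages: np.ndarray
    separation_distance: np.ndarray  # log10 units
    linearity_distance: np.ndarray   # log10 units
    selected_range: tuple[float, float]
    flags: dict = field(default_factory=dict)


def _log_distances(ladder: PeakLadder, eps: float = 1e-6):
    if len(ladder.peaks) < 3:
        raise ConfigError("gain-range distances need >= 3 peaks "
                          "(negative + two positive)")
    neg, p1, p2 = ladder.peaks[0], ladder.peaks[1], ladder.peaks[2]
    sep = np.log10(max(p1.mfi, eps)) - np.log10(max(neg.p90, eps))
    lin = np.log10(max(p2.mfi, eps)) - np.log10(max(p1.mfi, eps))
    return sep, lin


def gain_range_tool(
    ladders: list[PeakLadder],
    linearity_tolerance: float = defaults.LINEARITY_TOLERANCE,
    pileup_max: float = defaults.PILEUP_MAX,
) -> GainRangeResult:
    """Select the optimal voltage range from per-voltage bead ladders.

    Candidates are voltages whose separation distance is within
    ``linearity_tolerance`` of its maximum and whose brightest peak stays on
    scale; the selected range is the longest contiguous candidate run over
    which the linearity distance varies by at most the same tolerance.
    """
    if len(ladders) < 3:
        raise InsufficientDataError(
            "gain-range tool needs at least 3 voltages")
    ladders = sorted(ladders, key=lambda l: l.voltage)
    v = np.array([l.voltage for l in ladders])
    if np.unique(v).size != v.size:
        raise ConfigError("duplicate voltages among ladders")
    sep, lin = map(np.array, zip(*[_log_distances(l) for l in ladders]))
    on_scale = np.array([l.peaks[-1].clip_frac <= pileup_max for l in ladders])

    sep_max = sep[on_scale].max() if on_scale.any() else sep.max()
    candidates = (sep >= (1 - linearity_tolerance) * sep_max) & on_scale
    if not candidates.any():
        raise NoValidRangeError(
            "no voltage combines near-maximal separation with an on-scale "
            f"top peak (max separation {sep.max():.3g} dex, "
            f"on-scale voltages: {v[on_scale].tolist()})")

    # longest contiguous candidate window with near-constant linearity
    best = None
    i = 0
    n = v.size
    while i < n:
        if not candidates[i]:
            i += 1
            continue
        j = i
        while j < n and candidates[j]:
            j += 1
        # sliding window within the run [i, j)
        lo = i
        for hi in range(i, j):
            while (lin[lo:hi + 1].max() - lin[lo:hi + 1].min()
                   > linearity_tolerance * abs(lin[lo:hi + 1]).max()):
                lo += 1
            if best is None or hi - lo > best[1] - best[0]:
                best = (lo, hi)
        i = j
    lo, hi = best
    flags = {}
    if lo == hi == n - 1:
        flags["saturation_not_reached"] = True
    if not on_scale.all():
        flags["clipped_voltages"] = v[~on_scale].tolist()
    return GainRangeResult(
        detector=ladders[0].detector, voltages=v,
        separation_distance=sep, linearity_distance=lin,
        selected_range=(float(v[lo]), float(v[hi])), flags=flags)


@dataclass(frozen=True)
class QsbcRatios:
    """M2/M5 separation ratios of a QSBC ladder at one voltage."""

    detector: str
    voltage: float
    m2_ratio: float
    m5_ratio: float
    m5_clip_frac: float = 0.0
    degenerate_negative: bool = False


def qsbc_ratios(ladder: PeakLadder) -> QsbcRatios:
    """M2 and M5 ratios: peak MFI over the negative bead's 90th percentile."""
    labels = [p.label for p in ladder.peaks]
    if labels != ["M1", "M2", "M3", "M4", "M5"]:
        raise ConfigError(
            f"QSBC ratios need exactly peaks M1..M5, got {labels}")
    m1, m2, m5 = ladder.peak("M1"), ladder.peak("M2"), ladder.peak("M5")
    if m1.p90 <= 0:
        return QsbcRatios(ladder.detector, ladder.voltage,
                          float("inf"), float("inf"),
                          m5_clip_frac=m5.clip_frac, degenerate_negative=True)
    return QsbcRatios(
        detector=ladder.detector, voltage=ladder.voltage,
        m2_ratio=m2.mfi / m1.p90, m5_ratio=m5.mfi / m1.p90,
        m5_clip_frac=m5.clip_frac)


@dataclass
class RefineResult:
    voltage: float
    m2_optimum: float
    m5_optimum: float
    tie: bool = False
    optima_disagree: bool = False
    excluded_voltages: list = field(default_factory=list)


def refine_voltage(
    ratio_series: list[QsbcRatios],
    pileup_max: float = defaults.PILEUP_MAX,
) -> RefineResult:
    """Pick the voltage with the highest M2 ratio within the QSBC series.

    Voltages whose M5 peak piles up at the ceiling are excluded first.  Ties
    on the M2 ratio are broken by the M5 ratio, then by the lower voltage;
    disagreement between the M2- and M5-optimal voltages is flagged, never
    silent.
    """
    if not ratio_series:
        raise ConfigError("empty QSBC ratio series")
    series = sorted(ratio_series, key=lambda r: r.voltage)
    usable = [r for r in series if r.m5_clip_frac <= pileup_max]
    excluded = [r.voltage for r in series if r.m5_clip_frac > pileup_max]
    if not usable:
        raise NoValidRangeError(
            "all QSBC voltages have the M5 peak out of scale")
    if len(usable) < 2:
        raise InsufficientDataError(
            "QSBC refinement needs >= 2 on-scale voltages")

    m2 = np.array([r.m2_ratio for r in usable])
    m5 = np.array([r.m5_ratio for r in usable])
    best_m2 = m2.max()
    tied = np.isclose(m2, best_m2, rtol=0, atol=0) | (m2 == best_m2)
    idx = np.where(tied)[0]
    tie = idx.size > 1
    if tie:
        best_m5 = m5[idx].max()
        idx = idx[m5[idx] == best_m5]
    chosen = usable[int(idx[0])]
    m5_opt = usable[int(np.argmax(m5))]
    return RefineResult(
        voltage=chosen.voltage,
        m2_optimum=usable[int(np.argmax(m2))].voltage,
        m5_optimum=m5_opt.voltage,
        tie=tie,
        optima_disagree=m5_opt.voltage != usable[int(np.argmax(m2))].voltage,
        excluded_voltages=excluded)
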