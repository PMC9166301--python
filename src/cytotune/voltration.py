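"""SI-versus-voltage curves and automated PMT voltage selection.

A "voltage titration" acquires a single-stained sample at a grid of PMT
voltages (default 250-750 V in 25 V steps) and computes the stain index at
each one.  SI rises steeply while electronic noise dominates the unstained
population, then flattens once amplified photon noise takes over; the
selection criteria are

  (i)   choose the knee of the SI curve (further voltage only inflates
        signals without buying resolution),
  (ii)  the negative population must be fully resolved above the scale floor,
  (iii) the positive signal must stay within the linear range (no ADC
        pile-up),
  (iv)  the fluorochrome must emit primarily into its own detector,
  (v)   detectors with no evident knee fall back to the voltages chosen for
        neighbouring detectors of the same laser.

The knee, judged visually in practice, is operationalized here: after
moving-median smoothing, the knee is the lowest grid voltage after which the
relative SI gain per step stays below ``rel_gain_threshold`` — provided the
curve had a steep phase before it (some step with relative gain at least
twice the threshold).  Curves that never reach the threshold at all are flat
(degenerate; lowest voltage returned, flagged); curves that grow without a
steep-then-flat contrast (e.g. linearly) have no evident inflection and
trigger the criterion (v) fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .exceptions import (
    ConfigError,
    InsufficientDataError,
    UnresolvableDetectorError,
    UnseparablePopulationsError,
)
from .fcs_io import EventTable
from .robust_stats import PopulationSplit, StainIndexResult, split_pos_neg, stain_index

__all__ = [
    "OnScaleFlags",
    "SICurvePoint",
    "SICurve",
    "DetectorRecommendation",
    "VoltrationReport",
    "build_si_curve",
    "detect_knee",
    "check_on_scale",
    "check_primary_emission",
    "recommend_voltages",
]


@dataclass(frozen=True)
class OnScaleFlags:
    """Diagnostics of criteria (ii) and (iii) at one voltage."""

    neg_resolved_frac: float
    pileup_frac: float
    neg_resolved: bool
    pos_on_scale: bool


@dataclass
class SICurvePoint:
    voltage: float
    si: StainIndexResult | None
    on_scale: OnScaleFlags | None = None
    primary_ok: bool | None = None
    separable: bool = True
    note: str = ""

    @property
    def si_value(self) -> float:
        return self.si.si if self.si is not None else float("nan")


@dataclass
class SICurve:
    """Stain index as a function of voltage for one detector/fluorochrome."""

    detector: str
    fluorochrome: str
    points: list[SICurvePoint]

    @property
    def voltages(self) -> np.ndarray:
        return np.array([p.voltage for p in self.points])

    @property
    def si_values(self) -> np.ndarray:
        return np.array([p.si_value for p in self.points])

    def point_at(self, voltage: float) -> SICurvePoint:
        for p in self.points:
            if p.voltage == voltage:
                return p
        raise KeyError(f"no SI point at {voltage} V")


def check_on_scale(
    table: EventTable,
    detector: str,
    split: PopulationSplit,
    scale_min: float = 0.0,
    adc_max: float | None = None,
    neg_resolved_min: float = defaults.NEG_RESOLVED_MIN,
    pileup_max: float = defaults.PILEUP_MAX,
) -> OnScaleFlags:
    """Criteria (ii)/(iii): negative above the floor, positive off the ceiling.

    The negative is "fully resolved" when at least ``neg_resolved_min`` of
    negative events sit strictly above the scale floor; the positive is "on
    scale" when at most ``pileup_max`` of positive events pile up at the ADC
    ceiling.
    """
    if adc_max is None:
        adc_max = table.channel(detector).adc_max
    values = table.column(detector)
    neg = values[split.negative]
    pos = values[split.positive]
    neg_frac = float(np.mean(neg > scale_min)) if neg.size else 0.0
    pile_frac = float(np.mean(pos >= adc_max)) if pos.size else 0.0
    return OnScaleFlags(
        neg_resolved_frac=neg_frac,
        pileup_frac=pile_frac,
        neg_resolved=neg_frac >= neg_resolved_min,
        pos_on_scale=pile_frac <= pileup_max,
    )


def check_primary_emission(
    table: EventTable,
    fluorochrome: str,
    split: PopulationSplit,
) -> tuple[bool, dict[str, float]]:
    """Criterion (iv): the dye's strongest (background-subtracted) positive
    median must be in its assigned detector.

    Returns (primary_ok, per-detector background-subtracted positive medians).
    """
    if not np.any(split.positive):
        raise UnseparablePopulationsError(
            "primary-emission check requires a positive population"
        )
    assigned = None
    for ch in table.channels:
        if ch.fluorochrome == fluorochrome:
            assigned = ch.detector
            break
    if assigned is None:
        raise ConfigError(
            f"no channel is assigned fluorochrome {fluorochrome!r}")
    deltas = {}
    for ch in table.channels:
        col = table.column(ch.detector)
        deltas[ch.detector] = float(
            np.median(col[split.positive]) - np.median(col[split.negative]))
    primary = deltas[assigned]
    ok = all(primary > v for d, v in deltas.items() if d != assigned)
    return ok, deltas


def _resolve_split(table: EventTable, detector: str, split_method: str,
                   **split_kwargs) -> PopulationSplit:
    if split_method == "truth":
        truth = table.meta.get("truth_pos")
        if truth is None:
            raise ConfigError("split_method='truth' requires meta['truth_pos']")
        return split_pos_neg(table.column(detector), "truth", truth=truth)
    return split_pos_neg(table.column(detector), split_method, **split_kwargs)


def build_si_curve(
    series: list[EventTable],
    detector: str,
    split_method: str = "truth",
    neg_resolved_min: float = defaults.NEG_RESOLVED_MIN,
    pileup_max: float = defaults.PILEUP_MAX,
    scale_min: float = 0.0,
    **split_kwargs,
) -> SICurve:
    """One SI point per voltage, with on-scale and primary-emission diagnostics.

    Each table must carry its acquisition voltage (``meta['voltage']`` or the
    detector's ``$PnV``).  Voltages must be unique; points where the
    positive/negative split fails are flagged, never dropped silently.
    """
    if not series:
        raise ConfigError("empty voltage series")
    fluor = series[0].meta.get("fluorochrome") or \
        series[0].channel(detector).fluorochrome or ""
    entries = []
    for t in series:
        v = t.meta.get("voltage")
        if v is None:
            v = t.channel(detector).pmt_voltage
        if v is None:
            raise ConfigError("table lacks a voltage (meta or $PnV)")
        entries.append((float(v), t))
    voltages = [v for v, _ in entries]
    if len(set(voltages)) != len(voltages):
        dups = sorted({v for v in voltages if voltages.count(v) > 1})
        raise ConfigError(f"duplicate voltages in series: {dups}")
    entries.sort(key=lambda e: e[0])

    points = []
    for v, t in entries:
        try:
            split = _resolve_split(t, detector, split_method, **split_kwargs)
        except UnseparablePopulationsError as exc:
            points.append(SICurvePoint(voltage=v, si=None, separable=False,
                                       note=str(exc)))
            continue
        values = t.column(detector)
        si = stain_index(values[split.positive], values[split.negative])
        flags = check_on_scale(t, detector, split, scale_min=scale_min,
                               neg_resolved_min=neg_resolved_min,
                               pileup_max=pileup_max)
        try:
            primary_ok, _ = check_primary_emission(t, fluor, split) \
                if fluor else (None, None)
        except ConfigError:
            primary_ok = None
        points.append(SICurvePoint(voltage=v, si=si, on_scale=flags,
                                   primary_ok=primary_ok))
    return SICurve(detector=detector, fluorochrome=fluor, points=points)


def _moving_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def detect_knee(
    curve: SICurve,
    rel_gain_threshold: float = defaults.KNEE_REL_GAIN,
    smoothing_window: int = defaults.KNEE_SMOOTHING_WINDOW,
    steep_factor: float = defaults.KNEE_STEEP_FACTOR,
) -> tuple[float | None, dict]:
    """Locate the knee (inflection) of an SI curve.

    Returns ``(knee_voltage, diagnostics)``; the voltage is ``None`` when no
    inflection is evident (criterion (v) applies).  See the module docstring
    for the exact rule.
    """
    finite = [p for p in curve.points if np.isfinite(p.si_value)]
    if len(finite) < 4:
        raise InsufficientDataError(
            f"knee detection needs >= 4 finite SI points, got {len(finite)}")
    v = np.array([p.voltage for p in finite])
    s = _moving_median(np.array([p.si_value for p in finite]),
                       smoothing_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.diff(s) / np.where(s[:-1] != 0, s[:-1], np.nan)
    rel = np.nan_to_num(rel, nan=0.0)
    diag = {"voltages": v, "smoothed_si": s, "rel_gains": rel}

    # flat curve: total excursion below the per-step threshold
    if s.max() - s.min() < rel_gain_threshold * max(abs(s).max(), 1e-12):
        diag["degenerate"] = True
        return float(v[0]), diag
    above = np.where(rel >= rel_gain_threshold)[0]
    if above.size and above[-1] == rel.size - 1:
        diag["reason"] = "SI still gaining at the top of the grid"
        return None, diag
    knee_idx = int(above[-1]) + 1 if above.size else 0
    steep = np.where(rel >= steep_factor * rel_gain_threshold)[0]
    if not steep.size or steep[0] >= knee_idx:
        diag["reason"] = ("no steep-then-flat contrast; "
                          "no evident inflection point")
        return None, diag
    return float(v[knee_idx]), diag


@dataclass
class DetectorRecommendation:
    detector: str
    fluorochrome: str
    chosen_voltage: float
    knee_voltage: float | None
    criteria_flags: dict = field(default_factory=dict)
    primary_emission_ok: bool | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class VoltrationReport:
    """Per-detector voltage choices with full criterion attribution."""

    recommendations: dict[str, DetectorRecommendation]
    params: dict = field(default_factory=dict)

    def chosen(self, detector: str) -> float:
        return self.recommendations[detector].chosen_voltage

    def to_records(self) -> list[dict]:
        out = []
        for rec in self.recommendations.values():
            row = {
                "detector": rec.detector,
                "fluorochrome": rec.fluorochrome,
                "chosen_voltage": rec.chosen_voltage,
                "knee_voltage": rec.knee_voltage,
                "primary_emission_ok": rec.primary_emission_ok,
                "notes": "; ".join(rec.notes),
            }
            for k, flag in sorted(rec.criteria_flags.items()):
                row[f"criterion_{k}"] = flag
            out.append(row)
        return out


def _passes(point: SICurvePoint) -> bool:
    return (point.separable and point.on_scale is not None
            and point.on_scale.neg_resolved and point.on_scale.pos_on_scale
            and point.primary_ok is not False)


def _snap_to_grid(value: float, grid: np.ndarray) -> float:
    return float(grid[np.argmin(np.abs(grid - value))])


def recommend_voltages(
    curves: list[SICurve],
    laser_map: dict[str, str] | None = None,
    rel_gain_threshold: float = defaults.KNEE_REL_GAIN,
    smoothing_window: int = defaults.KNEE_SMOOTHING_WINDOW,
) -> VoltrationReport:
    """Apply selection criteria (i)-(v) to a set of SI curves.

    Detectors whose knee voltage fails the on-scale checks are moved to the
    nearest passing grid voltage (downwards for pile-up, upwards for an
    unresolved negative); detectors with no knee receive the median of the
    chosen voltages of the other detectors on the same laser (nearest by
    configured order), flagged (v).
    """
    laser_map = laser_map or {c.detector: "laser-1" for c in curves}
    order = [c.detector for c in curves]
    recs: dict[str, DetectorRecommendation] = {}
    pending: list[SICurve] = []

    for curve in curves:
        grid = curve.voltages
        try:
            knee, diag = detect_knee(curve, rel_gain_threshold,
                                     smoothing_window)
        except InsufficientDataError:
            knee, diag = None, {"reason": "too few finite points"}
        flags = {"i": knee is not None, "ii": True, "iii": True,
                 "iv": True, "v": False}
        notes = []
        if diag.get("degenerate"):
            notes.append("degenerate flat SI curve; lowest voltage kept")
        if knee is None:
            pending.append(curve)
            recs[curve.detector] = DetectorRecommendation(
                detector=curve.detector, fluorochrome=curve.fluorochrome,
                chosen_voltage=float("nan"), knee_voltage=None,
                criteria_flags=flags,
                notes=notes + [diag.get("reason", "no knee")])
            continue

        passing = np.array([_passes(p) for p in curve.points])
        if not passing.any():
            failing = {
                "neg_resolved": min((p.on_scale.neg_resolved_frac
                                     for p in curve.points if p.on_scale),
                                    default=0.0),
                "pileup": max((p.on_scale.pileup_frac
                               for p in curve.points if p.on_scale),
                              default=1.0),
            }
            raise UnresolvableDetectorError(
                f"{curve.detector}: no grid voltage passes the on-scale "
                f"criteria ({failing})")
        chosen = knee
        point = curve.point_at(knee)
        if not _passes(point):
            if point.on_scale is not None and not point.on_scale.pos_on_scale:
                below = [p for p in curve.points
                         if p.voltage < knee and _passes(p)]
                if below:
                    chosen = below[-1].voltage
                    flags["iii"] = False
                    notes.append(
                        f"positive pile-up at knee {knee:g} V; moved down "
                        f"to highest on-scale voltage {chosen:g} V")
            if chosen == knee:  # unresolved negative (or still failing)
                above = [p for p in curve.points
                         if p.voltage >= knee and _passes(p)]
                candidates = above or [p for p in curve.points if _passes(p)]
                chosen = candidates[0].voltage
                flags["ii"] = point.on_scale is None or \
                    point.on_scale.neg_resolved
                notes.append(
                    f"knee {knee:g} V failed checks; moved to nearest "
                    f"passing voltage {chosen:g} V")
        final = curve.point_at(chosen)
        flags["ii"] = bool(final.on_scale and final.on_scale.neg_resolved)
        flags["iii"] = bool(final.on_scale and final.on_scale.pos_on_scale)
        flags["iv"] = final.primary_ok is not False
        recs[curve.detector] = DetectorRecommendation(
            detector=curve.detector, fluorochrome=curve.fluorochrome,
            chosen_voltage=float(chosen), knee_voltage=float(knee),
            criteria_flags=flags,
            primary_emission_ok=final.primary_ok, notes=notes)

    # criterion (v): fall back to same-laser neighbours
    for curve in pending:
        det = curve.detector
        laser = laser_map.get(det, "laser-1")
        same_laser = [d for d in order
                      if d != det and laser_map.get(d, "laser-1") == laser
                      and np.isfinite(recs[d].chosen_voltage)]
        if not same_laser:
            raise UnresolvableDetectorError(
                f"{det}: no knee and no same-laser detector to fall back on")
        # nearest in configured order stand in for "closer wavelengths"
        same_laser.sort(key=lambda d: abs(order.index(d) - order.index(det)))
        nearest = same_laser[:max(2, min(3, len(same_laser)))]
        fallback = float(np.median([recs[d].chosen_voltage for d in nearest]))
        rec = recs[det]
        rec.chosen_voltage = _snap_to_grid(fallback, curve.voltages)
        rec.criteria_flags["v"] = True
        rec.notes.append(
            f"criterion (v): set in range with same-laser detectors "
            f"{nearest} -> {rec.chosen_voltage:g} V")

    return VoltrationReport(
        recommendations=recs,
        params={"rel_gain_threshold": rel_gain_threshold,
                "smoothing_window": smoothing_window,
                **{k.lower(): v for k, v in defaults.as_dict().items()
                   if k in ("NEG_RESOLVED_MIN", "PILEUP_MAX")}},
    )
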