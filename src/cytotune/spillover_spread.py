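"""Spillover estimation, compensation, and spillover-spreading (RIM) mapping.

Spillover is the *mean* signal a fluorochrome leaks into other detectors; it
is removed exactly by multiplying observed vectors with the inverse of the
spillover matrix.  Spread is the *variance* that leaking photons add to the
receiving detector; being noise, it survives compensation and erodes the
resolution of double-positive (DP) populations while leaving single-positive
(SP) resolution intact.  The spread map (RIM) quantifies, per affecting dye
and affected detector, the added robust SD at a reference brightness and the
resulting DP stain-index reduction, and drives the panel-assignment rules:

  (i)   dim / low-density markers must sit on detectors that are spread-free
        from co-expressed markers' dyes,
  (ii)  bright markers should sit on dyes that generate little total spread,
  (iii) low-density antigens belong on bright dyes,
  (iv)  high-density antigens belong on dim dyes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .exceptions import (
    ConfigError,
    NonInvertibleError,
    PanelSpecError,
    UnusableControlError,
)
from .fcs_io import EventTable
from .robust_stats import PopulationSplit, robust_sd, split_pos_neg, stain_index

__all__ = [
    "SpilloverMatrix",
    "SpreadMatrix",
    "PanelAssignment",
    "PanelSpec",
    "PanelWarning",
    "estimate_spillover",
    "compensate",
    "spread_matrix",
    "dp_resolution_impact",
    "check_panel",
]


@dataclass
class SpilloverMatrix:
    """n x n spillover coefficients, rows = fluorochromes, cols = detectors.

    Entry [f, d] is the fraction of fluorochrome f's primary-detector signal
    appearing in detector d; the diagonal (each dye in its own detector) is
    exactly 1.
    """

    fluorochromes: list[str]
    detectors: list[str]
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = len(self.fluorochromes)
        if self.coefficients.shape != (n, len(self.detectors)):
            raise ConfigError("coefficient shape does not match labels")
        if not np.allclose(np.diag(self.coefficients), 1.0):
            raise ConfigError("spillover diagonal must be exactly 1")
        if np.any(self.coefficients < 0):
            raise ConfigError("spillover entries must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.coefficients, index=self.fluorochromes,
                            columns=self.detectors)

    def inverse(self) -> np.ndarray:
        cond = np.linalg.cond(self.coefficients)
        if not np.isfinite(cond) or cond > 1e12:
            raise NonInvertibleError(
                f"spillover matrix is singular (condition number {cond:.3g})")
        return np.linalg.inv(self.coefficients)


def _split_for(table: EventTable, detector: str, splits, fluor: str
               ) -> PopulationSplit:
    if isinstance(splits, dict) and fluor in splits:
        return splits[fluor]
    method = splits if isinstance(splits, str) else "truth"
    if method == "truth":
        truth = table.meta.get("truth_pos")
        if truth is None:
            raise ConfigError(
                f"no truth labels for single stain {fluor!r}; pass explicit "
                "splits or split method")
        return split_pos_neg(table.column(detector), "truth", truth=truth)
    return split_pos_neg(table.column(detector), method)


def estimate_spillover(
    single_stains: dict[str, EventTable],
    splits: dict[str, PopulationSplit] | str = "truth",
    detector_of: dict[str, str] | None = None,
) -> SpilloverMatrix:
    """Estimate the spillover matrix from single-stain controls.

    ``coefficient[f, d] = (median_d(pos) - median_d(neg)) /
    (median_primary(pos) - median_primary(neg))``.  The primary detector is
    the channel whose fluorochrome matches (overridable via ``detector_of``).
    Negative estimates are clipped to 0 with a warning; a control whose
    primary-channel median difference is not positive raises
    :class:`UnusableControlError`.
    """
    fluors = list(single_stains)
    if not fluors:
        raise ConfigError("no single-stain controls supplied")
    detectors = single_stains[fluors[0]].detector_names
    coeff = np.zeros((len(fluors), len(detectors)))
    for i, f in enumerate(fluors):
        table = single_stains[f]
        if table.detector_names != detectors:
            raise ConfigError("single stains must share the channel layout")
        primary = (detector_of or {}).get(f)
        if primary is None:
            for ch in table.channels:
                if ch.fluorochrome == f:
                    primary = ch.detector
                    break
        if primary is None:
            raise ConfigError(f"cannot locate the primary detector for {f!r}")
        split = _split_for(table, primary, splits, f)
        deltas = np.array([
            np.median(table.column(d)[split.positive])
            - np.median(table.column(d)[split.negative])
            for d in detectors
        ])
        dp = deltas[detectors.index(primary)]
        neg_rsd = robust_sd(table.column(primary)[split.negative])
        if dp <= 2.0 * neg_rsd:
            raise UnusableControlError(
                f"single stain for {f!r} has no usable positive signal in "
                f"its primary detector {primary} (median difference "
                f"{dp:.3g} <= 2 x negative rSD {neg_rsd:.3g})")
        row = deltas / dp
        if np.any(row < 0):
            warnings.warn(
                f"negative spillover estimates for {f!r} clipped to 0",
                stacklevel=2)
            row = np.clip(row, 0.0, None)
        row[detectors.index(primary)] = 1.0
        coeff[i] = row
    return SpilloverMatrix(fluorochromes=fluors, detectors=detectors,
                           coefficients=coeff)


def compensate(table: EventTable, matrix: SpilloverMatrix) -> EventTable:
    """Apply spillover compensation on the linear scale.

    ``compensated = observed @ inverse(matrix)``; negative results are kept
    (no truncation).  Channel order must match the matrix detectors.
    """
    if table.detector_names != matrix.detectors:
        raise ConfigError(
            "table channels do not match the spillover matrix detectors")
    inv = matrix.inverse()
    comp = table.data @ inv
    out = table.with_data(comp, compensated=True)
    return out


@dataclass
class SpreadEntry:
    sigma_spread: float
    dp_si_drop: float
    missing: bool = False


@dataclass
class SpreadMatrix:
    """Affecting fluorochrome x affected detector spread map (the RIM)."""

    fluorochromes: list[str]
    detectors: list[str]
    entries: dict[tuple[str, str], SpreadEntry]
    reference_brightness: float

    def sigma(self, fluor: str, detector: str) -> float:
        return self.entries[(fluor, detector)].sigma_spread

    def to_dataframe(self) -> pd.DataFrame:
        mat = np.array([[self.entries[(f, d)].sigma_spread
                         for d in self.detectors]
                        for f in self.fluorochromes])
        return pd.DataFrame(mat, index=self.fluorochromes,
                            columns=self.detectors)

    def drop_dataframe(self) -> pd.DataFrame:
        mat = np.array([[self.entries[(f, d)].dp_si_drop
                         for d in self.detectors]
                        for f in self.fluorochromes])
        return pd.DataFrame(mat, index=self.fluorochromes,
                            columns=self.detectors)


def spread_matrix(
    single_stains: dict[str, EventTable],
    matrix: SpilloverMatrix,
    splits: dict[str, PopulationSplit] | str = "truth",
    reference_brightness: float = defaults.SPREAD_REFERENCE_BRIGHTNESS,
) -> SpreadMatrix:
    """Quantify spillover spreading from compensated single stains.

    For each affecting fluorochrome f and affected detector d:

        sigma_spread[f, d] = sqrt(max(rsd_d(pos)^2 - rsd_d(neg)^2, 0))
                             * sqrt(reference_brightness / brightness_f)

    computed on compensated data, where brightness_f is the control's
    primary-channel positive-negative median difference (spread grows with
    the square root of brightness, so entries are comparable at the stated
    reference).  ``dp_si_drop`` is the implied relative SI loss of a
    double-positive population whose negative-side robust SD is the
    measured rsd_d(neg):  1 - rsd / sqrt(rsd^2 + sigma_ref^2).  Diagonal
    entries are 0 by convention; fluorochromes with no control are flagged
    missing, not silently zero.
    """
    entries: dict[tuple[str, str], SpreadEntry] = {}
    detectors = matrix.detectors
    for f in matrix.fluorochromes:
        if f not in single_stains:
            for d in detectors:
                entries[(f, d)] = SpreadEntry(float("nan"), float("nan"),
                                              missing=True)
            continue
        raw = single_stains[f]
        primary = detectors[matrix.fluorochromes.index(f)]
        split = _split_for(raw, primary, splits, f)
        comp = compensate(raw, matrix)
        prim = comp.column(primary)
        brightness = float(np.median(prim[split.positive])
                           - np.median(prim[split.negative]))
        if brightness <= 0:
            raise UnusableControlError(
                f"compensated control for {f!r} lost its positive signal")
        scale = np.sqrt(reference_brightness / brightness)
        for d in detectors:
            if d == primary:
                entries[(f, d)] = SpreadEntry(0.0, 0.0)
                continue
            col = comp.column(d)
            rsd_pos = robust_sd(col[split.positive])
            rsd_neg = robust_sd(col[split.negative])
            sigma = float(np.sqrt(max(rsd_pos ** 2 - rsd_neg ** 2, 0.0)))
            sigma_ref = sigma * scale
            drop = 1.0 - rsd_neg / np.sqrt(rsd_neg ** 2 + sigma_ref ** 2) \
                if rsd_neg > 0 else (1.0 if sigma_ref > 0 else 0.0)
            entries[(f, d)] = SpreadEntry(sigma_ref, float(drop))
    return SpreadMatrix(fluorochromes=list(matrix.fluorochromes),
                        detectors=list(detectors), entries=entries,
                        reference_brightness=reference_brightness)


def dp_resolution_impact(
    config,
    affecting: str,
    affected: str,
    dim_marker_si_without_spread: float = 20.0,
    n_events: int = 40_000,
    seed: int = 0,
    voltage: float | None = None,
):
    """Simulated DP-versus-SP resolution cost of one spillover path.

    Simulates four equally frequent populations (double negative, affecting-
    only, affected-only, double positive), compensates with the model's own
    mixing matrix, and returns ``(si_dp, si_sp)`` in the affected channel:
    ``si_dp`` resolves the double positive against the affecting-only
    population (whose spread inflates the baseline), ``si_sp`` resolves the
    affected-only single positive against the double negative.  Spread hurts
    the former and not the latter.

    The affected dye's brightness is set so that its SI without spread is
    approximately ``dim_marker_si_without_spread``.
    """
    from . import simulator as sim

    config = _config_with_dim_brightness(
        config, affected, dim_marker_si_without_spread, voltage)
    f_aff = config.fluorochromes[config.detector_index(affected)]
    pops = [
        sim.PopulationSpec("nn", 0.25, {}),
        sim.PopulationSpec("f_only", 0.25, {affecting: 1.0}),
        sim.PopulationSpec("d_only", 0.25, {f_aff: 1.0}),
        sim.PopulationSpec("dp", 0.25, {affecting: 1.0, f_aff: 1.0}),
    ]
    v = voltage or config.v_ref
    vmap = {d: v for d in config.detector_names}
    table = sim.simulate_acquisition(config, pops, vmap, n_events, seed)

    # measured-unit mixing matrix implied by the model (gains are equal at a
    # common voltage, so it equals the truth spillover)
    g = np.array([(vmap[d] / config.v_ref) ** config.gamma[i]
                  for i, d in enumerate(config.detector_names)])
    mixing = config.spillover * g[None, :] / g[:, None]
    sm = SpilloverMatrix(config.fluorochromes, config.detector_names, mixing)
    comp = compensate(table, sm)

    pop = table.meta["population"]
    col = comp.column(affected)
    si_dp = stain_index(col[pop == "dp"], col[pop == "f_only"]).si
    si_sp = stain_index(col[pop == "d_only"], col[pop == "nn"]).si
    return float(si_dp), float(si_sp)


def _config_with_dim_brightness(config, affected, target_si, voltage):
    """Set the affected dye's brightness to hit a target spread-free SI."""
    from dataclasses import replace as _replace

    from . import simulator as sim

    d = config.detector_index(affected)
    v = voltage or config.v_ref
    g = (v / config.v_ref) ** config.gamma[d]
    q_lo = sim.analytic_quantile(config, affected, v, 0.1587)
    q_hi = sim.analytic_quantile(config, affected, v, 0.8413)
    rsd_neg = (q_hi - q_lo) / 2.0
    brightness = dict(config.brightness)
    f_aff = config.fluorochromes[d]
    brightness[f_aff] = max(target_si * 2.0 * rsd_neg / g, 1e-9)
    return _replace(config, brightness=brightness)


# ---------------------------------------------------------------------------
# panel assignment QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelAssignment:
    fluorochrome: str
    brightness_class: str  # "dim" | "bright"
    density_class: str     # "low" | "high"

    def __post_init__(self):
        if self.brightness_class not in ("dim", "bright"):
            raise PanelSpecError(
                f"brightness_class must be dim/bright, "
                f"got {self.brightness_class!r}")
        if self.density_class not in ("low", "high"):
            raise PanelSpecError(
                f"density_class must be low/high, got {self.density_class!r}")


@dataclass
class PanelSpec:
    """Marker -> dye assignments plus expected co-expression pairs."""

    assignments: dict[str, PanelAssignment]
    coexpression: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        dyes = [a.fluorochrome for a in self.assignments.values()]
        if len(set(dyes)) != len(dyes):
            raise PanelSpecError("each fluorochrome may carry one marker only")
        for pair in self.coexpression:
            for m in pair:
                if m not in self.assignments:
                    raise PanelSpecError(
                        f"co-expression references unassigned marker {m!r}")


@dataclass(frozen=True)
class PanelWarning:
    rule: str
    markers: tuple
    message: str


def check_panel(
    panel: PanelSpec,
    spread: SpreadMatrix,
    spread_threshold: float = defaults.SPREAD_WARN_SIGMA,
) -> list[PanelWarning]:
    """Audit a panel against the spread map and assignment rules (i)-(iv).

    Emits one warning per violation; an empty list means the panel respects
    all four rules at the given spread threshold.
    """
    fluor_to_det = dict(zip(spread.fluorochromes, spread.detectors))
    warnings_out: list[PanelWarning] = []

    def sigma(f: str, d: str) -> float:
        e = spread.entries.get((f, d))
        return 0.0 if e is None or e.missing else e.sigma_spread

    for marker, a in panel.assignments.items():
        det = fluor_to_det.get(a.fluorochrome)
        is_dim_target = a.brightness_class == "dim" or a.density_class == "low"
        if det is not None and is_dim_target:
            for pair in panel.coexpression:
                if marker not in pair:
                    continue
                (other,) = set(pair) - {marker} or {marker}
                other_dye = panel.assignments[other].fluorochrome
                s = sigma(other_dye, det)
                if s > spread_threshold:
                    warnings_out.append(PanelWarning(
                        rule="i", markers=(marker, other),
                        message=(
                            f"rule (i): dim/low-density marker {marker!r} on "
                            f"{det} receives spread {s:.1f} (> "
                            f"{spread_threshold:g}) from co-expressed "
                            f"{other!r} ({other_dye})")))
        if a.brightness_class == "bright":
            row = sum(sigma(a.fluorochrome, d) for d in spread.detectors)
            if row > spread_threshold * max(len(spread.detectors) - 1, 1):
                warnings_out.append(PanelWarning(
                    rule="ii", markers=(marker,),
                    message=(
                        f"rule (ii): bright marker {marker!r} sits on "
                        f"{a.fluorochrome} whose total generated spread "
                        f"{row:.1f} exceeds the budget")))
        if a.density_class == "low" and a.brightness_class == "dim":
            warnings_out.append(PanelWarning(
                rule="iii", markers=(marker,),
                message=(
                    f"rule (iii): low-density antigen {marker!r} should be "
                    f"on a bright fluorochrome, not dim "
                    f"{a.fluorochrome}")))
        if a.density_class == "high" and a.brightness_class == "bright":
            warnings_out.append(PanelWarning(
                rule="iv", markers=(marker,),
                message=(
                    f"rule (iv): high-density antigen {marker!r} should be "
                    f"on a dim fluorochrome, not bright "
                    f"{a.fluorochrome}")))
    return warnings_out
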