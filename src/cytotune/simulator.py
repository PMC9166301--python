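"""Synthetic cytometer: every input the toolkit consumes, with ground truth.

Signal model (per event, per detector ``d``, all on the linear scale):

    gain        g_d(V)   = (V / v_ref) ** gamma_d          (PMT power law)
    reference   S_d      = sum_f load_f * spill[f, d] + AF_d
    observed    x_d      = g_d * (S_d + eps_shot) + eps_bg
    clipped     x_d     -> min(max(x_d, scale_min), adc_max)

where ``load_f`` is the event's fluorophore load (log-normal cell-to-cell
variation around ``multiplier * brightness_f``), ``AF_d`` is log-normal
autofluorescence, ``eps_shot ~ N(0, sqrt(q_d * S_d))`` is photon shot noise
entering *before* amplification (so its contribution scales with gain, which
is what makes spillover spread grow with brightness), and ``eps_bg`` is
voltage-independent electronic noise added after amplification.  Because the
electronic term does not scale with gain, resolution of dim signals improves
with voltage until the amplified photon noise dominates — the mechanism
behind the knee of SI-versus-voltage curves.

The ``analytic_*`` functions compute exact quantiles of this model by
numerical integration (Gauss-Hermite over the log-normal factors); they are
distribution-level predictions used as independent oracles against the
event-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .exceptions import ConfigError
from .fcs_io import ChannelDef, EventTable

__all__ = [
    "SimConfig",
    "PopulationSpec",
    "make_config",
    "simulate_acquisition",
    "simulate_single_stain_series",
    "simulate_broad_ladder",
    "simulate_qsbc_ladder",
    "simulate_titration",
    "simulate_panel",
    "gain",
    "expected_mean_matrix",
    "analytic_quantile",
    "analytic_clip_fraction",
    "analytic_si_curve",
]


def _per_detector(value, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ConfigError(f"{name} must be finite")
    return arr


@dataclass
class SimConfig:
    """Instrument + staining model parameters.

    One fluorochrome per detector, in matching order; ``spillover`` rows are
    fluorochromes and columns detectors with a unit diagonal.  Per-detector
    parameters accept scalars (broadcast) or length-n sequences.
    """

    channels: list[ChannelDef]
    fluorochromes: list[str]
    brightness: dict[str, float]
    spillover: np.ndarray | None = None
    gamma: float | np.ndarray = 6.0
    v_ref: float = 500.0
    af_median: float | np.ndarray = 50.0
    af_sigma: float | np.ndarray = 0.25
    background_sd: float | np.ndarray = 30.0
    photoelectron_scale: float | np.ndarray = 3.0
    expression_sigma: float = 0.25
    scale_min: float = 0.0
    seed: int = 0

    def __post_init__(self):
        n = len(self.channels)
        if n == 0:
            raise ConfigError("config needs at least one channel")
        if len(self.fluorochromes) != n:
            raise ConfigError("need exactly one fluorochrome per detector")
        for f in self.fluorochromes:
            if f not in self.brightness:
                raise ConfigError(f"missing brightness for {f!r}")
            if self.brightness[f] <= 0:
                raise ConfigError(f"brightness of {f!r} must be positive")
        if self.spillover is None:
            self.spillover = np.eye(n)
        self.spillover = np.asarray(self.spillover, dtype=float)
        if self.spillover.shape != (n, n):
            raise ConfigError("spillover must be n_fluorochromes x n_detectors")
        if not np.allclose(np.diag(self.spillover), 1.0):
            raise ConfigError("spillover diagonal must be exactly 1")
        if np.any(self.spillover < 0):
            raise ConfigError("spillover entries must be non-negative")
        self.gamma = _per_detector(self.gamma, n, "gamma")
        if np.any(self.gamma <= 0):
            raise ConfigError("gamma must be positive")
        self.af_median = _per_detector(self.af_median, n, "af_median")
        self.af_sigma = _per_detector(self.af_sigma, n, "af_sigma")
        self.background_sd = _per_detector(self.background_sd, n, "background_sd")
        self.photoelectron_scale = _per_detector(
            self.photoelectron_scale, n, "photoelectron_scale")
        if np.any(self.photoelectron_scale < 0):
            raise ConfigError("photoelectron_scale must be non-negative")

    @property
    def n_detectors(self) -> int:
        return len(self.channels)

    @property
    def detector_names(self) -> list[str]:
        return [c.detector for c in self.channels]

    def detector_index(self, detector: str) -> int:
        return self.detector_names.index(detector)

    def fluor_index(self, fluorochrome: str) -> int:
        return self.fluorochromes.index(fluorochrome)

    def primary_detector(self, fluorochrome: str) -> str:
        return self.detector_names[self.fluor_index(fluorochrome)]

    def brightness_vector(self) -> np.ndarray:
        return np.array([self.brightness[f] for f in self.fluorochromes])


@dataclass(frozen=True)
class PopulationSpec:
    """A simulated cell/bead population.

    ``marker_levels`` maps fluorochrome -> expression multiplier (0 =
    negative, 1 = fully stained); unlisted fluorochromes are absent.
    ``scatter_sigma > 0`` turns the population into multidimensional
    scattered outliers: each event's per-detector signal is additionally
    multiplied by independent log-normal factors of that sigma, emulating the
    debris/aggregate events that density censoring should remove.
    """

    name: str
    frequency: float
    marker_levels: dict[str, float] = field(default_factory=dict)
    scatter_sigma: float = 0.0

    def __post_init__(self):
        if not 0 <= self.frequency <= 1:
            raise ConfigError(f"frequency {self.frequency} outside [0, 1]")
        for f, m in self.marker_levels.items():
            if not np.isfinite(m) or m < 0:
                raise ConfigError(f"marker level for {f!r} must be finite, >= 0")


def make_config(
    n_detectors: int = 4,
    brightness: float | list[float] = 5000.0,
    spillover: np.ndarray | None = None,
    **kwargs,
) -> SimConfig:
    """Convenience constructor: detectors D1..Dn with dyes F1..Fn."""
    names = [f"D{i + 1}" for i in range(n_detectors)]
    dyes = [f"F{i + 1}" for i in range(n_detectors)]
    bvals = np.broadcast_to(np.asarray(brightness, dtype=float), (n_detectors,))
    channels = [ChannelDef(detector=n) for n in names]
    return SimConfig(
        channels=channels,
        fluorochromes=dyes,
        brightness=dict(zip(dyes, bvals.tolist())),
        spillover=spillover,
        **kwargs,
    )


def gain(config: SimConfig, detector: str, voltage: float) -> float:
    """Amplification factor (V / v_ref) ** gamma for one detector."""
    d = config.detector_index(detector)
    return float((voltage / config.v_ref) ** config.gamma[d])


def _gain_vector(config: SimConfig, voltage_map: dict[str, float]) -> np.ndarray:
    missing = [d for d in config.detector_names if d not in voltage_map]
    if missing:
        raise ConfigError(f"voltage_map missing detectors: {missing}")
    v = np.array([voltage_map[d] for d in config.detector_names])
    return (v / config.v_ref) ** config.gamma


def _multiplier_matrix(config: SimConfig,
                       populations: list[PopulationSpec]) -> np.ndarray:
    mult = np.zeros((len(populations), config.n_detectors))
    for k, pop in enumerate(populations):
        for f, m in pop.marker_levels.items():
            if f not in config.fluorochromes:
                raise ConfigError(f"population {pop.name!r} references unknown "
                                  f"fluorochrome {f!r}")
            mult[k, config.fluor_index(f)] = m
    return mult


def expected_mean_matrix(
    config: SimConfig,
    populations: list[PopulationSpec],
    voltage_map: dict[str, float],
) -> np.ndarray:
    """Noise-free detector means, populations x detectors.

    With all noise sources off (q = 0, background_sd = 0, af_sigma = 0,
    expression_sigma = 0) every simulated event of population k equals row k
    exactly: ``(mult_k * A) @ spill * gain + af_median * gain``.
    """
    g = _gain_vector(config, voltage_map)
    load = _multiplier_matrix(config, populations) * config.brightness_vector()
    return (load @ config.spillover + config.af_median) * g


def simulate_acquisition(
    config: SimConfig,
    populations: list[PopulationSpec],
    voltage_map: dict[str, float],
    n_events: int,
    seed: int,
) -> EventTable:
    """Simulate one acquisition tube.

    Ground truth (per-event population name/index) and per-detector clip
    fractions are stored in ``meta``; channel definitions carry the applied
    voltages.
    """
    freqs = np.array([p.frequency for p in populations])
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ConfigError(f"population frequencies sum to {freqs.sum()}, not 1")
    g = _gain_vector(config, voltage_map)
    A = config.brightness_vector()
    mult = _multiplier_matrix(config, populations)
    scatter = np.array([p.scatter_sigma for p in populations])

    rng = np.random.default_rng(seed)
    pop_idx = rng.choice(len(populations), size=n_events, p=freqs)
    base = mult[pop_idx] * A  # n x F load medians
    load = np.where(
        base > 0,
        base * np.exp(rng.normal(0.0, config.expression_sigma, base.shape)),
        0.0,
    )
    af = config.af_median * np.exp(
        rng.normal(size=(n_events, config.n_detectors)) * config.af_sigma)
    S = load @ config.spillover + af
    sct = scatter[pop_idx]
    if np.any(sct > 0):
        S = S * np.exp(rng.normal(size=S.shape) * sct[:, None])
    shot = rng.normal(size=S.shape) * np.sqrt(config.photoelectron_scale * S)
    obs = (S + shot) * g + rng.normal(size=S.shape) * config.background_sd

    adc = np.array([c.adc_max for c in config.channels])
    clip_low = obs < config.scale_min
    clip_high = obs > adc
    obs = np.clip(obs, config.scale_min, adc)

    channels = [replace(c, pmt_voltage=float(voltage_map[c.detector]),
                        fluorochrome=config.fluorochromes[i])
                for i, c in enumerate(config.channels)]
    names = np.array([p.name for p in populations])
    denom = max(n_events, 1)
    meta = {
        "population": names[pop_idx],
        "population_index": pop_idx,
        "voltage_map": dict(voltage_map),
        "seed": int(seed),
        "clip_low_frac": {c.detector: float(clip_low[:, i].sum() / denom)
                          for i, c in enumerate(channels)},
        "clip_high_frac": {c.detector: float(clip_high[:, i].sum() / denom)
                           for i, c in enumerate(channels)},
    }
    return EventTable(data=obs, channels=channels, meta=meta)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def _series_voltage_map(config: SimConfig, detector: str, v: float) -> dict:
    vmap = {c.detector: (c.pmt_voltage if c.pmt_voltage is not None
                         else config.v_ref)
            for c in config.channels}
    vmap[detector] = float(v)
    return vmap


def simulate_single_stain_series(
    config: SimConfig,
    fluorochrome: str,
    voltages,
    pos_fraction: float = 0.5,
    n_events: int = 10_000,
    seed: int = 0,
) -> list[EventTable]:
    """One tube per voltage: a stained and an unstained population.

    The detector assigned to ``fluorochrome`` walks the voltage grid; all
    other detectors sit at their configured (or reference) voltage.  Truth
    labels are stored under ``meta['truth_pos']``.
    """
    voltages = list(voltages)
    if not voltages:
        raise ConfigError("voltage list must be non-empty")
    detector = config.primary_detector(fluorochrome)
    pops = [
        PopulationSpec("positive", pos_fraction, {fluorochrome: 1.0}),
        PopulationSpec("negative", 1.0 - pos_fraction, {}),
    ]
    tables = []
    for v, s in zip(voltages, _child_seeds(seed, len(voltages))):
        t = simulate_acquisition(config, pops,
                                 _series_voltage_map(config, detector, v),
                                 n_events, s)
        t.meta["truth_pos"] = t.meta["population"] == "positive"
        t.meta["voltage"] = float(v)
        t.meta["fluorochrome"] = fluorochrome
        t.meta["detector"] = detector
        tables.append(t)
    return tables


def simulate_broad_ladder(
    config: SimConfig,
    n_levels: int = 5,
    voltages=(250, 300, 350, 400, 450, 500, 550, 600, 650, 700, 750, 800),
    n_events: int = 6_000,
    seed: int = 0,
    base: float = 200.0,
    ratio: float = 6.0,
) -> list[EventTable]:
    """Broad-spectrum calibration bead ladder, one tube per voltage.

    Beads emit in ALL detectors at ``n_levels`` geometric intensity levels
    plus a blank level 0; levels are equally frequent and the truth level is
    stored under ``meta['truth_level']``.
    """
    if n_levels < 2:
        raise ConfigError("bead ladder needs at least 2 positive levels")
    A = config.brightness_vector()
    freq = 1.0 / (n_levels + 1)
    pops = [PopulationSpec("L0", freq, {})]
    for lvl in range(1, n_levels + 1):
        intensity = base * ratio ** (lvl - 1)
        levels = {f: intensity / A[i]
                  for i, f in enumerate(config.fluorochromes)}
        pops.append(PopulationSpec(f"L{lvl}", freq, levels))
    # make frequencies sum exactly to 1
    pops[0] = replace(pops[0], frequency=1.0 - freq * n_levels)
    tables = []
    for v, s in zip(voltages, _child_seeds(seed, len(voltages))):
        vmap = {d: float(v) for d in config.detector_names}
        t = simulate_acquisition(config, pops, vmap, n_events, s)
        t.meta["truth_level"] = t.meta["population_index"]
        t.meta["voltage"] = float(v)
        tables.append(t)
    return tables


def simulate_qsbc_ladder(
    config: SimConfig,
    fluorochrome: str,
    voltages,
    n_events: int = 10_000,
    seed: int = 0,
    abc_base: float = 2_000.0,
    abc_ratio: float = 8.0,
) -> list[EventTable]:
    """Antibody-capture bead ladder M1 (blank) .. M5, one fluorochrome only.

    Peak loads follow a geometric antibody-binding-capacity series; the truth
    peak (1..5) is stored under ``meta['truth_peak']``.
    """
    A = config.brightness[fluorochrome]
    detector = config.primary_detector(fluorochrome)
    pops = [PopulationSpec("M1", 0.2, {})]
    for i in range(4):
        load = abc_base * abc_ratio ** i
        pops.append(PopulationSpec(f"M{i + 2}", 0.2, {fluorochrome: load / A}))
    tables = []
    for v, s in zip(voltages, _child_seeds(seed, len(voltages))):
        t = simulate_acquisition(config, pops,
                                 _series_voltage_map(config, detector, v),
                                 n_events, s)
        t.meta["truth_peak"] = t.meta["population_index"] + 1
        t.meta["voltage"] = float(v)
        t.meta["fluorochrome"] = fluorochrome
        t.meta["detector"] = detector
        tables.append(t)
    return tables


def simulate_titration(
    config: SimConfig,
    fluorochrome: str,
    concentrations,
    kd: float,
    n_events: int = 10_000,
    seed: int = 0,
    pos_fraction: float = 0.5,
    nonspecific_slope: float = 0.02,
) -> list[EventTable]:
    """Serial-dilution titration series, one tube per concentration.

    The stained population's brightness follows saturation binding
    ``c / (c + kd)``; the unstained background rises linearly with
    concentration (nonspecific binding), so the stain index is unimodal
    across a wide enough series.
    """
    if kd <= 0:
        raise ConfigError("kd must be positive")
    detector = config.primary_detector(fluorochrome)
    tables = []
    for c, s in zip(concentrations, _child_seeds(seed, len(list(concentrations)))):
        occupancy = c / (c + kd)
        pops = [
            PopulationSpec("positive", pos_fraction,
                           {fluorochrome: occupancy}),
            PopulationSpec("negative", 1.0 - pos_fraction,
                           {fluorochrome: nonspecific_slope * c}),
        ]
        vmap = _series_voltage_map(
            config, detector,
            config.channels[config.detector_index(detector)].pmt_voltage
            or config.v_ref)
        t = simulate_acquisition(config, pops, vmap, n_events, s)
        t.meta["truth_pos"] = t.meta["population"] == "positive"
        t.meta["concentration"] = float(c)
        t.meta["occupancy"] = float(occupancy)
        t.meta["fluorochrome"] = fluorochrome
        t.meta["detector"] = detector
        tables.append(t)
    return tables


def simulate_panel(
    config: SimConfig,
    populations: list[PopulationSpec],
    voltage_map: dict[str, float],
    n_events: int,
    seed: int,
) -> EventTable:
    """Multicolor panel acquisition with truth subset labels in meta."""
    return simulate_acquisition(config, populations, voltage_map,
                                n_events, seed)


# ---------------------------------------------------------------------------
# analytic theory: exact quantiles of the signal model
# ---------------------------------------------------------------------------

_GH_NODES = 48


def _gh(n: int):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()


def analytic_cdf(
    config: SimConfig,
    detector: str,
    voltage: float,
    x,
    load_median: float = 0.0,
    load_sigma: float | None = None,
) -> np.ndarray:
    """CDF of the observed (unclipped) signal for a single-dye population.

    The population carries ``load_median`` (its median fluorophore load,
    already multiplied into the detector under study, i.e. spillover applied
    by the caller) with log-normal sigma ``load_sigma`` (defaults to the
    config's expression sigma), plus autofluorescence, shot and electronic
    noise.  Computed by Gauss-Hermite integration over the two log-normal
    factors; clipping is not applied.
    """
    d = config.detector_index(detector)
    g = (voltage / config.v_ref) ** config.gamma[d]
    q = config.photoelectron_scale[d]
    bg = config.background_sd[d]
    if load_sigma is None:
        load_sigma = config.expression_sigma

    za, wa = _gh(_GH_NODES)
    af = config.af_median[d] * np.exp(config.af_sigma[d] * za)
    if load_median > 0:
        zl, wl = _gh(_GH_NODES)
        load = load_median * np.exp(load_sigma * zl)
        S = load[:, None] + af[None, :]
        w = wl[:, None] * wa[None, :]
    else:
        S = af[None, :]
        w = wa[None, :]
    sd = np.sqrt(np.maximum(g * g * q * S + bg * bg, 1e-300))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = (x[:, None, None] - g * S) / sd
    out = np.einsum("xlk,lk->x", ndtr(z), w)
    return out if out.size > 1 else out


def analytic_quantile(
    config: SimConfig,
    detector: str,
    voltage: float,
    q: float,
    load_median: float = 0.0,
    load_sigma: float | None = None,
) -> float:
    """Quantile (q in (0,1)) of the observed signal; inverse of analytic_cdf."""
    d = config.detector_index(detector)
    g = (voltage / config.v_ref) ** config.gamma[d]
    center = g * (load_median + config.af_median[d])
    span = 20.0 * (abs(center) + g * config.af_median[d]
                   + config.background_sd[d] + 1.0)

    def f(x):
        return float(analytic_cdf(config, detector, voltage, x,
                                  load_median, load_sigma)[0]) - q

    return float(brentq(f, center - span, center + span, xtol=1e-9 * span + 1e-12))


def analytic_clip_fraction(
    config: SimConfig,
    detector: str,
    voltage: float,
    load_median: float = 0.0,
    load_sigma: float | None = None,
) -> float:
    """Expected fraction of events piling up at the ADC ceiling."""
    adc = config.channels[config.detector_index(detector)].adc_max
    cdf = analytic_cdf(config, detector, voltage, adc, load_median, load_sigma)
    return float(1.0 - cdf[0])


def analytic_si_curve(
    config: SimConfig,
    fluorochrome: str,
    voltages,
) -> np.ndarray:
    """Theoretical SI(V) for a single stain: exact model quantiles.

    Uses the analytic median of the stained population and the analytic
    median / robust SD (15.87-84.13 half-distance) of the unstained one; this
    is the distribution-level counterpart of running the event simulator and
    serves as ground truth for voltage-recovery experiments.
    """
    detector = config.primary_detector(fluorochrome)
    A = config.brightness[fluorochrome]
    out = []
    for v in voltages:
        med_pos = analytic_quantile(config, detector, v, 0.5, load_median=A)
        med_neg = analytic_quantile(config, detector, v, 0.5)
        q_lo = analytic_quantile(config, detector, v, 0.1587)
        q_hi = analytic_quantile(config, detector, v, 0.8413)
        rsd = (q_hi - q_lo) / 2.0
        out.append((med_pos - med_neg) / (2.0 * rsd))
    return np.array(out)
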