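"""Named study scenarios: the fixed conditions under which the toolkit is
exercised and validated.

Each function returns the configuration (and auxiliary constants) of one
simulated study.  The constants are chosen once, from the acquisition
settings the protocols prescribe (voltage grids, dilution series, censoring
percentage) and from instrument-plausible noise parameters; they are part of
the study design, not tuning knobs.  The derivations live in the methods
note.
"""

from __future__ import annotations

import numpy as np

from .simulator import PopulationSpec, SimConfig, make_config

__all__ = [
    "VOLTAGE_GRID",
    "BEAD_VOLTAGE_GRID",
    "voltration_study",
    "bead_study",
    "spillover_study",
    "spread_study",
    "titration_study",
    "censor_study",
    "panel_study",
]

#: Single-stain voltage walk: 250-750 V in 25 V steps.
VOLTAGE_GRID: tuple = tuple(range(250, 775, 25))

#: Bead-ladder walk: 250-800 V in 50 V steps.
BEAD_VOLTAGE_GRID: tuple = tuple(range(250, 850, 50))


def voltration_study() -> dict:
    """Four detectors with distinct electronic noise floors.

    The per-detector background SD spreads the SI-curve knees across the
    voltage grid (analytically: 475, 550, 625 and 675 V), so voltage
    recovery is probed over most of the usable range.  20,000 events per
    tube, half stained.
    """
    config = make_config(
        n_detectors=4,
        brightness=5000.0,
        gamma=6.0,
        af_median=50.0,
        af_sigma=0.25,
        background_sd=[10.0, 25.0, 50.0, 100.0],
        photoelectron_scale=3.0,
    )
    return {
        "config": config,
        "voltages": VOLTAGE_GRID,
        "n_events": 20_000,
        "pos_fraction": 0.5,
        "laser_map": {d: "laser-1" for d in config.detector_names},
    }


def bead_study() -> dict:
    """Single-detector bead calibration matching one voltration detector.

    The broad ladder (negative + five levels, ratio 2.335, brightest level
    35,700 at reference gain) saturates its separation distance around
    550 V and runs its brightest peak off scale above 600 V; the QSBC set
    (M2 load 89.6, ratio 8) keeps M5 on scale up to 575 V.  The same
    detector noise model as voltration detector 2 (background SD 25) makes
    the two procedures comparable on one scenario.
    """
    config = make_config(
        n_detectors=1,
        brightness=5000.0,
        gamma=6.0,
        af_median=50.0,
        af_sigma=0.25,
        background_sd=25.0,
        photoelectron_scale=3.0,
    )
    return {
        "config": config,
        "ladder_voltages": BEAD_VOLTAGE_GRID,
        "ladder_kwargs": {"n_levels": 5, "base": 1200.0, "ratio": 2.335,
                          "n_events": 6_000},
        "qsbc_kwargs": {"abc_base": 89.6, "abc_ratio": 8.0,
                        "n_events": 30_000},
        "voltration_voltages": VOLTAGE_GRID,
        "voltration_n_events": 20_000,
    }


def spillover_study() -> dict:
    """Four-dye panel with a known spillover matrix (off-diagonals to 0.3)."""
    truth = np.array([
        [1.00, 0.30, 0.15, 0.05],
        [0.10, 1.00, 0.20, 0.02],
        [0.00, 0.08, 1.00, 0.25],
        [0.01, 0.00, 0.12, 1.00],
    ])
    config = make_config(
        n_detectors=4,
        brightness=[8000.0, 6000.0, 7000.0, 5000.0],
        spillover=truth,
        gamma=6.0,
        af_median=50.0,
        af_sigma=0.25,
        background_sd=25.0,
        photoelectron_scale=5.0,
    )
    return {"config": config, "truth": truth, "n_events": 10_000,
            "voltage": 500.0}


def spread_study(spill: float = 0.0) -> SimConfig:
    """Two detectors: a bright affecting dye spilling ``spill`` into a dim
    neighbour; strong shot noise so spread is the dominant resolution cost."""
    truth = np.array([[1.0, spill], [0.0, 1.0]])
    return make_config(
        n_detectors=2,
        brightness=[50_000.0, 2_000.0],
        spillover=truth,
        gamma=6.0,
        af_median=50.0,
        af_sigma=0.25,
        background_sd=25.0,
        photoelectron_scale=10.0,
    )


def titration_study() -> dict:
    """Six 1:2 dilutions with saturation binding (kd 0.35 in reagent units).

    90% receptor occupancy is reached at 9 * kd = 3.15, between the two top
    concentrations; nonspecific background grows with concentration so the
    SI series is unimodal.
    """
    config = make_config(
        n_detectors=1,
        brightness=5000.0,
        gamma=6.0,
        af_median=50.0,
        af_sigma=0.25,
        background_sd=25.0,
        photoelectron_scale=3.0,
    )
    return {
        "config": config,
        "concentrations": (0.2, 0.4, 0.8, 1.6, 3.2, 6.4),
        "kd": 0.35,
        "nonspecific_slope": 0.001,
        "n_events": 20_000,
        "occupancy_90_concentration": 9 * 0.35,
    }


def _panel_config(n_detectors: int) -> SimConfig:
    # mild nearest-neighbour spillover chain for realism
    spill = np.eye(n_detectors)
    for i in range(n_detectors - 1):
        spill[i, i + 1] = 0.05
    return make_config(
        n_detectors=n_detectors,
        brightness=5000.0,
        spillover=spill,
        gamma=6.0,
        af_median=50.0,
        af_sigma=0.25,
        background_sd=25.0,
        photoelectron_scale=3.0,
    )


def censor_study() -> dict:
    """10,000-event acquisition with a dense rare island and scattered
    outliers, the input for density-censoring validation.

    94.5% bulk in two dense populations, 0.5% tight rare subset, and 5%
    multidimensional scattered events (log-normal scatter sigma 2) standing
    in for debris/aggregates.
    """
    config = _panel_config(4)
    populations = [
        PopulationSpec("bulk_a", 0.645, {"F1": 1.0, "F2": 0.1}),
        PopulationSpec("bulk_b", 0.30, {"F2": 1.0, "F3": 0.8}),
        PopulationSpec("rare", 0.005, {"F3": 1.0, "F4": 1.0}),
        PopulationSpec("outlier", 0.05, {"F1": 0.5, "F2": 0.5, "F3": 0.5},
                       scatter_sigma=2.0),
    ]
    return {"config": config, "populations": populations,
            "n_events": 10_000,
            "voltage_map": {d: 500.0 for d in config.detector_names}}


def panel_study() -> dict:
    """Ten-color panel with a 0.5% tetramer-like rare subset.

    Channel D1 plays the viability-dye role (excluded from clustering);
    F10 is the tetramer channel, positive only on the rare subset.  A 4%
    scattered debris population provides the low-density tail that the 3%
    censoring step is designed to remove — without it the cut would eat
    into genuine populations instead.
    """
    config = _panel_config(10)
    populations = [
        PopulationSpec("debris", 0.04,
                       {"F2": 0.5, "F4": 0.5, "F7": 0.5},
                       scatter_sigma=2.0),
        PopulationSpec("t_helper", 0.51,
                       {"F2": 1.0, "F3": 1.0, "F5": 0.8}),
        PopulationSpec("t_cytotoxic", 0.30,
                       {"F2": 1.0, "F4": 1.0, "F6": 0.6}),
        PopulationSpec("b_cells", 0.09,
                       {"F7": 1.0, "F8": 0.9}),
        PopulationSpec("nk_cells", 0.055,
                       {"F6": 1.0, "F9": 1.0}),
        PopulationSpec("tetramer_pos", 0.005,
                       {"F2": 1.0, "F4": 0.8, "F10": 1.0}),
    ]
    return {
        "config": config,
        "populations": populations,
        "n_events": 20_000,
        "voltage_map": {d: 500.0 for d in config.detector_names},
        "exclude_channels": ("D1",),
        "n_neighbors": 10,
    }
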