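import numpy as np
import pytest

from cytotune import simulator as sim
from cytotune.fcs_io import ChannelDef, EventTable
from cytotune.robust_stats import StainIndexResult
from cytotune.voltration import OnScaleFlags, SICurve, SICurvePoint


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_table(rng):
    data = rng.uniform(0, 10_000, size=(500, 3))
    channels = [ChannelDef("D1", "F1", 450.0),
                ChannelDef("D2", "F2", 500.0),
                ChannelDef("D3")]
    return EventTable(data=data, channels=channels,
                      meta={"sample": "unit", "dilution": 1.0})


@pytest.fixture
def noise_free_config():
    return sim.make_config(
        n_detectors=3, brightness=5000.0, af_sigma=0.0,
        background_sd=0.0, photoelectron_scale=0.0, expression_sigma=0.0)


def make_curve(voltages, si_values, detector="D1", fluorochrome="F1",
               on_scale=True, primary_ok=True):
    """Synthetic SI curve for rule-level tests."""
    flags = OnScaleFlags(1.0, 0.0, True, True) if on_scale else None
    points = [
        SICurvePoint(
            voltage=float(v),
            si=StainIndexResult(si=float(s), median_pos=float(s),
                                median_neg=0.0, rsd_neg=0.5,
                                n_pos=100, n_neg=100),
            on_scale=flags, primary_ok=primary_ok)
        for v, s in zip(voltages, si_values)
    ]
    return SICurve(detector=detector, fluorochrome=fluorochrome,
                   points=points)


@pytest.fixture
def curve_factory():
    return make_curve
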