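"""SI-curve construction, knee detection, on-scale checks, voltage choice."""

import numpy as np
import pytest

from cytotune import simulator as sim
from cytotune import voltration as vt
from cytotune.exceptions import (
    ConfigError,
    InsufficientDataError,
    UnseparablePopulationsError,
)
from cytotune.robust_stats import split_pos_neg


def _study_config(background_sd=25.0):
    return sim.make_config(1, brightness=5000.0, gamma=6.0, af_median=50.0,
                           af_sigma=0.25, background_sd=background_sd,
                           photoelectron_scale=3.0)


GRID = list(range(250, 775, 25))


class TestBuildSiCurve:
    def test_one_point_per_voltage_sorted(self):
        cfg = _study_config()
        series = sim.simulate_single_stain_series(cfg, "F1", GRID[::-1],
                                                  n_events=2000, seed=0)
        curve = vt.build_si_curve(series, "D1")
        assert len(curve.points) == 21
        assert np.all(np.diff(curve.voltages) > 0)
        assert all(p.si is not None for p in curve.points)

    def test_duplicate_voltages_rejected(self):
        cfg = _study_config()
        series = sim.simulate_single_stain_series(cfg, "F1", [500, 500],
                                                  n_events=500, seed=0)
        with pytest.raises(ConfigError, match="duplicate"):
            vt.build_si_curve(series, "D1")

    def test_pileup_increases_when_signal_saturates(self):
        cfg = sim.make_config(1, brightness=120_000.0)
        series = sim.simulate_single_stain_series(cfg, "F1",
                                                  [500, 600, 700, 750],
                                                  n_events=4000, seed=1)
        curve = vt.build_si_curve(series, "D1")
        pile = [p.on_scale.pileup_frac for p in curve.points]
        assert pile[-1] > pile[0]
        assert pile == sorted(pile)

    def test_unseparable_point_flagged_not_dropped(self):
        cfg = _study_config()
        series = sim.simulate_single_stain_series(cfg, "F1", [300, 500],
                                                  n_events=3000, seed=2)
        # pretend the dim tube has no usable truth: force mixture split on a
        # voltage where positive and negative overlap heavily
        series[0].data[:, 0] = np.random.default_rng(0).normal(100, 5, 3000)
        for t in series:
            del t.meta["truth_pos"]
        curve = vt.build_si_curve(series, "D1", split_method="mixture")
        assert not curve.points[0].separable
        assert curve.points[1].separable
        assert len(curve.points) == 2


class TestDetectKnee:
    def test_recovers_analytic_saturation_voltage(self):
        cfg = _study_config(background_sd=25.0)
        truth_si = sim.analytic_si_curve(cfg, "F1", GRID)
        from conftest import make_curve

        truth_knee, _ = vt.detect_knee(make_curve(GRID, truth_si))
        series = sim.simulate_single_stain_series(cfg, "F1", GRID,
                                                  n_events=20_000, seed=3)
        knee, _ = vt.detect_knee(vt.build_si_curve(series, "D1"))
        assert abs(knee - truth_knee) <= 25.0

    def test_linear_growth_has_no_inflection(self, curve_factory):
        curve = curve_factory(GRID, [0.1 * v for v in GRID])
        knee, diag = vt.detect_knee(curve)
        assert knee is None
        assert "inflection" in diag["reason"]

    def test_constant_curve_degenerate_boundary(self, curve_factory):
        curve = curve_factory(GRID, [5.0] * len(GRID))
        knee, diag = vt.detect_knee(curve)
        assert knee == 250.0
        assert diag.get("degenerate")

    def test_too_few_points_rejected(self, curve_factory):
        curve = curve_factory([250, 275, 300], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            vt.detect_knee(curve)

    def test_still_rising_at_top_returns_none(self, curve_factory):
        curve = curve_factory(GRID, [2.0 ** (i / 2) for i in range(21)])
        knee, diag = vt.detect_knee(curve)
        assert knee is None


class TestOnScaleAndPrimary:
    def test_resolved_negative(self, rng):
        cfg = _study_config()
        (t,) = sim.simulate_single_stain_series(cfg, "F1", [600],
                                                n_events=5000, seed=4)
        split = split_pos_neg(t.column("D1"), "truth",
                              truth=t.meta["truth_pos"])
        flags = vt.check_on_scale(t, "D1", split)
        assert flags.neg_resolved
        assert flags.pos_on_scale

    def test_clipping_positive_fails_on_scale(self):
        cfg = sim.make_config(1, brightness=200_000.0)
        (t,) = sim.simulate_single_stain_series(cfg, "F1", [700],
                                                n_events=5000, seed=5)
        split = split_pos_neg(t.column("D1"), "truth",
                              truth=t.meta["truth_pos"])
        flags = vt.check_on_scale(t, "D1", split)
        assert flags.pileup_frac > 0.01
        assert not flags.pos_on_scale

    def test_primary_emission_with_moderate_spillover(self):
        spill = np.array([[1.0, 0.4], [0.0, 1.0]])
        cfg = sim.make_config(2, spillover=spill)
        (t,) = sim.simulate_single_stain_series(cfg, "F1", [500],
                                                n_events=4000, seed=6)
        split = split_pos_neg(t.column("D1"), "truth",
                              truth=t.meta["truth_pos"])
        ok, deltas = vt.check_primary_emission(t, "F1", split)
        assert ok
        assert deltas["D1"] > deltas["D2"]

    def test_primary_emission_fails_for_dominant_spillover(self):
        spill = np.array([[1.0, 1.2], [0.0, 1.0]])
        cfg = sim.make_config(2, spillover=spill)
        (t,) = sim.simulate_single_stain_series(cfg, "F1", [500],
                                                n_events=4000, seed=7)
        split = split_pos_neg(t.column("D1"), "truth",
                              truth=t.meta["truth_pos"])
        ok, _ = vt.check_primary_emission(t, "F1", split)
        assert not ok

    def test_unstained_sample_rejected(self):
        cfg = _study_config()
        (t,) = sim.simulate_single_stain_series(cfg, "F1", [500],
                                                pos_fraction=0.5,
                                                n_events=1000, seed=8)
        split = split_pos_neg(t.column("D1"), "truth",
                              truth=np.zeros(1000, dtype=bool))
        with pytest.raises(UnseparablePopulationsError):
            vt.check_primary_emission(t, "F1", split)


class TestRecommendVoltages:
    def test_report_complete_and_on_scale(self):
        cfg = sim.make_config(2, brightness=5000.0, gamma=6.0,
                              af_median=50.0, af_sigma=0.25,
                              background_sd=[10.0, 50.0],
                              photoelectron_scale=3.0)
        curves = []
        for f, d in zip(cfg.fluorochromes, cfg.detector_names):
            series = sim.simulate_single_stain_series(cfg, f, GRID,
                                                      n_events=8000, seed=9)
            curves.append(vt.build_si_curve(series, d))
        report = vt.recommend_voltages(curves)
        assert set(report.recommendations) == {"D1", "D2"}
        for rec in report.recommendations.values():
            assert rec.chosen_voltage in GRID
            assert set(rec.criteria_flags) == {"i", "ii", "iii", "iv", "v"}
            point = next(c for c in curves
                         if c.detector == rec.detector
                         ).point_at(rec.chosen_voltage)
            assert point.on_scale.neg_resolved
            assert point.on_scale.pos_on_scale

    def test_fallback_to_same_laser_median(self, curve_factory):
        sat = [10 * (1 - 0.5 ** (i / 2)) for i in range(21)]  # knees
        curves = [curve_factory(GRID, sat, detector="D1"),
                  curve_factory(GRID, sat, detector="D2"),
                  curve_factory(GRID, [0.1 * v for v in GRID],
                                detector="D3")]
        report = vt.recommend_voltages(
            curves, laser_map={"D1": "a", "D2": "a", "D3": "a"})
        rec = report.recommendations["D3"]
        assert rec.criteria_flags["v"]
        assert rec.knee_voltage is None
        chosen = [report.chosen("D1"), report.chosen("D2")]
        assert rec.chosen_voltage == pytest.approx(np.median(chosen))

    def test_clipping_knee_moves_down_a_step(self):
        # brightness so large that the knee voltage clips the positives,
        # with a low noise floor so the negative resolves below the knee
        cfg = sim.make_config(1, brightness=300_000.0, gamma=6.0,
                              af_median=50.0, af_sigma=0.25,
                              background_sd=5.0, photoelectron_scale=3.0)
        series = sim.simulate_single_stain_series(cfg, "F1", GRID,
                                                  n_events=8000, seed=10)
        curve = vt.build_si_curve(series, "D1")
        knee, _ = vt.detect_knee(curve)
        report = vt.recommend_voltages([curve])
        rec = report.recommendations["D1"]
        assert not curve.point_at(knee).on_scale.pos_on_scale
        assert rec.chosen_voltage < knee
        assert not rec.criteria_flags["iii"] or \
            curve.point_at(rec.chosen_voltage).on_scale.pos_on_scale
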