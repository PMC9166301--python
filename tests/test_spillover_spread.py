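"""Spillover estimation/compensation, spread mapping and panel rules."""

import numpy as np
import pytest

from cytotune import scenarios
from cytotune import simulator as sim
from cytotune import spillover_spread as sp
from cytotune.exceptions import (
    ConfigError,
    NonInvertibleError,
    PanelSpecError,
    UnusableControlError,
)
from cytotune.robust_stats import robust_sd


def make_singles(config, n_events=10_000, seed=0, voltage=500.0):
    singles = {}
    for i, f in enumerate(config.fluorochromes):
        pops = [sim.PopulationSpec("positive", 0.5, {f: 1.0}),
                sim.PopulationSpec("negative", 0.5, {})]
        t = sim.simulate_acquisition(
            config, pops, {d: voltage for d in config.detector_names},
            n_events, seed * 100 + i)
        t.meta["truth_pos"] = t.meta["population"] == "positive"
        singles[f] = t
    return singles


@pytest.fixture(scope="module")
def study():
    st = scenarios.spillover_study()
    singles = make_singles(st["config"], st["n_events"], seed=3)
    with pytest.warns(UserWarning):  # tiny negative estimates clipped
        matrix = sp.estimate_spillover(singles)
    return st, singles, matrix


class TestEstimateSpillover:
    def test_null_spillover_estimated_near_zero(self):
        cfg = sim.make_config(3, photoelectron_scale=3.0)
        matrix = sp.estimate_spillover(make_singles(cfg, 10_000, seed=1))
        off = matrix.coefficients[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) <= 0.005)

    def test_known_matrix_recovered(self, study):
        st, _, matrix = study
        err = np.max(np.abs(matrix.coefficients - st["truth"]))
        assert err < 0.02

    def test_error_decreases_with_control_size(self):
        st = scenarios.spillover_study()
        errs = []
        for n in (1000, 10_000):
            reps = []
            for seed in range(4):
                m = sp.estimate_spillover(
                    make_singles(st["config"], n, seed=10 + seed))
                reps.append(np.max(np.abs(m.coefficients - st["truth"])))
            errs.append(np.mean(reps))
        assert errs[1] < errs[0]

    def test_unstained_control_rejected(self):
        cfg = sim.make_config(2)
        singles = make_singles(cfg, 2000, seed=2)
        # an unstained tube passed off as the F1 single stain
        blank = sim.simulate_acquisition(
            cfg, [sim.PopulationSpec("negative", 1.0, {})],
            {"D1": 500.0, "D2": 500.0}, 2000, 5)
        blank.meta["truth_pos"] = np.random.default_rng(0).random(2000) < 0.5
        singles["F1"] = blank
        with pytest.raises(UnusableControlError):
            sp.estimate_spillover(singles)


class TestCompensate:
    def test_identity_matrix_is_noop(self, study):
        _, singles, _ = study
        table = singles["F1"]
        ident = sp.SpilloverMatrix(
            ["F1", "F2", "F3", "F4"], table.detector_names, np.eye(4))
        out = sp.compensate(table, ident)
        np.testing.assert_allclose(out.data, table.data)

    def test_compensation_removes_off_channel_signal(self, study):
        _, singles, matrix = study
        comp = sp.compensate(singles["F1"], matrix)
        pos = comp.meta["truth_pos"]
        for d in ("D2", "D3", "D4"):
            col = comp.column(d)
            delta = abs(np.median(col[pos]) - np.median(col[~pos]))
            assert delta < 2 * robust_sd(col[~pos])

    def test_roundtrip_restores_original(self, study):
        _, singles, matrix = study
        comp = sp.compensate(singles["F2"], matrix)
        back = comp.data @ matrix.coefficients
        np.testing.assert_allclose(back, singles["F2"].data, rtol=1e-9,
                                   atol=1e-6)

    def test_singular_matrix_rejected(self, study):
        _, singles, _ = study
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 1.0  # rank deficient pair
        m = sp.SpilloverMatrix(["F1", "F2", "F3", "F4"],
                               singles["F1"].detector_names, bad)
        with pytest.raises(NonInvertibleError):
            sp.compensate(singles["F1"], m)


class TestSpreadMatrix:
    def _spread_for(self, spill, q=None, seed=7):
        cfg = scenarios.spread_study(spill)
        if q is not None:
            from dataclasses import replace
            cfg = replace(cfg, photoelectron_scale=q)
        singles = make_singles(cfg, 20_000, seed=seed)
        matrix = sp.estimate_spillover(singles)
        return sp.spread_matrix(singles, matrix)

    def test_no_spread_without_shot_noise(self):
        noisy = self._spread_for(0.3)
        quiet = self._spread_for(0.3, q=0.0)
        ref = noisy.sigma("F1", "D2")
        assert ref > 50.0
        assert quiet.sigma("F1", "D2") < 0.05 * ref

    def test_spread_increases_with_spillover(self):
        sigmas = [self._spread_for(s).sigma("F1", "D2")
                  for s in (0.05, 0.15, 0.3)]
        assert sigmas[0] < sigmas[1] < sigmas[2]

    def test_diagonal_zero_by_convention(self):
        m = self._spread_for(0.15)
        assert m.sigma("F1", "D1") == 0.0
        assert m.sigma("F2", "D2") == 0.0

    def test_missing_single_stain_flagged(self):
        cfg = scenarios.spread_study(0.15)
        singles = make_singles(cfg, 5000, seed=8)
        matrix = sp.estimate_spillover(singles)
        del singles["F2"]
        m = sp.spread_matrix(singles, matrix)
        assert m.entries[("F2", "D1")].missing
        assert np.isnan(m.entries[("F2", "D1")].sigma_spread)

    def test_compensation_does_not_remove_spread(self):
        """Spread is variance, not mean: the compensated control must keep
        at least 90% of the uncompensated spread statistic.

        Cell-to-cell brightness variation is switched off here: that part of
        the off-channel width tracks the primary signal event by event and
        is removed by compensation by design.  What must survive is the
        photon-noise component."""
        from dataclasses import replace

        cfg = replace(scenarios.spread_study(0.3), expression_sigma=0.0)
        singles = make_singles(cfg, 20_000, seed=9)
        matrix = sp.estimate_spillover(singles)
        t = singles["F1"]
        pos = t.meta["truth_pos"]

        def sigma_of(table):
            col = table.column("D2")
            return np.sqrt(max(robust_sd(col[pos]) ** 2
                               - robust_sd(col[~pos]) ** 2, 0.0))

        raw = sigma_of(t)
        comp = sigma_of(sp.compensate(t, matrix))
        assert comp >= 0.9 * raw


class TestDpResolutionImpact:
    def test_no_spillover_no_penalty(self):
        cfg = scenarios.spread_study(0.0)
        si_dp, si_sp = sp.dp_resolution_impact(cfg, "F1", "D2", 20.0,
                                               seed=1)
        assert si_dp == pytest.approx(si_sp, rel=0.1)

    def test_dp_hurt_sp_intact(self):
        base_dp, base_sp = sp.dp_resolution_impact(
            scenarios.spread_study(0.0), "F1", "D2", 20.0, seed=2)
        dp, spv = sp.dp_resolution_impact(
            scenarios.spread_study(0.3), "F1", "D2", 20.0, seed=2)
        assert dp < 0.5 * base_dp
        assert spv == pytest.approx(base_sp, rel=0.1)

    def test_monotone_in_spillover(self):
        sis = [sp.dp_resolution_impact(scenarios.spread_study(s),
                                       "F1", "D2", 20.0, seed=3)[0]
               for s in (0.0, 0.05, 0.15, 0.3)]
        assert all(a > b for a, b in zip(sis, sis[1:]))


class TestCheckPanel:
    def _spread(self, sigma):
        fl = ["F1", "F2"]
        det = ["D1", "D2"]
        entries = {("F1", "D1"): sp.SpreadEntry(0.0, 0.0),
                   ("F1", "D2"): sp.SpreadEntry(sigma, 0.5),
                   ("F2", "D1"): sp.SpreadEntry(0.0, 0.0),
                   ("F2", "D2"): sp.SpreadEntry(0.0, 0.0)}
        return sp.SpreadMatrix(fl, det, entries, 10_000.0)

    def test_empty_panel_no_warnings(self):
        panel = sp.PanelSpec(assignments={})
        assert sp.check_panel(panel, self._spread(500.0)) == []

    def test_dim_marker_under_spread_fires_rules_i_and_iii(self):
        panel = sp.PanelSpec(
            assignments={
                "ag_low": sp.PanelAssignment("F2", "dim", "low"),
                "ag_high": sp.PanelAssignment("F1", "bright", "low"),
            },
            coexpression={frozenset({"ag_low", "ag_high"})})
        warnings_out = sp.check_panel(panel, self._spread(500.0))
        rules = sorted(w.rule for w in warnings_out)
        assert "i" in rules and "iii" in rules

    def test_clean_panel_on_zero_spread(self):
        panel = sp.PanelSpec(
            assignments={
                "ag_low": sp.PanelAssignment("F1", "bright", "low"),
                "ag_high": sp.PanelAssignment("F2", "dim", "high"),
            },
            coexpression={frozenset({"ag_low", "ag_high"})})
        assert sp.check_panel(panel, self._spread(0.0)) == []

    def test_high_density_on_bright_dye_fires_rule_iv(self):
        panel = sp.PanelSpec(assignments={
            "ag": sp.PanelAssignment("F1", "bright", "high")})
        warnings_out = sp.check_panel(panel, self._spread(0.0))
        assert [w.rule for w in warnings_out] == ["iv"]

    def test_unassigned_coexpression_marker_rejected(self):
        with pytest.raises(PanelSpecError):
            sp.PanelSpec(
                assignments={"a": sp.PanelAssignment("F1", "dim", "high")},
                coexpression={frozenset({"a", "ghost"})})
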