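"""Simulator correctness: exact noise-free algebra, gain law, determinism,
and the phenomenology each downstream tool relies on."""

import numpy as np
import pytest

from cytotune import simulator as sim
from cytotune.exceptions import ConfigError
from cytotune.robust_stats import robust_sd


class TestAcquisition:
    def test_noise_free_limit_is_exact_linear_model(self, noise_free_config):
        pops = [sim.PopulationSpec("a", 0.6, {"F1": 1.0, "F2": 0.5}),
                sim.PopulationSpec("b", 0.4, {})]
        vmap = {d: 600.0 for d in noise_free_config.detector_names}
        table = sim.simulate_acquisition(noise_free_config, pops, vmap,
                                         2000, 3)
        expected = sim.expected_mean_matrix(noise_free_config, pops, vmap)
        np.testing.assert_allclose(
            table.data, expected[table.meta["population_index"]])

    def test_same_seed_is_bit_identical(self):
        cfg = sim.make_config(2)
        pops = [sim.PopulationSpec("a", 1.0, {"F1": 1.0})]
        vmap = {"D1": 500.0, "D2": 500.0}
        t1 = sim.simulate_acquisition(cfg, pops, vmap, 5000, 11)
        t2 = sim.simulate_acquisition(cfg, pops, vmap, 5000, 11)
        assert np.array_equal(t1.data, t2.data)
        assert np.array_equal(t1.meta["population_index"],
                              t2.meta["population_index"])

    def test_gain_law_doubling_voltage(self):
        # gamma=2: doubling V quadruples the median signal
        cfg = sim.make_config(1, brightness=5000.0, gamma=2.0, v_ref=250.0,
                              af_median=1.0, background_sd=5.0)
        pops = [sim.PopulationSpec("pos", 1.0, {"F1": 1.0})]
        lo = sim.simulate_acquisition(cfg, pops, {"D1": 250.0}, 100_000, 5)
        hi = sim.simulate_acquisition(cfg, pops, {"D1": 500.0}, 100_000, 6)
        ratio = np.median(hi.column("D1")) / np.median(lo.column("D1"))
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_bad_frequencies_rejected(self):
        cfg = sim.make_config(1)
        pops = [sim.PopulationSpec("a", 0.5, {})]
        with pytest.raises(ConfigError):
            sim.simulate_acquisition(cfg, pops, {"D1": 500.0}, 10, 0)

    def test_shot_noise_spread_grows_with_spillover(self):
        # variance received in an off-diagonal detector rises with the
        # spillover coefficient: the mechanism behind spreading error
        widths = []
        for s in (0.05, 0.15, 0.3):
            cfg = sim.make_config(
                2, brightness=[50_000.0, 1_000.0],
                spillover=np.array([[1.0, s], [0.0, 1.0]]),
                photoelectron_scale=10.0, expression_sigma=0.0)
            pops = [sim.PopulationSpec("pos", 1.0, {"F1": 1.0})]
            t = sim.simulate_acquisition(cfg, pops,
                                         {"D1": 500.0, "D2": 500.0},
                                         20_000, 8)
            widths.append(robust_sd(t.column("D2")))
        assert widths[0] < widths[1] < widths[2]


class TestSingleStainSeries:
    def test_one_table_per_voltage(self):
        cfg = sim.make_config(2)
        series = sim.simulate_single_stain_series(
            cfg, "F1", range(250, 775, 25), n_events=200, seed=0)
        assert len(series) == 21
        assert [t.meta["voltage"] for t in series] == list(range(250, 775, 25))

    def test_stained_fraction_binomial(self):
        cfg = sim.make_config(1)
        (table,) = sim.simulate_single_stain_series(
            cfg, "F1", [500], pos_fraction=0.4, n_events=100_000, seed=1)
        assert table.meta["truth_pos"].mean() == pytest.approx(0.4, abs=0.01)

    def test_pileup_recorded_at_saturating_voltage(self):
        cfg = sim.make_config(1, brightness=250_000.0)
        (table,) = sim.simulate_single_stain_series(
            cfg, "F1", [750], n_events=5000, seed=2)
        assert table.meta["clip_high_frac"]["D1"] > 0


class TestBeadLadders:
    def test_broad_ladder_levels(self):
        cfg = sim.make_config(2)
        tables = sim.simulate_broad_ladder(cfg, n_levels=5,
                                           voltages=[400, 500], seed=0)
        assert len(tables) == 2
        assert set(np.unique(tables[0].meta["truth_level"])) == set(range(6))

    def test_noise_free_medians_follow_geometric_ladder(self,
                                                        noise_free_config):
        tables = sim.simulate_broad_ladder(
            noise_free_config, n_levels=4, voltages=[500], seed=0,
            base=100.0, ratio=5.0, n_events=3000)
        t = tables[0]
        level = t.meta["truth_level"]
        med = [np.median(t.column("D1")[level == k]) for k in range(5)]
        af = noise_free_config.af_median[0]
        expected = [af] + [100.0 * 5.0 ** k + af for k in range(4)]
        np.testing.assert_allclose(med, expected)

    def test_reproducible_from_seed(self):
        cfg = sim.make_config(1)
        a = sim.simulate_broad_ladder(cfg, voltages=[500], seed=3)[0]
        b = sim.simulate_broad_ladder(cfg, voltages=[500], seed=3)[0]
        assert np.array_equal(a.data, b.data)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ConfigError):
            sim.simulate_broad_ladder(sim.make_config(1), n_levels=1,
                                      voltages=[500], seed=0)

    def test_qsbc_five_peaks_and_ordering(self):
        cfg = sim.make_config(1)
        (t,) = sim.simulate_qsbc_ladder(cfg, "F1", [500], n_events=5000,
                                        seed=0)
        peaks = np.unique(t.meta["truth_peak"])
        assert list(peaks) == [1, 2, 3, 4, 5]
        m2 = np.median(t.column("D1")[t.meta["truth_peak"] == 2])
        m5 = np.median(t.column("D1")[t.meta["truth_peak"] == 5])
        assert m5 > 50 * m2 / 8  # geometric ladder: M5 >> M2

    def test_qsbc_medians_follow_gain_law(self):
        cfg = sim.make_config(1, background_sd=1.0, af_median=1.0,
                              photoelectron_scale=0.0)
        tables = sim.simulate_qsbc_ladder(cfg, "F1", [500, 550],
                                          n_events=20_000, seed=1,
                                          abc_base=50.0)
        med = [np.median(t.column("D1")[t.meta["truth_peak"] == 5])
               for t in tables]
        assert med[1] / med[0] == pytest.approx((550 / 500) ** 6, rel=0.02)


class TestTitrationAndPanel:
    def test_half_saturation_at_kd(self, noise_free_config):
        tables = sim.simulate_titration(
            noise_free_config, "F1", [2.0], kd=2.0, n_events=500, seed=0,
            nonspecific_slope=0.0)
        assert tables[0].meta["occupancy"] == pytest.approx(0.5)
        pos = tables[0].meta["truth_pos"]
        sig = np.median(tables[0].column("D1")[pos]) \
            - noise_free_config.af_median[0]
        assert sig == pytest.approx(2500.0, rel=1e-9)

    def test_saturation_limit(self, noise_free_config):
        tables = sim.simulate_titration(noise_free_config, "F1", [1e6],
                                        kd=2.0, n_events=100, seed=0)
        assert tables[0].meta["occupancy"] == pytest.approx(1.0, abs=1e-5)

    def test_si_series_is_unimodal(self):
        # saturation binding + rising nonspecific background: SI rises to a
        # peak then falls
        from cytotune.robust_stats import stain_index

        cfg = sim.make_config(1)
        concs = [0.1 * 2 ** k for k in range(9)]
        tables = sim.simulate_titration(cfg, "F1", concs, kd=0.35,
                                        n_events=10_000, seed=4,
                                        nonspecific_slope=0.05)
        si = []
        for t in tables:
            pos = t.meta["truth_pos"]
            v = t.column("D1")
            si.append(stain_index(v[pos], v[~pos]).si)
        peak = int(np.argmax(si))
        assert 0 < peak < len(si) - 1
        assert si[0] < si[peak] and si[-1] < si[peak]

    def test_panel_truth_frequencies(self):
        cfg = sim.make_config(3)
        pops = [sim.PopulationSpec("big", 0.995, {"F1": 1.0}),
                sim.PopulationSpec("rare", 0.005, {"F2": 1.0})]
        t = sim.simulate_panel(cfg, pops,
                               {d: 500.0 for d in cfg.detector_names},
                               100_000, 9)
        n_rare = int((t.meta["population"] == "rare").sum())
        assert n_rare == pytest.approx(500, abs=80)  # ~3.5 binomial SD

    def test_distinct_levels_separate_without_noise(self, noise_free_config):
        pops = [sim.PopulationSpec("a", 0.5, {"F1": 1.0}),
                sim.PopulationSpec("b", 0.5, {"F2": 1.0})]
        t = sim.simulate_panel(
            noise_free_config, pops,
            {d: 500.0 for d in noise_free_config.detector_names}, 1000, 0)
        a = t.meta["population"] == "a"
        assert t.column("D1")[a].min() > t.column("D1")[~a].max()


class TestAnalyticTheory:
    def test_quantiles_match_large_simulation(self):
        cfg = sim.make_config(1, brightness=5000.0)
        pops = [sim.PopulationSpec("neg", 1.0, {})]
        t = sim.simulate_acquisition(cfg, pops, {"D1": 550.0}, 400_000, 12)
        v = t.column("D1")
        for q in (0.1587, 0.5, 0.8413, 0.9):
            assert sim.analytic_quantile(cfg, "D1", 550.0, q) == \
                pytest.approx(np.quantile(v, q), rel=0.02, abs=0.5)

    def test_clip_fraction_prediction(self):
        cfg = sim.make_config(1, brightness=200_000.0)
        pops = [sim.PopulationSpec("pos", 1.0, {"F1": 1.0})]
        t = sim.simulate_acquisition(cfg, pops, {"D1": 550.0}, 200_000, 13)
        predicted = sim.analytic_clip_fraction(cfg, "D1", 550.0,
                                               load_median=200_000.0)
        observed = t.meta["clip_high_frac"]["D1"]
        assert observed == pytest.approx(predicted, rel=0.1, abs=0.002)
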