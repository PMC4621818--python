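"""Synthetic-data generators: designs, determinism, ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drylysim import association, coloc, expression, lysimetry, phenotypes, synth


class TestClimate:
    def test_temperature_range_and_peak(self):
        clim = synth.simulate_climate(days=1, step_min=10, seed=0)
        assert clim["air_temp_c"].max() == pytest.approx(34.0)
        assert clim["air_temp_c"].min() == pytest.approx(15.0)
        peak = clim["air_temp_c"].idxmax()
        assert peak.hour == 14

    def test_determinism(self):
        a = synth.simulate_climate(days=2, step_min=10, seed=5, noise_sd=0.5)
        b = synth.simulate_climate(days=2, step_min=10, seed=5, noise_sd=0.5)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_free_vpd_identical_across_days(self):
        clim = synth.simulate_climate(days=7, step_min=10, seed=0)
        vpd = lysimetry.compute_vpd(
            clim["air_temp_c"].to_numpy(), clim["rel_humidity_pct"].to_numpy()
        )
        daily_peak = pd.Series(vpd, index=clim.index).groupby(
            clim.index.normalize()
        ).max()
        assert daily_peak.std() < 1e-12

    def test_humidity_within_bounds(self):
        clim = synth.simulate_climate(days=2, step_min=10, seed=1, noise_sd=5.0)
        assert clim["rel_humidity_pct"].between(0, 100).all()

    @pytest.mark.parametrize("kwargs", [dict(days=0), dict(days=1, step_min=7)])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.simulate_climate(**{"step_min": 10, "seed": 0, **kwargs})


class TestLysimeterRun:
    def test_water_balance_closes(self, noisefree_run):
        led = noisefree_run.ledger
        cap = 1000.0
        w0 = noisefree_run.probe.data["swc"].iloc[0] * cap
        w1 = noisefree_run.probe.data["swc"].iloc[-1] * cap
        resid = (
            led["irrigation_g"].sum() - led["drainage_g"].sum()
            - (w1 - w0) - led["transpiration_g"].sum()
        )
        assert abs(resid) < 1e-6

    def test_predawn_weights_step_by_biomass_gain(self, climate17):
        """Without drought, each predawn weight is the previous plus gain."""
        truth = synth.LysimeterTruth("g")
        run = synth.simulate_lysimeter_run(truth, climate17, phases=(6, 0, 0))
        w = run.trace.data["weight_g"]
        predawn = w.between_time("04:30", "05:00").groupby(
            w.between_time("04:30", "05:00").index.normalize()
        ).mean()
        steps = predawn.diff().dropna().to_numpy()
        gains = run.ledger["biomass_gain_g"].to_numpy()[: len(steps)]
        assert np.allclose(steps, gains, atol=1e-6)

    def test_zero_e_max_flat_between_irrigations(self, climate17):
        truth = synth.LysimeterTruth("flat", e_max_true=0.0)
        run = synth.simulate_lysimeter_run(truth, climate17, phases=(3, 0, 0))
        # flat outside the nightly irrigation-to-drainage window
        w = run.trace.data["weight_g"].between_time("00:00", "21:50")
        per_day = w.groupby(w.index.normalize()).agg(["min", "max"])
        assert ((per_day["max"] - per_day["min"]).abs() < 1e-9).all()

    def test_no_irrigation_during_drought(self, noisefree_run):
        drought = noisefree_run.trace.data.loc["2010-08-08":"2010-08-17"]
        assert not drought["irrigation"].any()

    def test_determinism_with_noise(self, climate17):
        truth = synth.LysimeterTruth("g", seed=9)
        a = synth.simulate_lysimeter_run(truth, climate17, phases=(3, 2, 0), noise_g=1.0)
        b = synth.simulate_lysimeter_run(truth, climate17, phases=(3, 2, 0), noise_g=1.0)
        pd.testing.assert_frame_equal(a.trace.data, b.trace.data)

    def test_weight_monotone_decline_during_drought_day(self, noisefree_run):
        day = noisefree_run.trace.data.loc["2010-08-10"]
        deltas = np.diff(day["weight_g"].to_numpy())
        assert (deltas <= 1e-9).all()

    def test_climate_shorter_than_phases_rejected(self):
        clim = synth.simulate_climate(days=2, step_min=10, seed=0)
        truth = synth.LysimeterTruth("g")
        with pytest.raises(ValueError):
            synth.simulate_lysimeter_run(truth, clim, phases=(7, 10, 0))


class TestPanel:
    def test_study_scale_dimensions(self):
        panel = synth.simulate_panel(n_acc=95, n_snp=1127, seed=0)
        assert panel.genotypes.shape == (95, 1127)
        assert panel.q.shape[0] == 95
        assert panel.k.shape == (95, 95)

    def test_q_rows_sum_to_one_and_k_psd(self, small_panel):
        assert np.allclose(small_panel.q.sum(axis=1), 1.0)
        k = small_panel.k.to_numpy()
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-8

    def test_inbred_coding(self, small_panel):
        vals = set(np.unique(small_panel.genotypes.to_numpy()))
        assert vals <= {0.0, 2.0}

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            synth.PanelTruth(h2={"Scu": 1.5})

    def test_scores_cover_ordinal_range(self, small_panel):
        assert small_panel.scores["score"].between(0, 5).all()
        assert small_panel.scores["score"].nunique() == 6

    def test_null_panel_pvalues_uniform(self):
        """With no planted signal the scan's p-values are Uniform(0,1)."""
        panel = synth.simulate_panel(n_acc=95, n_snp=1000, seed=42)
        means = phenotypes.accession_means(panel.scores)
        res = association.glm_scan(means["Wt2012"], panel.genotypes, panel.q)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_causal_snp_tops_the_scan(self):
        """A strong causal marker attains the panel minimum p in >=90% of seeds."""
        truth = synth.PanelTruth(causal_snps={"Scu": [(10, 1.0)]}, h2={"Scu": 0.5})
        hits = 0
        for seed in range(50):
            panel = synth.simulate_panel(n_acc=200, n_snp=150, truth=truth, seed=seed)
            means = phenotypes.accession_means(panel.scores)
            res = association.glm_scan(means["Scu2011"], panel.genotypes, panel.q)
            best = res.loc[res["neg_log10_p"].idxmax(), "marker"]
            hits += int(best == panel.genotypes.columns[10])
        assert hits >= 45

    def test_determinism(self):
        a = synth.simulate_panel(n_acc=30, n_snp=50, seed=3)
        b = synth.simulate_panel(n_acc=30, n_snp=50, seed=3)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.scores, b.scores)


class TestExpressionSim:
    def test_factorial_design_yields_24_samples(self):
        sim = synth.simulate_expression(n_genes=100, seed=0)
        assert sim.matrix.shape[1] == 24
        assert len(sim.annotations) == 24
        cells = sim.annotations.groupby(["genotype", "tissue", "treatment"]).size()
        assert (cells == 3).all()

    def test_single_replicate_design_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_expression(n_genes=10, n_reps=1, seed=0)

    def test_weak_planted_effect_rejected(self):
        with pytest.raises(ValueError):
            synth.ExpressionTruth(true_degs={("B47", "leaf"): {"UG00001": 0.5}})

    def test_null_design_produces_no_deg_calls(self):
        sim = synth.simulate_expression(n_genes=1000, seed=6)
        norm = expression.quantile_normalize(sim.matrix)
        de = expression.de_test(norm, sim.annotations, "B47", "leaf")
        assert len(expression.call_degs(de)) == 0

    def test_low_noise_planted_degs_recovered(self):
        """Planted |log2FC|=2 DEGs at low replicate noise: recall >= 0.9."""
        ids = [f"UG{i:05d}" for i in range(100)]
        truth = synth.ExpressionTruth(
            true_degs={("B47", "leaf"): {g: (2.0 if i % 2 else -2.0)
                                         for i, g in enumerate(ids)}}
        )
        recalls = []
        for seed in range(5):
            sim = synth.simulate_expression(
                n_genes=1000, truth=truth, seed=seed, rep_sd=0.05
            )
            de = expression.de_test(
                expression.quantile_normalize(sim.matrix), sim.annotations,
                "B47", "leaf",
            )
            called = set(expression.call_degs(de)["unigene_id"])
            recalls.append(len(called & set(ids)) / len(ids))
        assert np.mean(recalls) >= 0.9


class TestMaps:
    def test_eleven_linkage_groups_generated(self):
        maps = synth.simulate_maps(n_deg=200, n_snp=39, planted_pairs=5, seed=0)
        assert set(maps.snp_map["linkage_group"]) <= set(range(1, 12))
        assert maps.deg_map["linkage_group"].nunique() == 11

    def test_zero_planted_pairs_empty_candidates(self):
        maps = synth.simulate_maps(n_deg=50, n_snp=20, planted_pairs=0, seed=1)
        cand = coloc.genetic_colocalize(maps.deg_map, maps.snp_map)
        assert len(cand) == 0

    def test_planted_pairs_exactly_recovered(self):
        maps = synth.simulate_maps(n_deg=100, n_snp=39, planted_pairs=7, seed=4)
        genetic = coloc.genetic_colocalize(maps.deg_map, maps.snp_map)
        assert set(zip(genetic["unigene_id"], genetic["snp"])) == maps.genetic_pairs
        deg_best = coloc.best_ortholog(maps.deg_hits)
        snp_best = coloc.best_ortholog(maps.snp_hits)
        physical = coloc.physical_colocalize(deg_best, snp_best)
        assert set(zip(physical["unigene_id"], physical["snp"])) == maps.physical_pairs

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError):
            synth.simulate_maps(n_deg=10, n_snp=5, planted_pairs=7, seed=0)
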