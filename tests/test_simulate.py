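"""Synthetic experiment generator: invariants, seeding, and effect structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stoichres import (EffectConfig, apply_disturbance,
                       generate_control_abundances, generate_experiment,
                       generate_sites, resistance_index)
from stoichres.config import SiteModel
from stoichres.errors import InvalidArgumentError, InvalidConfigError
from stoichres.panel import ALL_GENES, FUNCTIONAL_GENES, STRESSORS


def zero_noise_config():
    cfg = EffectConfig()
    sm = cfg.site_model
    totals = {k: (v[0], v[1], v[2], 0.0) for k, v in sm.totals.items()}
    return cfg.replace(
        site_model=SiteModel(sm.mat_range, sm.map_range, totals),
        abundance_noise_sd=0.0)


class TestGenerateSites:
    def test_shape_and_ratio_invariants(self):
        sites = generate_sites(54, seed=0)
        assert len(sites) == 54
        assert sites["site_id"].is_unique
        for col in ("total_c", "total_n", "total_p"):
            assert (sites[col] > 0).all()
        assert np.allclose(sites["cn"], sites["total_c"] / sites["total_n"],
                           atol=1e-9)
        assert np.allclose(sites["cp"], sites["total_c"] / sites["total_p"],
                           atol=1e-9)
        assert np.allclose(sites["np"], sites["total_n"] / sites["total_p"],
                           atol=1e-9)

    def test_climate_gradients_cover_configured_ranges(self):
        sites = generate_sites(500, seed=1)
        assert sites["mat"].between(0, 20).all()
        assert sites["map"].between(100, 1600).all()

    def test_too_few_sites_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_sites(1, seed=0)

    def test_non_finite_config_rejected(self):
        cfg = EffectConfig()
        cfg.site_model.totals["total_c"] = (12.0, np.nan, 0.0, 0.25)
        with pytest.raises(InvalidConfigError):
            generate_sites(5, seed=0, config=cfg)

    def test_zero_noise_sites_on_regression_surface(self):
        cfg = zero_noise_config()
        sites = generate_sites(2, seed=3, config=cfg)
        z_map = stats.zscore(sites["map"], ddof=0)
        z_mat = stats.zscore(sites["mat"], ddof=0)
        for name, (mean, s_map, s_mat, _) in cfg.site_model.totals.items():
            expected = np.exp(np.log(mean) + s_map * z_map + s_mat * z_mat)
            np.testing.assert_allclose(sites[name], expected, rtol=1e-12)

    def test_seeding_contract(self):
        a = generate_sites(10, seed=7)
        b = generate_sites(10, seed=7)
        c = generate_sites(10, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.drop(columns=["site_id", "province"]).equals(
            c.drop(columns=["site_id", "province"]))


class TestControlAbundances:
    def test_constant_at_intercept_without_slopes_or_noise(self, panel):
        cfg = EffectConfig(slopes={}, abundance_noise_sd=0.0)
        sites = generate_sites(5, seed=0)
        ab = generate_control_abundances(sites, panel, cfg, seed=0)
        for gene in ALL_GENES:
            vals = ab.loc[ab["gene"] == gene, "copies_per_g"]
            np.testing.assert_allclose(
                vals, 10.0 ** cfg.intercepts[gene], rtol=1e-12)

    def test_reported_correlation_signs_at_large_n(self):
        """phoD tracks total N (+) and total P (-); nifH tracks total C (+)."""
        cfg = EffectConfig()
        sites = generate_sites(500, seed=11, config=cfg)
        ab = generate_control_abundances(sites, config=cfg, seed=11)
        wide = ab.pivot(index="site_id", columns="gene",
                        values="copies_per_g").loc[sites["site_id"]]
        r_p, p_p = stats.pearsonr(np.log10(wide["phoD"]), sites["total_p"])
        r_n, p_n = stats.pearsonr(np.log10(wide["phoD"]), sites["total_n"])
        r_c, p_c = stats.pearsonr(np.log10(wide["nifH"]), sites["total_c"])
        assert r_p < 0 and p_p < 0.01
        assert r_n > 0 and p_n < 0.01
        assert r_c > 0 and p_c < 0.01

    def test_sign_recovery_for_every_configured_slope(self):
        """Over 20 seeds at n=500, sample correlation signs match the
        configured effect signs for every gene x predictor pair."""
        cfg = EffectConfig()
        mismatches = 0
        total = 0
        for seed in range(20):
            sites = generate_sites(500, seed, cfg)
            ab = generate_control_abundances(sites, config=cfg, seed=seed)
            wide = ab.pivot(index="site_id", columns="gene",
                            values="copies_per_g").loc[sites["site_id"]]
            logw = np.log10(wide)
            preds = dict(sites[["mat", "map", "total_c", "total_n", "total_p",
                                "cn", "cp", "np"]])
            preds["log_16S"] = logw["bact_16S"]
            preds["log_ITS"] = logw["fungal_ITS"]
            for gene, slopes in cfg.slopes.items():
                for pred, b in slopes.items():
                    r = np.corrcoef(preds[pred], logw[gene])[0, 1]
                    total += 1
                    mismatches += np.sign(r) != np.sign(b)
        assert mismatches / total <= 0.01

    def test_unknown_gene_in_config_rejected(self, panel):
        cfg = EffectConfig(slopes={"notAgene": {"mat": 0.1}})
        sites = generate_sites(5, seed=0)
        with pytest.raises(InvalidConfigError):
            generate_control_abundances(sites, panel, cfg, seed=0)


class TestDisturbance:
    def test_zero_effect_is_identity_and_rs_one(self, panel):
        cfg = EffectConfig()
        for dm in cfg.disturbance.values():
            dm.baseline = {}
            dm.slopes = {}
            dm.noise_sd = 0.0
        sites = generate_sites(6, seed=2)
        control = generate_control_abundances(sites, panel, cfg, seed=2)
        treated = apply_disturbance(control, sites, "warming", cfg, seed=2)
        pd.testing.assert_frame_equal(
            control.assign(treatment="warming"), treated)
        rs = resistance_index(control["copies_per_g"].to_numpy(),
                              treated["copies_per_g"].to_numpy())
        np.testing.assert_array_equal(rs, 1.0)

    def test_unknown_stressor_rejected(self, small_bundle):
        control = small_bundle.abundances.query("treatment == 'control'")
        with pytest.raises(InvalidArgumentError):
            apply_disturbance(control, small_bundle.site_table, "flooding")

    def test_n_deposition_hits_carbon_genes_harder_than_amoA_b(self):
        """GH51's larger baseline effect gives it lower mean resistance to
        N deposition than amoA-b (n=200 sites)."""
        bundle = generate_experiment(n_sites=200, seed=5)
        control = bundle.abundances.query("treatment == 'control'")
        treated = bundle.abundances.query("treatment == 'n_deposition'")
        merged = control.merge(treated, on=["site_id", "gene"],
                               suffixes=("_c", "_t"))
        rs = merged.assign(rs=resistance_index(
            merged["copies_per_g_c"].to_numpy(),
            merged["copies_per_g_t"].to_numpy()))
        mean_rs = rs.groupby("gene")["rs"].mean()
        assert mean_rs["amoA-b"] > mean_rs["GH51"]

    def test_doubling_baseline_strictly_decreases_rs(self, panel):
        cfg = EffectConfig()
        for dm in cfg.disturbance.values():
            dm.slopes = {}
            dm.noise_sd = 0.0
        sites = generate_sites(8, seed=9)
        control = generate_control_abundances(sites, panel, cfg, seed=9)
        t1 = apply_disturbance(control, sites, "warming", cfg, seed=9)
        cfg2 = EffectConfig()
        for st, dm in cfg2.disturbance.items():
            dm.baseline = {g: 2 * v for g, v in cfg.disturbance[st].baseline.items()}
            dm.slopes = {}
            dm.noise_sd = 0.0
        t2 = apply_disturbance(control, sites, "warming", cfg2, seed=9)
        c0 = control["copies_per_g"].to_numpy()
        rs1 = resistance_index(c0, t1["copies_per_g"].to_numpy())
        rs2 = resistance_index(c0, t2["copies_per_g"].to_numpy())
        func = control["gene"].isin(FUNCTIONAL_GENES).to_numpy()
        assert (rs2[func] < rs1[func]).all()


class TestExperiment:
    def test_default_design_yields_216_samples(self):
        bundle = generate_experiment(n_sites=54, seed=0)
        assert bundle.n_samples == 216

    def test_two_sites_yield_eight_samples(self):
        bundle = generate_experiment(n_sites=2, seed=0)
        assert bundle.n_samples == 8

    def test_all_abundances_positive(self, small_bundle):
        assert (small_bundle.abundances["copies_per_g"] > 0).all()
        assert set(small_bundle.abundances["treatment"]) == {
            "control", *STRESSORS}

    def test_ground_truth_round_trip(self, small_bundle):
        gt = small_bundle.ground_truth
        again = generate_experiment(gt["config"], gt["n_sites"], gt["seed"])
        pd.testing.assert_frame_equal(small_bundle.site_table, again.site_table)
        pd.testing.assert_frame_equal(small_bundle.abundances, again.abundances)
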