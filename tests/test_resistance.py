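"""Resistance index, group normalization, and cross-stressor comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stoichres import (compare_stressors, generate_experiment, group_resistance,
                       normalize_group, resistance_index, resistance_table)
from stoichres.errors import (AlignmentError, DegenerateInputError,
                              InvalidArgumentError, InvalidInputError,
                              UndefinedControlError)
from stoichres.panel import FUNCTIONAL_GENES


class TestResistanceIndex:
    def test_no_change_is_complete_resistance(self):
        assert resistance_index(100.0, 100.0) == 1.0

    def test_hundred_percent_change_is_zero(self):
        assert resistance_index(50.0, 100.0) == 0.0

    def test_hand_example(self):
        assert resistance_index(4.0, 2.0) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_huge_change_approaches_but_never_reaches_minus_one(self):
        # rs + 1 = 2 c0 / (c0 + |d0|) = 2/1e6 exactly here
        rs = resistance_index(1.0, 1e6)
        assert -1.0 < rs <= -1.0 + 2.000001e-6

    def test_complete_loss_is_zero(self):
        assert resistance_index(123.0, 0.0) == 0.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(UndefinedControlError):
            resistance_index(0.0, 10.0)
        with pytest.raises(UndefinedControlError):
            resistance_index(np.array([1.0, -2.0]), np.array([1.0, 1.0]))

    def test_negative_treated_rejected(self):
        with pytest.raises(InvalidArgumentError):
            resistance_index(10.0, -1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(c0=st.floats(1e-3, 1e6), d=st.floats(0, 1e9))
    def test_bounds_hold_everywhere(self, c0, d):
        rs = resistance_index(c0, c0 + d)
        assert -1.0 < rs <= 1.0

    def test_strictly_decreasing_in_change_magnitude(self):
        c0 = 37.0
        d = np.linspace(0.0, 500.0, 1000)
        rs = resistance_index(np.full_like(d, c0), c0 + d)
        assert np.all(np.diff(rs) < 0)


class TestResistanceTable:
    def test_identity_treatment_gives_all_ones(self, small_bundle):
        control = small_bundle.abundances.query("treatment == 'control'")
        treated = control.assign(treatment="warming")
        rt = resistance_table(control, treated, "warming")
        np.testing.assert_array_equal(rt["rs"], 1.0)

    def test_record_count_is_sites_times_genes(self):
        bundle = generate_experiment(n_sites=54, seed=0)
        control = bundle.abundances.query("treatment == 'control'")
        control = control[control["gene"].isin(FUNCTIONAL_GENES)]
        treated = bundle.abundances.query("treatment == 'warming'")
        treated = treated[treated["gene"].isin(FUNCTIONAL_GENES)]
        rt = resistance_table(control, treated, "warming")
        assert len(rt) == 54 * 16

    def test_missing_site_raises_alignment_error(self, small_bundle):
        control = small_bundle.abundances.query("treatment == 'control'")
        treated = small_bundle.abundances.query("treatment == 'warming'")
        treated = treated[treated["site_id"] != "S03"]
        with pytest.raises(AlignmentError, match="S03"):
            resistance_table(control, treated, "warming")

    def test_nonpositive_control_excluded_and_reported(self, small_bundle):
        control = small_bundle.abundances.query("treatment == 'control'").copy()
        treated = small_bundle.abundances.query("treatment == 'warming'")
        control.iloc[0, control.columns.get_loc("copies_per_g")] = 0.0
        rt = resistance_table(control, treated, "warming")
        assert len(rt.attrs["excluded"]) == 1
        assert len(rt) == len(control) - 1


class TestNormalizeGroup:
    def test_equal_abundances_give_equal_shares(self):
        values = pd.DataFrame({"g1": [2.0, 2.0, 2.0, 2.0]})
        scores = normalize_group(values, ["g1"])
        np.testing.assert_allclose(scores, 0.25)

    def test_two_gene_hand_example(self):
        values = pd.DataFrame({"g1": [1.0, 3.0], "g2": [2.0, 2.0]})
        scores = normalize_group(values, ["g1", "g2"])
        np.testing.assert_allclose(scores, [0.375, 0.625], atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(2, 8), st.integers(1, 5), st.integers(0, 2 ** 31 - 1))
    def test_scores_sum_to_one(self, n_samples, n_genes, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.uniform(0.1, 100.0, (n_samples, n_genes)),
                              columns=[f"g{i}" for i in range(n_genes)])
        scores = normalize_group(values, list(values.columns))
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_rescaling_one_gene(self, rng):
        values = pd.DataFrame(rng.uniform(1.0, 50.0, (6, 3)),
                              columns=["a", "b", "c"])
        scaled = values.assign(b=values["b"] * 1e4)
        np.testing.assert_allclose(normalize_group(values, ["a", "b", "c"]),
                                   normalize_group(scaled, ["a", "b", "c"]),
                                   rtol=1e-12)

    def test_error_paths(self):
        values = pd.DataFrame({"g1": [1.0, -1.0]})
        with pytest.raises(InvalidInputError):
            normalize_group(values, ["g1"])
        with pytest.raises(DegenerateInputError):
            normalize_group(pd.DataFrame({"g1": [0.0, 0.0]}), ["g1"])


class TestGroupResistance:
    @staticmethod
    def records(rs_by_gene, sites=("S1", "S2")):
        rows = []
        for site in sites:
            for gene, rs in rs_by_gene.items():
                rows.append({"site_id": site, "gene": gene,
                             "stressor": "warming", "rs": rs})
        return pd.DataFrame(rows)

    def test_all_ones_gives_one(self):
        rec = self.records({"a": 1.0, "b": 1.0})
        np.testing.assert_allclose(group_resistance(rec, ["a", "b"]), 1.0)

    def test_mean_mode_hand_example(self):
        rec = self.records({"a": 0.2, "b": 0.4, "c": 0.6})
        np.testing.assert_allclose(group_resistance(rec, ["a", "b", "c"]), 0.4)

    def test_mean_mode_matches_brute_force(self, small_bundle):
        control = small_bundle.abundances.query("treatment == 'control'")
        treated = small_bundle.abundances.query("treatment == 'n_deposition'")
        rt = resistance_table(control, treated, "n_deposition")
        genes = ["nifH", "narG", "nosZ"]
        got = group_resistance(rt, genes)
        for site in rt["site_id"].unique():
            manual = rt[(rt["site_id"] == site)
                        & rt["gene"].isin(genes)]["rs"].mean()
            assert got[site] == pytest.approx(manual, abs=1e-12)

    def test_eq2_mode_scores_sum_to_one(self, small_bundle):
        control = small_bundle.abundances.query("treatment == 'control'")
        treated = small_bundle.abundances.query("treatment == 'warming'")
        rt = resistance_table(control, treated, "warming")
        scores = group_resistance(rt, ["nifH", "narG"], mode="eq2")
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_gene_reported(self):
        rec = self.records({"a": 0.5})
        with pytest.raises(InvalidInputError, match="zzz"):
            group_resistance(rec, ["a", "zzz"])


class TestCompareStressors:
    @staticmethod
    def records(shift=0.0, n=54, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for stressor in ("drying_wetting", "warming", "n_deposition"):
            delta = shift if stressor == "warming" else 0.0
            vals = np.clip(rng.normal(0.5 + delta, 0.1, n), -0.99, 1.0)
            for i, v in enumerate(vals):
                rows.append({"site_id": f"S{i}", "gene": "nifH",
                             "stressor": stressor, "rs": v})
        return pd.DataFrame(rows)

    def test_identical_distributions_not_significant(self):
        rec = self.records(shift=0.0, seed=1)
        out = compare_stressors(rec)
        assert not out["significant"].iloc[0]
        assert out["p"].iloc[0] > 0.05
        # identical values exactly
        rec["rs"] = 0.5
        out = compare_stressors(rec)
        assert out["p"].iloc[0] == 1.0

    def test_three_sd_shift_detected_with_direction(self):
        rec = self.records(shift=0.3, seed=2)
        out = compare_stressors(rec)
        row = out.iloc[0]
        assert row["significant"]
        assert row["mean_rs"]["warming"] > row["mean_rs"]["drying_wetting"]
        pw = row["pairwise"]
        dw_warm = pw[(pw["group_a"] == "drying_wetting")
                     & (pw["group_b"] == "warming")]
        assert dw_warm["p"].iloc[0] < 0.05
        assert row["letters"]["warming"] != row["letters"]["drying_wetting"]

    def test_parametric_alternative_agrees_on_strong_effect(self):
        rec = self.records(shift=0.3, seed=3)
        out = compare_stressors(rec, method="anova")
        assert out["significant"].iloc[0]

    def test_too_few_sites_rejected(self):
        rec = self.records(n=1)
        with pytest.raises(InvalidInputError):
            compare_stressors(rec)

    def test_amoA_b_most_resistant_to_n_deposition_on_defaults(self):
        bundle = generate_experiment(n_sites=54, seed=3)
        control = bundle.abundances.query("treatment == 'control'")
        frames = []
        for stressor in ("drying_wetting", "warming", "n_deposition"):
            treated = bundle.abundances.query("treatment == @stressor")
            frames.append(resistance_table(control, treated, stressor))
        rec = pd.concat(frames, ignore_index=True)
        out = compare_stressors(rec, genes=["amoA-b"])
        means = out.iloc[0]["mean_rs"]
        assert means["n_deposition"] > means["warming"]
        assert means["n_deposition"] > means["drying_wetting"]
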