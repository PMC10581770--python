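"""Subnetwork aggregation, random-forest screening and enrichment testing."""

import numpy as np
import pandas as pd
import pytest

from exocue.core_model import PipelineConfig, ValidationError
from exocue.subnetwork_enrichment import (
    aggregate_subnetworks,
    detect_treatment_only,
    enrichment_ttests,
    ontology_composition,
    profile_log10,
    rf_screen,
    select_by_mda,
)

import _oracles as oracles
from conftest import as_rows, random_dataset


def sample_table(n_control, n_treatment, n_blank=0):
    ids = (
        [f"B{i}" for i in range(n_blank)]
        + [f"C{i}" for i in range(n_control)]
        + [f"T{i}" for i in range(n_treatment)]
    )
    roles = ["blank"] * n_blank + ["control"] * n_control + ["treatment"] * n_treatment
    return pd.DataFrame(
        {"role": roles, "group_label": "", "replicate": 1},
        index=pd.Index(ids, name="sample_id"),
    )


def profiles_from(values: dict[str, list[float]], samples) -> pd.DataFrame:
    out = pd.DataFrame.from_dict(values, orient="index", columns=samples.index)
    out.index.name = "subnetwork_id"
    return out


class TestAggregate:
    def test_singleton_subnetwork_equals_feature_row(self, toy_tables):
        matrix, features, _ = toy_tables
        profiles = aggregate_subnetworks(matrix, features)
        np.testing.assert_allclose(profiles.loc["SN2"], matrix.loc["F3"])

    def test_two_member_sum(self, toy_tables):
        matrix, features, _ = toy_tables
        profiles = aggregate_subnetworks(matrix, features)
        assert profiles.at["SN1", "C1"] == pytest.approx(1e5 + 5e4)

    def test_random_fixture_matches_oracle(self):
        matrix, features, samples = random_dataset(np.random.default_rng(2))
        profiles = aggregate_subnetworks(matrix, features)
        expected = oracles.subnetwork_sums(
            as_rows(matrix), list(matrix.columns), features["subnetwork_id"].to_dict()
        )
        for sub, per_sample in expected.items():
            for sample, value in per_sample.items():
                assert profiles.at[sub, sample] == pytest.approx(value, rel=1e-12)


class TestMdaSelection:
    def test_hand_computed_threshold(self, cfg):
        # mean 2.5, sd 5 -> threshold 7.5: only the 10 passes
        mda = pd.Series([0.0, 0.0, 0.0, 10.0], index=list("abcd"))
        assert select_by_mda(mda, cfg) == {"d"}

    def test_all_equal_mda_selects_everything(self, cfg):
        mda = pd.Series([0.3, 0.3, 0.3], index=list("abc"))
        assert select_by_mda(mda, cfg) == {"a", "b", "c"}

    def test_sd_multiplier_config(self):
        mda = pd.Series([0.0, 0.0, 0.0, 10.0], index=list("abcd"))
        lax = PipelineConfig(mda_sd_multiplier=0.5)
        assert select_by_mda(mda, lax) == {"d"}


def quick_cfg(seed=0, trees=150, reps=200):
    return PipelineConfig(n_trees=trees, n_importance_reps=reps, rng_seed=seed)


class TestRfScreen:
    def make_profiles(self, seed, n_sub=30, n_per=5, effect=1.0):
        rng = np.random.default_rng(seed)
        samples = sample_table(n_per, n_per)
        values = rng.normal(5.0, 0.2, size=(n_sub, 2 * n_per))
        values[0, n_per:] += effect  # SN0 planted
        profiles = pd.DataFrame(
            values,
            index=pd.Index([f"SN{i}" for i in range(n_sub)], name="subnetwork_id"),
            columns=samples.index,
        )
        return profiles, samples

    def test_bit_reproducible_given_seed(self):
        profiles, samples = self.make_profiles(4)
        mda1, sel1 = rf_screen(profiles, samples, quick_cfg(11))
        mda2, sel2 = rf_screen(profiles, samples, quick_cfg(11))
        pd.testing.assert_series_equal(mda1, mda2)
        assert sel1 == sel2

    def test_seed_changes_result(self):
        profiles, samples = self.make_profiles(4)
        mda1, _ = rf_screen(profiles, samples, quick_cfg(11))
        mda2, _ = rf_screen(profiles, samples, quick_cfg(12))
        assert not np.allclose(mda1, mda2)

    def test_single_class_rejected(self):
        profiles, samples = self.make_profiles(4)
        only_ctrl = samples[samples["role"] == "control"]
        with pytest.raises(ValidationError):
            rf_screen(profiles[only_ctrl.index], only_ctrl, quick_cfg())

    def test_blank_samples_rejected(self):
        samples = sample_table(4, 4, n_blank=2)
        rng = np.random.default_rng(4)
        profiles = profiles_from(
            {f"SN{i}": rng.normal(5, 0.2, len(samples)) for i in range(5)}, samples
        )
        with pytest.raises(ValidationError, match="blank"):
            rf_screen(profiles, samples, quick_cfg())

    def test_too_few_subnetworks_rejected(self):
        samples = sample_table(3, 3)
        profiles = profiles_from({"SN0": [1, 2, 3, 4, 5, 6]}, samples)
        with pytest.raises(ValidationError):
            rf_screen(profiles, samples, quick_cfg())

    def test_planted_effect_ranks_first(self):
        hits = 0
        for seed in range(10):
            profiles, samples = self.make_profiles(seed)
            mda, selected = rf_screen(profiles, samples, quick_cfg(seed))
            if "SN0" in selected and mda.idxmax() == "SN0":
                hits += 1
        assert hits >= 9  # strong single effect is found nearly always


class TestEnrichmentTtests:
    def test_identical_groups_give_p_one_direction_none(self, cfg):
        samples = sample_table(3, 3)
        profiles = profiles_from({"SN0": [3, 3, 3, 3, 3, 3], "SN1": [1, 2, 3, 1, 2, 3]},
                                 samples)
        mda = pd.Series([1.0, 0.5], index=profiles.index)
        res = enrichment_ttests(profiles, samples, mda, {"SN0"}, cfg)
        assert res.at["SN0", "p_raw"] == 1.0
        assert res.at["SN0", "t_stat"] == 0.0
        assert res.at["SN0", "direction"] == "none"
        assert np.isnan(res.at["SN1", "p_raw"])  # unselected: untested

    def test_bh_adjustment_matches_hand_computation(self, cfg):
        # raw p {0.01, 0.02, 0.04} -> BH q {0.03, 0.03, 0.04}
        rng = np.random.default_rng(0)
        samples = sample_table(4, 4)
        raw_ps = [0.01, 0.02, 0.04]
        # construct groups whose pooled t-test p equals the target p exactly
        from scipy import stats

        values = {}
        for i, p in enumerate(raw_ps):
            t = stats.t.isf(p / 2, df=6)
            # groups with sd fixed: mean diff tuned to give statistic t
            base = np.array([-1.0, 0.0, 1.0, 0.0])
            s = base.std(ddof=1)
            shift = t * s * np.sqrt(2.0 / 4.0)
            values[f"SN{i}"] = np.concatenate([base, base + shift])
        profiles = profiles_from(values, samples)
        mda = pd.Series(1.0, index=profiles.index)
        res = enrichment_ttests(profiles, samples, mda, set(profiles.index), cfg)
        np.testing.assert_allclose(res["p_raw"].sort_values(), raw_ps, rtol=1e-9)
        np.testing.assert_allclose(
            sorted(res["q_fdr"]), oracles.bh_adjust(raw_ps), rtol=1e-9
        )
        np.testing.assert_allclose(sorted(res["q_fdr"]), [0.03, 0.03, 0.04], rtol=1e-9)

    def test_direction_follows_sign_of_effect(self, cfg):
        rng = np.random.default_rng(1)
        samples = sample_table(3, 3)
        jitter = rng.normal(0, 1e-6, 6)
        profiles = profiles_from(
            {"SN0": np.array([1, 1, 1, 5, 5, 5]) + jitter,
             "SN1": np.array([5, 5, 5, 1, 1, 1]) + jitter},
            samples,
        )
        mda = pd.Series(1.0, index=profiles.index)
        res = enrichment_ttests(profiles, samples, mda, set(profiles.index), cfg)
        assert res.at["SN0", "direction"] == "treatment"
        assert res.at["SN1", "direction"] == "control"

    def test_zero_variance_unequal_means_warns_p_zero(self, cfg):
        samples = sample_table(3, 3)
        profiles = profiles_from({"SN0": [1, 1, 1, 5, 5, 5], "SN1": [1, 2, 1, 2, 1, 2]},
                                 samples)
        mda = pd.Series(1.0, index=profiles.index)
        with pytest.warns(UserWarning, match="zero variance"):
            res = enrichment_ttests(profiles, samples, mda, {"SN0"}, cfg)
        assert res.at["SN0", "p_raw"] == 0.0

    def test_welch_variant_differs_under_unequal_variance(self):
        samples = sample_table(4, 4)
        profiles = profiles_from(
            {"SN0": [1.0, 1.1, 0.9, 1.0, 3.0, 7.0, 5.0, 1.0],
             "SN1": [0, 1, 0, 1, 0, 1, 0, 1]},
            samples,
        )
        mda = pd.Series(1.0, index=profiles.index)
        pooled = enrichment_ttests(
            profiles, samples, mda, {"SN0"}, PipelineConfig(welch=False)
        )
        welch = enrichment_ttests(
            profiles, samples, mda, {"SN0"}, PipelineConfig(welch=True)
        )
        assert pooled.at["SN0", "p_raw"] != welch.at["SN0", "p_raw"]

    def test_unknown_selection_rejected(self, cfg):
        samples = sample_table(2, 2)
        profiles = profiles_from({"SN0": [1, 2, 3, 4]}, samples)
        with pytest.raises(ValidationError):
            enrichment_ttests(profiles, samples, pd.Series(1.0, index=profiles.index),
                              {"SN9"}, cfg)


class TestTreatmentOnly:
    def build(self, control_values):
        samples = sample_table(2, 2)
        features = pd.DataFrame(
            {"mz": 300.0, "rt": 100.0,
             "subnetwork_id": ["SN0", "SN0", "SN0", "SN0"]},
            index=pd.Index([f"F{i}" for i in range(4)], name="feature_id"),
        )
        matrix = pd.DataFrame(
            np.column_stack([control_values, np.full((4, 2), 1e5)]),
            index=features.index,
            columns=samples.index,
        )
        results = pd.DataFrame(
            {"mda": 1.0, "selected": True, "t_stat": 3.0, "p_raw": 0.01,
             "q_fdr": 0.02, "direction": "treatment", "treatment_only": False},
            index=pd.Index(["SN0"], name="subnetwork_id"),
        )
        return matrix, features, samples, results

    def test_all_control_zero_flagged(self, cfg):
        matrix, features, samples, results = self.build(np.zeros((4, 2)))
        out = detect_treatment_only(matrix, features, samples, results, cfg)
        assert bool(out.at["SN0", "treatment_only"])

    def test_single_control_detection_blocks_strict_default(self, cfg):
        control = np.zeros((4, 2))
        control[0, 0] = 50.0
        matrix, features, samples, results = self.build(control)
        out = detect_treatment_only(matrix, features, samples, results, cfg)
        assert not bool(out.at["SN0", "treatment_only"])

    def test_relaxed_fraction(self):
        cfg = PipelineConfig(treatment_only_fraction=0.5)
        control = np.zeros((4, 2))
        control[0, 0] = 50.0  # 3 of 4 members control-absent
        matrix, features, samples, results = self.build(control)
        out = detect_treatment_only(matrix, features, samples, results, cfg)
        assert bool(out.at["SN0", "treatment_only"])


def enrichment_results(index, directions):
    return pd.DataFrame(
        {"mda": 1.0, "selected": True, "t_stat": 2.0, "p_raw": 0.01, "q_fdr": 0.02,
         "direction": directions, "treatment_only": False},
        index=pd.Index(index, name="subnetwork_id"),
    )


class TestOntology:
    def annotations(self, mapping):
        ann = pd.DataFrame(
            {"superclass": list(mapping.values()), "class": pd.NA, "subclass": pd.NA,
             "source": "consensus"},
            index=pd.Index(list(mapping), name="subnetwork_id"),
        )
        return ann

    def test_single_subnetwork_is_hundred_percent(self):
        samples = sample_table(2, 3)
        profiles = profiles_from({"SN0": [1, 1, 10.0, 20.0, 5.0]}, samples)
        res = enrichment_results(["SN0"], ["treatment"])
        out = ontology_composition(profiles, samples, res, self.annotations({"SN0": "X"}))
        assert out.loc[0, "superclass"] == "X"
        assert out.loc[0, "mean_pct"] == pytest.approx(100.0)
        assert out.loc[0, "sd_pct"] == pytest.approx(0.0)

    def test_even_split(self):
        samples = sample_table(2, 2)
        profiles = profiles_from(
            {"SN0": [1, 1, 7.0, 3.0], "SN1": [1, 1, 7.0, 3.0]}, samples
        )
        res = enrichment_results(["SN0", "SN1"], ["treatment", "treatment"])
        out = ontology_composition(
            profiles, samples, res, self.annotations({"SN0": "X", "SN1": "Y"})
        )
        np.testing.assert_allclose(out["mean_pct"], [50.0, 50.0])
        np.testing.assert_allclose(out["sd_pct"], [0.0, 0.0], atol=1e-12)

    def test_unannotated_pooled_as_unclassified_and_sums_to_100(self):
        rng = np.random.default_rng(8)
        samples = sample_table(2, 4)
        values = {f"SN{i}": rng.uniform(1, 100, 6) for i in range(5)}
        profiles = profiles_from(values, samples)
        res = enrichment_results(
            [f"SN{i}" for i in range(5)], ["treatment"] * 5
        )
        ann = self.annotations({"SN0": "X", "SN1": "Y"})  # SN2-4 unannotated
        out = ontology_composition(profiles, samples, res, ann)
        assert "unclassified" in set(out["superclass"])
        assert out["mean_pct"].sum() == pytest.approx(100.0)

    def test_mean_sd_match_bruteforce(self):
        rng = np.random.default_rng(12)
        samples = sample_table(2, 3)
        values = {f"SN{i}": rng.uniform(1, 100, 5) for i in range(4)}
        profiles = profiles_from(values, samples)
        res = enrichment_results([f"SN{i}" for i in range(4)], ["treatment"] * 4)
        mapping = {"SN0": "X", "SN1": "X", "SN2": "Y", "SN3": "Z"}
        out = ontology_composition(profiles, samples, res, self.annotations(mapping))
        treat_cols = ["T0", "T1", "T2"]
        pct = {}
        for col in treat_cols:
            total = sum(profiles.at[s, col] for s in mapping)
            for s, label in mapping.items():
                pct.setdefault(label, {}).setdefault(col, 0.0)
                pct[label][col] += profiles.at[s, col] / total * 100
        for label, per_sample in pct.items():
            vals = np.array(list(per_sample.values()))
            row = out[out["superclass"] == label].iloc[0]
            assert row["mean_pct"] == pytest.approx(vals.mean(), rel=1e-9)
            assert row["sd_pct"] == pytest.approx(vals.std(ddof=1), rel=1e-9)

    def test_no_enriched_warns_and_returns_empty(self):
        samples = sample_table(2, 2)
        profiles = profiles_from({"SN0": [1, 1, 1, 1]}, samples)
        res = enrichment_results(["SN0"], ["none"])
        with pytest.warns(UserWarning, match="no treatment-enriched"):
            out = ontology_composition(profiles, samples, res, None)
        assert out.empty


class TestRecoverySmall:
    def test_single_planted_subnetwork_recovered_across_seeds(self):
        """A 10x (1.0 log10) planted shift among 30 nulls is nearly always found."""
        found = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            samples = sample_table(5, 5)
            values = rng.normal(5.0, 0.2, size=(30, 10))
            values[0, 5:] += 1.0
            profiles = pd.DataFrame(
                values,
                index=pd.Index([f"SN{i}" for i in range(30)], name="subnetwork_id"),
                columns=samples.index,
            )
            cfg = quick_cfg(seed, trees=200, reps=300)
            mda, selected = rf_screen(profiles, samples, cfg)
            res = enrichment_ttests(profiles, samples, mda, selected, cfg)
            if res.at["SN0", "direction"] == "treatment":
                found += 1
        assert found >= 11
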