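"""Summary tables, two-sample tests, top-K concentration and overlap."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aelead as ae


def _pooled_t_oracle(x, y):
    """Textbook pooled-variance t-test, written independently of the
    implementation path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = (sum((v - x.mean()) ** 2 for v in x) + sum((v - y.mean()) ** 2 for v in y)) / (
        n1 + n2 - 2
    )
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestCompareMeans:
    def test_identical_samples_give_t_zero_p_one(self):
        t, df, p = ae.compare_means([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert df == 4

    def test_large_shift_is_detected(self):
        _, _, p = ae.compare_means([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_matches_hand_computed_pooled_formula(self):
        x, y = [2.1, 1.9, 2.0, 2.2], [2.9, 3.1, 3.0]
        t, df, p = ae.compare_means(x, y, "student")
        t0, p0 = _pooled_t_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_matches_oracle_on_random_gaussian_samples(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(3, 30))
            y = rng.normal(0.3, 1.4, rng.integers(3, 30))
            t, _, p = ae.compare_means(x, y, "student")
            t0, p0 = _pooled_t_oracle(x, y)
            assert abs(t - t0) < 1e-10 and abs(p - p0) < 1e-10

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            ae.compare_means([1.0], [1, 2, 3])
        with pytest.raises(ValueError, match="pooled variance"):
            ae.compare_means([2.0, 2.0], [2.0, 2.0])

    def test_welch_uses_satterthwaite_df(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 30.0, 50.0]
        _, df, _ = ae.compare_means(x, y, "welch")
        assert df < len(x) + len(y) - 2  # unequal variances shrink the df


class TestCompareProportions:
    def test_equal_proportions_give_z_zero_p_one(self):
        z, chi2, p = ae.compare_proportions(3, 10, 6, 20)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_seriousness_gap_is_highly_significant(self):
        # 2.5% of 670 vs 38.2% of 10455 serious-pain proportions
        _, _, p = ae.compare_proportions(17, 670, 3996, 10455)
        assert p < 0.001

    def test_symmetry_in_group_order(self):
        z1, _, p1 = ae.compare_proportions(5, 10, 2, 12)
        z2, _, p2 = ae.compare_proportions(2, 12, 5, 10)
        assert p1 == pytest.approx(p2) and z1 == pytest.approx(-z2)

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(UserWarning):
            _, _, p = ae.compare_proportions(0, 10, 0, 12)
        assert p == 1.0

    def test_chi2_is_z_squared(self):
        z, chi2, _ = ae.compare_proportions(8, 40, 3, 50)
        assert chi2 == pytest.approx(z * z)


def _flag_frame(n, n_specific, n_serious, stream, name="pain"):
    return pd.DataFrame(
        {
            "record_id": [f"{stream}{i}" for i in range(n)],
            "age": np.nan,
            "gender": "",
            f"has_{name}": [i < n_specific for i in range(n)],
            "serious_derived": [i < n_serious for i in range(n)],
            "rating": np.nan,
        }
    )


class TestSummarize:
    def test_proportions_from_counts(self):
        sm = _flag_frame(998, 670, 17, "sm")
        reg = _flag_frame(69003, 10455, 3996, "reg")
        table = ae.summarize(sm, reg, "pain").per_stream.set_index("stream")
        assert round(table.loc["social_media", "pct_specific"], 1) == 67.1
        assert round(table.loc["regulatory", "pct_specific"], 1) == 15.2
        assert round(table.loc["social_media", "pct_serious_specific"], 1) == 2.5
        assert round(table.loc["regulatory", "pct_serious_specific"], 1) == 38.2

    def test_all_serious_specific_gives_100_percent(self):
        sm = _flag_frame(10, 10, 10, "sm")
        t = ae.summarize(sm, None, "pain").per_stream.iloc[0]
        assert t["pct_specific"] == 100.0 and t["pct_serious_specific"] == 100.0

    def test_empty_dataset_yields_zero_table(self):
        t = ae.summarize(_flag_frame(0, 0, 0, "sm"), None, "pain").per_stream.iloc[0]
        assert t["N"] == 0 and t["pct_specific"] == 0.0

    def test_union_additivity(self, sib_clean):
        sm, _ = sib_clean
        half = sm.records.iloc[: sm.n // 2]
        rest = sm.records.iloc[sm.n // 2 :]
        n_a = ae.summarize(half, None, "cardiac").per_stream.iloc[0]["N"]
        n_b = ae.summarize(rest, None, "cardiac").per_stream.iloc[0]["N"]
        n_all = ae.summarize(sm.records, None, "cardiac").per_stream.iloc[0]["N"]
        assert n_a + n_b == n_all

    def test_missing_demographics_excluded_from_denominators(self):
        sm = _flag_frame(4, 2, 1, "sm")
        sm.loc[0, "gender"] = "F"
        sm.loc[1, "gender"] = "M"
        sm.loc[[0, 1], "age"] = [40.0, 50.0]
        t = ae.summarize(sm, None, "pain").per_stream.iloc[0]
        assert t["n_gender_known"] == 2 and t["pct_female"] == 50.0
        assert t["n_age_known"] == 2 and t["age_mean"] == 45.0


def _cat_frame(cat_lists, stream="social_media"):
    return pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(len(cat_lists))],
            "ae_categories": [set(c) for c in cat_lists],
        }
    )


class TestTopK:
    def test_uniform_single_label_concentration_is_one(self):
        cats = [[f"c{i % 5}"] for i in range(50)]
        t = ae.top_k_table(_cat_frame(cats), k=5)
        assert t.concentration[5] == 1.0

    def test_multilabel_record_counts_once(self):
        cats = [["a", "b", "c"], ["d"]]
        t = ae.top_k_table(_cat_frame(cats), k=3)
        # ties break alphabetically so top-3 is {a, b, c}; the record
        # mentioning all three still contributes 1 to the numerator
        assert t.categories[:3] == ["a", "b", "c"]
        assert t.concentration[3] == pytest.approx(0.5)

    def test_ties_break_alphabetically(self):
        cats = [["b"], ["a"], ["c"], ["a"], ["b"], ["c"]]
        t = ae.top_k_table(_cat_frame(cats), k=3)
        assert t.categories == ["a", "b", "c"]

    def test_k_exceeding_categories_noted(self):
        t = ae.top_k_table(_cat_frame([["a"], ["b"]]), k=10)
        assert t.k == 2 and "exceeds" in t.note

    def test_rank_one_category_under_study_mixture(self):
        """Sampling from the musculoskeletal-dominated review mixture puts
        muscle-or-bone pain on top essentially always."""
        cfg_base = ae.preset_config("atorvastatin", n_months=60)
        for seed in range(5):
            cfg = cfg_base.replace(seed=seed)
            sm, _, _ = ae.simulate_count_pair(cfg)
            reviews, _ = ae.simulate_reports(
                cfg,
                sm,
                ae.CountSeries(
                    pd.Series(0, index=sm.values.index), stream="regulatory"
                ),
            )
            cats = reviews.loc[reviews["truth_exclude"] == "", "truth_categories"].map(
                lambda s: set(s.split(";"))
            )
            t = ae.top_k_table(
                pd.DataFrame({"record_id": range(len(cats)), "ae_categories": cats})
            )
            assert t.categories[0] == "Muscle or bone pain"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from("abcdefghijklmnopqrstuvwxyz"), min_size=1, max_size=4), min_size=1, max_size=60))
    def test_concentration_nondecreasing_in_k(self, cat_lists):
        t = ae.top_k_table(_cat_frame(cat_lists), k=20)
        assert t.concentration[20] >= t.concentration[10] - 1e-12
        for c in t.concentration.values():
            assert 0.0 <= c <= 1.0

    def test_overlap_uses_concept_map(self, sib_vocab):
        sm_t = ae.top_k_table(_cat_frame([["Dry mouth"], ["Headaches"], ["Sweating"]]))
        reg_t = ae.top_k_table(
            _cat_frame([["Oral dryness and saliva altered"], ["Headaches NEC"], ["Appetite disorders"]], "regulatory")
        )
        assert ae.category_overlap(sm_t, reg_t, sib_vocab.category_map) == 2
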