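"""Normalization and differential expression: exact invariants plus a quick
model-fit sanity check (full calibration lives in the acceptance tests)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomir import de
from cardiomir.datatypes import CountMatrix, SampleTable


def bh_reference(p):
    """Brute-force BH: p*m/rank, then running minimum from the largest p."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 5, 1], "b": [10, 5, 1], "c": [10, 5, 1]})
        sf = de.estimate_size_factors(CountMatrix(df))
        assert np.allclose(sf, 1.0)

    def test_scale_equivariance_is_exact(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(50, 4))
        df = pd.DataFrame(base, columns=list("abcd"))
        doubled = df.copy()
        doubled["d"] = df["d"] * 2
        sf1 = de.estimate_size_factors(CountMatrix(df))
        sf2 = de.estimate_size_factors(CountMatrix(doubled))
        # doubling one column multiplies its factor by 2 relative to the rest
        ratio = (sf2 / sf1).to_numpy()
        assert np.allclose(ratio[3] / ratio[0], 2.0, rtol=1e-12)

    def test_hand_computed_two_sample_example(self):
        df = pd.DataFrame([[10, 20], [100, 200], [1, 2]], columns=["a", "b"])
        sf = de.estimate_size_factors(CountMatrix(df))
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.integers(1, 1000, size=(80, 6)))
        sf = de.estimate_size_factors(CountMatrix(df))
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-12)

    def test_no_always_positive_feature_raises(self):
        df = pd.DataFrame([[0, 1], [1, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            de.estimate_size_factors(CountMatrix(df))


class TestNormalize:
    def test_unit_factors_identity(self, tiny_counts):
        sf = pd.Series(1.0, index=tiny_counts.sample_ids)
        out = de.normalize_counts(tiny_counts, sf)
        assert np.allclose(out, tiny_counts.counts)

    def test_log2_with_pseudocount(self):
        cm = CountMatrix(pd.DataFrame({"s": [3]}, index=["g"]))
        out = de.normalize_counts(cm, pd.Series({"s": 2.0}), log2=True)
        assert out.iat[0, 0] == pytest.approx(np.log2(2.5), abs=1e-12)

    def test_zero_count_maps_to_zero_under_log2(self):
        cm = CountMatrix(pd.DataFrame({"s": [0]}, index=["g"]))
        out = de.normalize_counts(cm, pd.Series({"s": 3.0}), log2=True)
        assert out.iat[0, 0] == 0.0

    def test_sample_mismatch_rejected(self, tiny_counts):
        with pytest.raises(ValueError, match="match"):
            de.normalize_counts(tiny_counts, pd.Series({"s1": 1.0, "zz": 1.0}))


class TestBH:
    def test_worked_example(self):
        out = de.adjust_bh([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert de.adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_nan_propagated_and_excluded_from_m(self):
        out = de.adjust_bh([0.04, np.nan])
        assert out[0] == pytest.approx(0.04)
        assert np.isnan(out[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_bh([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_reference(self, ps):
        assert np.allclose(de.adjust_bh(ps), bh_reference(ps), atol=1e-12)


class TestTwoGroup:
    groups = pd.Series({"a1": "g10", "a2": "g10", "a3": "g10",
                        "b1": "g18", "b2": "g18", "b3": "g18"})

    def test_identical_groups_null(self):
        ab = pd.DataFrame([[5.0] * 6], index=["p"], columns=self.groups.index)
        res = de.fit_two_group(ab, self.groups)
        assert res.at["p", "log2fc"] == 0.0
        assert res.at["p", "p"] == 1.0

    def test_unit_shift_recovered(self):
        rng = np.random.default_rng(0)
        vals = np.array([1, 1, 1, 2, 2, 2], float) + rng.normal(0, 1e-4, 6)
        ab = pd.DataFrame([vals], index=["p"], columns=self.groups.index)
        res = de.fit_two_group(ab, self.groups)
        assert res.at["p", "log2fc"] == pytest.approx(1.0, abs=1e-3)
        assert res.at["p", "p"] < 1e-4

    def test_small_group_marked_failed(self):
        ab = pd.DataFrame([[1.0, 2.0, np.nan, 3.0, 4.0, np.nan]],
                          index=["p"], columns=self.groups.index)
        ab.iloc[0, [1, 2]] = np.nan  # one usable value in the first group
        res = de.fit_two_group(ab, self.groups)
        assert res.at["p", "status"] == "failed"


class TestNbContinuous:
    def test_all_zero_feature_low_count_na(self, small_cohort):
        cm, st_ = small_cohort
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        res = de.fit_nb_continuous(CountMatrix(counts), st_)
        assert res.iloc[0]["status"] == "low_count"
        assert pd.isna(res.iloc[0]["padj"])
        # excluded from the BH denominator: every other padj is still defined
        assert res.iloc[1:]["padj"].notna().all()

    def test_constant_covariate_rejected(self, small_cohort):
        cm, st_ = small_cohort
        flat = SampleTable(pd.DataFrame(
            {"gestational_age": 12.0}, index=st_.sample_ids))
        with pytest.raises(ValueError, match="vary"):
            de.fit_nb_continuous(cm, flat)

    def test_strong_slope_detected(self, small_cohort):
        cm, st_ = small_cohort
        rng = np.random.default_rng(5)
        ages = st_.ages(cm.sample_ids)
        mu = np.exp2(np.log2(200) + 0.3 * (ages - 13.5))
        counts = cm.counts.copy()
        counts.iloc[0] = rng.negative_binomial(10, 10 / (10 + mu))
        res = de.fit_nb_continuous(CountMatrix(counts), st_)
        assert res.iloc[0]["padj"] < 0.01
        assert res.iloc[0]["log2fc"] == pytest.approx(0.3, abs=0.1)


class TestDiagnostics:
    def test_pca_variance_fractions_well_formed(self, small_cohort):
        cm, _ = small_cohort
        sf = de.estimate_size_factors(cm)
        norm = de.normalize_counts(cm, sf, log2=True)
        _, frac = de.pca_samples(norm)
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() <= 1.0 + 1e-9

    def test_pca_age_signal_lands_on_pc1(self, small_cohort):
        cm, st_ = small_cohort
        ages = st_.ages(cm.sample_ids)
        rng = np.random.default_rng(0)
        x = 0.5 * (ages - ages.mean())[None, :] + rng.normal(0, 0.05, (100, len(ages)))
        norm = pd.DataFrame(x, columns=cm.sample_ids)
        coords, _ = de.pca_samples(norm)
        r = np.corrcoef(coords["PC1"], ages)[0, 1]
        assert abs(r) > 0.9

    def test_pca_invariant_to_feature_order(self, small_cohort):
        cm, _ = small_cohort
        sf = de.estimate_size_factors(cm)
        norm = de.normalize_counts(cm, sf, log2=True)
        _, f1 = de.pca_samples(norm)
        _, f2 = de.pca_samples(norm.sample(frac=1.0, random_state=7))
        assert np.allclose(f1, f2, atol=1e-9)

    def test_subtype_composition_proportions(self):
        df = pd.DataFrame({"s1": [200, 50], "s2": [100, 50]},
                          index=["c1", "m1"])
        ann = pd.DataFrame({"subtype": ["circRNA", "miRNA"]}, index=df.index)
        comp = de.subtype_composition(CountMatrix(df, ann))
        assert comp.at["circRNA", "count_fraction"] == pytest.approx(0.75)
        assert comp.at["miRNA", "count_fraction"] == pytest.approx(0.25)
        assert comp["count_fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_split_by_direction_tie_rule(self):
        tab = pd.DataFrame({
            "log2fc": [1.0, -2.0, 0.0, 0.5],
            "padj": [0.01, 0.2, 0.001, 0.04],
        }, index=["up1", "ns", "zero", "up2"])
        up, down = de.split_by_direction(tab, alpha=0.05)
        assert up == ["up1", "up2"]
        assert down == []
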