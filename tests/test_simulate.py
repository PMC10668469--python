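"""Synthetic-study generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cardiomir import de, network
from cardiomir.datatypes import SampleTable
from cardiomir.simulate import (SimulationConfig, simulate_ages,
                                simulate_cohort, simulate_gene_sets,
                                simulate_proteins, simulate_small_rna,
                                simulate_study, simulate_target_map,
                                template_profiles)


def small_cfg(**kw) -> SimulationConfig:
    """A scaled-down study for fast structural tests."""
    defaults = dict(n_mirna=60, n_mrna=300, n_protein=60, n_true_edges=20,
                    n_decoy_edges=40, members_per_template=5,
                    n_gene_sets=12, set_size_range=(5, 30),
                    n_protein_from_targets=15, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAges:
    def test_seed_determinism(self):
        assert np.array_equal(simulate_ages(5, seed=1), simulate_ages(5, seed=1))

    def test_bounds_and_sorted(self):
        ages = simulate_ages(100, (8, 19), seed=2)
        assert ages.min() >= 8 and ages.max() <= 19
        assert np.array_equal(ages, np.sort(ages))

    def test_uniform_mean(self):
        ages = simulate_ages(10_000, (8, 19), seed=3)
        assert 12.5 < ages.mean() < 14.5

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_ages(0)


class TestSmallRna:
    def test_same_seed_identical_matrices(self):
        cfg = small_cfg()
        samples, small_ids, _, _ = simulate_cohort(cfg, seed=1)
        cm1, _, _ = simulate_small_rna(cfg, samples, small_ids, seed=5)
        cm2, _, _ = simulate_small_rna(cfg, samples, small_ids, seed=5)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    def test_subtype_labels_follow_configured_classes(self):
        cfg = small_cfg()
        samples, small_ids, _, _ = simulate_cohort(cfg, seed=1)
        cm, truth, _ = simulate_small_rna(cfg, samples, small_ids, seed=5)
        assert set(cm.annotations["subtype"]) <= set(cfg.subtype_proportions)
        assert (cm.annotations["subtype"] == "miRNA").sum() == cfg.n_mirna

    def test_near_poisson_limit_variance_tracks_mean(self):
        cfg = small_cfg(nb_dispersion=1e-12, libsize_range=(1.0, 1.0 + 1e-9),
                        fraction_de=0.0, members_per_template=0,
                        n_samples_smallrna=200, n_samples_mrna=200,
                        n_shared_samples=200)
        samples, small_ids, _, _ = simulate_cohort(cfg, seed=2)
        cm, _, _ = simulate_small_rna(cfg, samples, small_ids, seed=3)
        x = cm.counts.to_numpy(float)
        ratio = x.var(axis=1, ddof=1) / x.mean(axis=1)
        # Poisson: var/mean = 1; MC error with n=200 samples per feature
        assert 0.8 < np.median(ratio) < 1.2

    def test_null_config_drives_nominal_de_rate(self):
        cfg = small_cfg(fraction_de=0.0, members_per_template=0, n_mirna=400,
                        n_true_edges=0, n_decoy_edges=0)
        samples, small_ids, _, _ = simulate_cohort(cfg, seed=4)
        cm, truth, _ = simulate_small_rna(cfg, samples, small_ids, seed=4)
        res = de.fit_nb_continuous(cm, samples)
        ok = res["status"] == "ok"
        frac = (res.loc[ok, "p"].astype(float) < 0.05).mean()
        assert 0.02 < frac < 0.08
        assert not truth["is_de"].any()


class TestTargetMap:
    def test_counts_and_disjointness(self):
        cfg = small_cfg()
        regs = [f"m{i}" for i in range(10)]
        pool = [f"g{i}" for i in range(200)]
        tm, edges = simulate_target_map(cfg, regs, pool, seed=0)
        assert len(tm) == 60
        planted = set(map(tuple, edges.query("kind=='planted'")[
            ["mirna_id", "mrna_id"]].to_numpy()))
        decoy = set(map(tuple, edges.query("kind=='decoy'")[
            ["mirna_id", "mrna_id"]].to_numpy()))
        assert len(planted) == 20 and len(decoy) == 40
        assert not planted & decoy

    def test_zero_decoys_map_equals_planted(self):
        cfg = small_cfg(n_decoy_edges=0)
        tm, edges = simulate_target_map(cfg, ["m1", "m2"],
                                        [f"g{i}" for i in range(50)], seed=1)
        assert len(tm) == cfg.n_true_edges
        assert (edges["kind"] == "planted").all()

    def test_infeasible_counts_rejected(self):
        cfg = small_cfg(n_true_edges=50, n_decoy_edges=50)
        with pytest.raises(ValueError):
            simulate_target_map(cfg, ["m1"], [f"g{i}" for i in range(60)],
                                seed=0)


class TestRepression:
    def _study(self, **kw):
        return simulate_study(SimulationConfig(**{"seed": 11, **kw}))

    def test_planted_pairs_anticorrelated(self):
        study = self._study()
        sf_s = de.estimate_size_factors(study.smallrna)
        sf_m = de.estimate_size_factors(study.mrna)
        norm_s = de.normalize_counts(study.smallrna, sf_s, log2=True)
        norm_m = de.normalize_counts(study.mrna, sf_m, log2=True)
        planted = study.truth.edges.query("kind=='planted'")
        rs = [network.pearson_edge(
            norm_s.loc[m, study.shared_samples],
            norm_m.loc[g, study.shared_samples])[0]
            for m, g in zip(planted["mirna_id"], planted["mrna_id"])]
        assert np.mean(np.array(rs) < 0) >= 0.95
        assert np.median(rs) < -0.3

    def test_zero_strength_makes_planted_indistinguishable_from_decoys(self):
        study = self._study(repression_strength=0.0)
        sf_s = de.estimate_size_factors(study.smallrna)
        sf_m = de.estimate_size_factors(study.mrna)
        norm_s = de.normalize_counts(study.smallrna, sf_s, log2=True)
        norm_m = de.normalize_counts(study.mrna, sf_m, log2=True)

        def corr_set(kind):
            sub = study.truth.edges.query(f"kind=='{kind}'")
            return [network.pearson_edge(
                norm_s.loc[m, study.shared_samples],
                norm_m.loc[g, study.shared_samples])[0]
                for m, g in zip(sub["mirna_id"], sub["mrna_id"])]

        ks = scipy.stats.ks_2samp(corr_set("planted"), corr_set("decoy"))
        assert ks.pvalue > 0.01

    def test_planted_edges_subset_of_emitted_map(self):
        study = self._study()
        planted = set(map(tuple, study.truth.edges.query("kind=='planted'")[
            ["mirna_id", "mrna_id"]].to_numpy()))
        assert planted <= study.target_map.edges


class TestProteins:
    def test_null_effect_calibrates_to_alpha(self):
        cfg = small_cfg(protein_effect=0.0, n_protein=400, n_mrna=800,
                        protein_missing_rate=0.0, n_protein_from_targets=0)
        truth = pd.DataFrame({
            "layer": "mRNA", "is_de": False, "true_slope": 0.0,
            "template_id": pd.array([pd.NA] * 800, dtype="Int64"),
            "true_direction": np.resize([1, -1], 800),
        }, index=[f"GENE{i + 1:05d}" for i in range(800)])
        tables, labels, _ = simulate_proteins(cfg, truth, seed=0)
        common = network.common_protein_filter(*tables.values())
        res = de.fit_two_group(common, labels)
        frac = (res["p"].astype(float) < 0.05).mean()
        assert 0.02 < frac < 0.08

    def test_full_concordance_large_effect(self):
        cfg = small_cfg(concordance_fraction=1.0, protein_effect=3.0,
                        protein_missing_rate=0.0)
        study = simulate_study(SimulationConfig(seed=3,
                                                concordance_fraction=1.0,
                                                protein_effect=3.0,
                                                protein_missing_rate=0.0))
        truth = study.truth.proteins
        directional = truth[truth["direction"] != 0]
        assert (directional["concordant"]).all()

    def test_same_seed_identical_tables(self):
        cfg = small_cfg()
        truth = simulate_study(SimulationConfig(seed=1, n_mirna=60, n_mrna=300,
                                                n_true_edges=20,
                                                n_decoy_edges=40,
                                                members_per_template=5)
                               ).truth.features
        mrna_truth = truth[truth["layer"] == "mRNA"]
        t1, _, _ = simulate_proteins(cfg, mrna_truth, seed=7)
        t2, _, _ = simulate_proteins(cfg, mrna_truth, seed=7)
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])


class TestGeneSets:
    def test_sizes_within_bounds(self):
        cfg = small_cfg()
        truth = pd.DataFrame({
            "true_direction": np.resize([1, -1, 0], 300),
        }, index=[f"G{i}" for i in range(300)])
        gsc, set_truth = simulate_gene_sets(cfg, truth, seed=0)
        lo, hi = cfg.set_size_range
        for _, members in gsc:
            assert lo <= len(members) <= hi
        assert len(gsc) == cfg.n_gene_sets

    def test_directional_sets_enriched_for_matching_genes(self):
        cfg = small_cfg(gene_set_bias=1.0)
        truth = pd.DataFrame({
            "true_direction": np.resize([1, -1, 0], 300),
        }, index=[f"G{i}" for i in range(300)])
        gsc, set_truth = simulate_gene_sets(cfg, truth, seed=1)
        up_sets = set_truth.query("direction=='up'")["set_id"]
        for sid in up_sets:
            members = gsc.sets[sid]
            frac_up = np.mean([truth.at[g, "true_direction"] > 0
                               for g in members])
            assert frac_up > 0.5


class TestTemplates:
    def test_templates_standardized(self):
        t = template_profiles()
        assert np.allclose(t.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(t.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_full_study_deterministic_under_seed(self):
        kw = dict(seed=9, n_mirna=60, n_mrna=200, n_protein=50,
                  n_true_edges=10, n_decoy_edges=20, members_per_template=5,
                  n_gene_sets=10, set_size_range=(5, 30),
                  n_protein_from_targets=10)
        s1 = simulate_study(SimulationConfig(**kw))
        s2 = simulate_study(SimulationConfig(**kw))
        pd.testing.assert_frame_equal(s1.smallrna.counts, s2.smallrna.counts)
        pd.testing.assert_frame_equal(s1.mrna.counts, s2.mrna.counts)
        assert s1.target_map.edges == s2.target_map.edges


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(subtype_proportions={"miRNA": 0.5, "piRNA": 0.2,
                                                  "circRNA": 0.1, "snoRNA": 0.1,
                                                  "snRNA": 0.05, "tRNA": 0.04})

    def test_shared_cannot_exceed_cohorts(self):
        with pytest.raises(ValueError, match="shared"):
            SimulationConfig(n_shared_samples=50, n_samples_smallrna=37,
                             n_samples_mrna=53)
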