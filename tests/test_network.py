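"""Anti-correlation network construction, filters and tripartite assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomir import network
from cardiomir.datatypes import TargetMap


def pearson_brute_force(x, y):
    """Definition-based Pearson r computed with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) \
        * math.sqrt(sum((b - my) ** 2 for b in y))
    return num / den


def _edges(rows):
    return pd.DataFrame(rows, columns=network.EDGE_COLUMNS)


class TestCandidatePairs:
    tm = TargetMap({("a", "X"), ("a", "Y"), ("b", "Z")})

    def test_hand_intersection(self):
        assert network.candidate_pairs(["a"], ["X", "Z"], self.tm) == [("a", "X")]

    def test_empty_map(self):
        assert network.candidate_pairs(["a"], ["X"], TargetMap(set())) == []

    def test_full_overlap_returns_whole_map(self):
        pairs = network.candidate_pairs(["a", "b"], ["X", "Y", "Z"], self.tm)
        assert set(pairs) == self.tm.edges


class TestPearsonEdge:
    def test_anti_identity(self):
        x = [1.0, 2.0, 5.0, 3.0]
        r, p = network.pearson_edge(x, [-v for v in x])
        assert r == -1.0 and p == 0.0

    def test_worked_example(self):
        r, p = network.pearson_edge([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(0.4, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            network.pearson_edge([1, 1, 1], [1, 2, 3])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, _ = network.pearson_edge(x, y)
        assert r == pytest.approx(pearson_brute_force(list(x), list(y)),
                                  abs=1e-12)


class TestCorrelatePairs:
    def test_too_few_shared_samples_rejected(self):
        m = pd.DataFrame([[1, 2]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 shared"):
            network.correlate_pairs([("a", "g")], m, m, ["s1", "s2"])

    def test_empty_pair_list_gives_empty_table(self):
        m = pd.DataFrame([[1, 2, 3]], index=["a"], columns=list("xyz"))
        out = network.correlate_pairs([], m, m, list("xyz"))
        assert out.empty

    def test_zero_variance_pair_dropped_not_fatal(self):
        mi = pd.DataFrame([[1, 2, 3]], index=["a"], columns=list("xyz"))
        mr = pd.DataFrame([[5, 5, 5], [3, 2, 1]], index=["g0", "g1"],
                          columns=list("xyz"))
        out = network.correlate_pairs([("a", "g0"), ("a", "g1")], mi, mr,
                                      list("xyz"))
        assert list(out["mrna_id"]) == ["g1"]


class TestFilters:
    def test_anticorrelation_filter_is_strict(self):
        edges = _edges([
            ("a", "g1", -0.5, 0.01, 10, ""),   # kept
            ("a", "g2", -0.5, 0.06, 10, ""),   # p too large
            ("a", "g3", 0.9, 1e-9, 10, ""),    # wrong sign
            ("a", "g4", 0.0, 0.01, 10, ""),    # r not < 0
        ])
        kept = network.filter_anticorrelated(edges)
        assert list(kept["mrna_id"]) == ["g1"]

    def test_filter_is_idempotent(self):
        edges = _edges([("a", "g1", -0.5, 0.01, 10, ""),
                        ("a", "g2", -0.2, 0.06, 10, "")])
        once = network.filter_anticorrelated(edges)
        twice = network.filter_anticorrelated(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_partition_by_direction_and_tie(self):
        edges = _edges([("a", "up_g", -0.5, 0.01, 10, ""),
                        ("a", "down_g", -0.6, 0.01, 10, ""),
                        ("a", "zero_g", -0.7, 0.01, 10, "")])
        de = pd.DataFrame({"log2fc": [1.2, -0.3, 0.0]},
                          index=["up_g", "down_g", "zero_g"])
        up, down = network.partition_by_mrna_direction(edges, de)
        assert list(up["mrna_id"]) == ["up_g"]
        assert list(down["mrna_id"]) == ["down_g"]

    def test_partition_missing_mrna_rejected(self):
        edges = _edges([("a", "gX", -0.5, 0.01, 10, "")])
        with pytest.raises(ValueError, match="gX"):
            network.partition_by_mrna_direction(edges,
                                                pd.DataFrame({"log2fc": []}))

    def test_top_fraction_counts_and_ceil(self):
        rows = [("a", f"g{i}", -i / 100, 0.01, 10, "") for i in range(100)]
        out = network.select_top_fraction(_edges(rows), 0.05)
        assert len(out) == 5
        out10 = network.select_top_fraction(_edges(rows[:10]), 0.05)
        assert len(out10) == 1  # ceil(0.5)

    def test_top_fraction_tie_broken_by_p(self):
        edges = _edges([("a", "g1", -0.9, 0.01, 10, ""),
                        ("b", "g2", -0.9, 0.001, 10, "")])
        out = network.select_top_fraction(edges, 0.5)  # one slot
        assert list(out["mrna_id"]) == ["g2"]

    def test_top_fraction_one_is_identity_up_to_order(self):
        edges = _edges([("a", "g1", -0.9, 0.01, 10, ""),
                        ("b", "g2", -0.1, 0.5, 10, "")])
        out = network.select_top_fraction(edges, 1.0)
        assert set(out["mrna_id"]) == {"g1", "g2"}

    def test_threshold_edges_strict_boundary(self):
        edges = _edges([("a", "g1", -0.71, 0.01, 10, ""),
                        ("b", "g2", -0.70, 0.01, 10, "")])
        out = network.threshold_edges(edges, -0.7)
        assert list(out["mrna_id"]) == ["g1"]

    def test_threshold_all_above_cut_empty(self):
        edges = _edges([("a", "g1", -0.5, 0.01, 10, "")])
        assert network.threshold_edges(edges, -0.85).empty


class TestProteinIntegration:
    def test_common_protein_filter_drops_any_missing(self):
        a = pd.DataFrame({"a1": [1.0, 2.0], "a2": [1.0, np.nan]},
                         index=["p1", "p2"])
        b = pd.DataFrame({"b1": [1.0, 2.0]}, index=["p1", "p2"])
        out = network.common_protein_filter(a, b)
        assert list(out.index) == ["p1"]

    def test_common_protein_filter_matches_brute_force_recount(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(25, 1, size=(100, 6))
        mask = rng.random((100, 6)) < 0.1
        vals[mask] = np.nan
        a = pd.DataFrame(vals[:, :3], columns=["a1", "a2", "a3"])
        b = pd.DataFrame(vals[:, 3:], columns=["b1", "b2", "b3"])
        out = network.common_protein_filter(a, b)
        expected = sum(1 for i in range(100) if not np.isnan(vals[i]).any())
        assert len(out) == expected

    def test_concordant_pairs_rules(self):
        prot = pd.DataFrame({"log2fc": [1.0, 1.0, 1.0],
                             "p": [0.01, 0.01, 0.2]},
                            index=["pA", "pB", "pC"])
        mrna = pd.DataFrame({"log2fc": [2.0, -2.0, 2.0],
                             "padj": [0.001, 0.001, 0.001]},
                            index=["pA", "pB", "pC"])
        out = network.concordant_pairs(prot, mrna)
        assert list(out["protein_id"]) == ["pA"]  # pB discordant, pC p>=alpha


class TestTripartite:
    mirna_de = pd.DataFrame({"log2fc": [-1.0, 2.0]}, index=["miR-d", "miR-u"])
    conc = pd.DataFrame({
        "protein_id": ["P1"], "mrna_id": ["G1"], "protein_log2fc": [1.5],
        "protein_p": [0.01], "mrna_log2fc": [1.0], "mrna_padj": [0.001],
        "direction": ["up"]})

    def test_minimal_network_three_nodes_two_edges(self):
        edges = _edges([("miR-d", "G1", -0.8, 0.001, 10, "up")])
        nodes, out_edges = network.build_tripartite(
            edges, self.conc, self.mirna_de, "down-miR:up-mRNA:enriched")
        assert len(nodes) == 3 and len(out_edges) == 2
        assert set(nodes["layer"]) == {"miRNA", "mRNA", "protein"}

    def test_protein_without_surviving_edge_excluded(self):
        edges = _edges([("miR-d", "G_other", -0.8, 0.001, 10, "up")])
        nodes, out_edges = network.build_tripartite(
            edges, self.conc, self.mirna_de, "down-miR:up-mRNA:enriched")
        assert nodes.empty and out_edges.empty

    def test_wrong_mirna_direction_excluded(self):
        edges = _edges([("miR-u", "G1", -0.8, 0.001, 10, "up")])
        nodes, _ = network.build_tripartite(
            edges, self.conc, self.mirna_de, "down-miR:up-mRNA:enriched")
        assert nodes.empty

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValueError, match="polarity"):
            network.build_tripartite(_edges([]), self.conc, self.mirna_de,
                                     "sideways")
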