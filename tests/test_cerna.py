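"""Seed-site scanning, trend filters and ceRNA triad assembly."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernapipe import cerna, synthetic


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _brute_force_sites(mirna, target):
    """Independent sliding-window oracle using per-base complement checks."""
    mir = mirna.upper().replace("U", "T")
    tgt = target.upper().replace("U", "T")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def pairs(window, seed):  # window 5'->3' pairs seed 3'->5'
        return all(comp[w] == s for w, s in zip(window, reversed(seed)))

    found = []
    for pos in range(len(tgt)):
        m8 = pos + 7 <= len(tgt) and pairs(tgt[pos:pos + 7], mir[1:8])
        a_after_8 = pos + 8 <= len(tgt) and tgt[pos + 7] == "A"
        m7 = pos + 6 <= len(tgt) and pairs(tgt[pos:pos + 6], mir[1:7])
        a_after_7 = pos + 7 <= len(tgt) and tgt[pos + 6] == "A"
        if m8 and a_after_8:
            found.append((pos + 1, "8mer"))
        elif m8:
            found.append((pos + 1, "7mer-m8"))
        elif m7 and a_after_7:
            found.append((pos + 1, "7mer-A1"))
    # suppress the 7mer-A1 nested inside every 8mer
    eight = {p for p, c in found if c == "8mer"}
    return [(p, c) for p, c in found if not (c == "7mer-A1" and p - 1 in eight)]


class TestScanSites:
    MIR = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt

    def test_constructed_8mer_found(self):
        site = _revcomp(self.MIR.replace("U", "T")[1:8]) + "A"
        target = "C" * 20 + site + "C" * 20
        sites = cerna.scan_sites(self.MIR, target, "m", "t")
        assert [(s["position"], s["site_class"]) for s in sites] == [(21, "8mer")]
        assert sites[0]["score"] == 3

    def test_site_classes_scored_by_strength(self):
        seed7 = _revcomp(self.MIR.replace("U", "T")[1:8])
        cases = {"8mer": seed7 + "A", "7mer-m8": seed7 + "C",
                 "7mer-A1": _revcomp(self.MIR.replace("U", "T")[1:7]) + "A"}
        for cls, site in cases.items():
            # G context: cannot extend a planted site into a longer match
            target = "G" * 10 + site + "G" * 10
            found = cerna.scan_sites(self.MIR, target, "m", "t")
            assert [s["site_class"] for s in found] == [cls]

    def test_no_complementarity_means_no_sites(self):
        # homopolymer target cannot complement the mixed seed
        assert cerna.scan_sites(self.MIR, "A" * 60, "m", "t") == []

    def test_agrees_with_brute_force_oracle_on_random_sequences(self, rng):
        bases = "ACGT"
        for _ in range(300):
            mir = "".join(bases[i] for i in rng.integers(0, 4, 22))
            tgt = "".join(bases[i] for i in rng.integers(0, 4, 80))
            got = [(s["position"], s["site_class"])
                   for s in cerna.scan_sites(mir, tgt, "m", "t")]
            assert got == _brute_force_sites(mir, tgt)

    def test_invalid_characters_name_the_record(self):
        with pytest.raises(cerna.SequenceError, match="weird"):
            cerna.scan_sites("ACGUACGUACGU", "ACGTNACGT", "m", "weird")

    def test_short_mirna_rejected(self):
        with pytest.raises(cerna.SequenceError):
            cerna.scan_sites("ACGU", "ACGTACGTACGT", "m", "t")


class TestAnticorrelationFilter:
    SITES = pd.DataFrame({"mirna": ["m1", "m1", "m2"],
                          "target": ["t1", "t2", "t3"],
                          "site_class": ["8mer"] * 3,
                          "position": [1, 1, 1], "score": [3, 3, 3]})

    def test_opposed_signs_retained(self):
        out = cerna.anticorrelation_filter(self.SITES, {"m1": 1, "t1": -1})
        assert list(out.itertuples(index=False))[0][:2] == ("m1", "t1")

    def test_same_sign_dropped(self):
        out = cerna.anticorrelation_filter(self.SITES, {"m1": 1, "t1": 1, "t2": 1})
        assert len(out) == 0

    def test_missing_or_flat_trend_skipped_with_log(self):
        out = cerna.anticorrelation_filter(self.SITES, {"m1": 1, "t1": -1, "m2": 0, "t3": -1})
        skipped = out.attrs["skipped"]
        assert ("m2", "t3", "missing or flat trend") in skipped
        assert ("m1", "t2", "missing or flat trend") in skipped


class TestAssembleCerna:
    def test_empty_pairs_give_empty_network(self):
        pairs = pd.DataFrame(columns=["mirna", "target", "mirna_trend", "target_trend"])
        triads, graph = cerna.assemble_cerna(pairs, {}, set())
        assert len(triads) == 0 and graph.number_of_nodes() == 0

    def _pairs(self):
        return pd.DataFrame({
            "mirna": ["miR:1", "miR:1"],
            "target": ["mRNA:1", "circ:1"],
            "mirna_trend": [1, 1], "target_trend": [-1, -1]})

    def test_triad_requires_enriched_mrna(self):
        trends = {"miR:1": 1, "mRNA:1": -1, "circ:1": -1}
        triads, _ = cerna.assemble_cerna(self._pairs(), trends, {"mRNA:1"})
        assert len(triads) == 1
        none, _ = cerna.assemble_cerna(self._pairs(), trends, set())
        assert len(none) == 0

    def test_network_closure_with_triads(self):
        trends = {"miR:1": 1, "mRNA:1": -1, "circ:1": -1}
        triads, graph = cerna.assemble_cerna(self._pairs(), trends, {"mRNA:1"})
        for row in triads.itertuples(index=False):
            assert graph.has_edge(row.mirna, row.mrna)
            assert graph.has_edge(row.mirna, row.sponge)
        assert graph.number_of_edges() == 2 * len(triads)

    def test_order_independence(self, rng):
        trends = {"miR:1": 1, "mRNA:1": -1, "circ:1": -1}
        pairs = self._pairs()
        shuffled = pairs.sample(frac=1, random_state=3).reset_index(drop=True)
        t1, _ = cerna.assemble_cerna(pairs, trends, {"mRNA:1"})
        t2, _ = cerna.assemble_cerna(shuffled, trends, {"mRNA:1"})
        pd.testing.assert_frame_equal(t1, t2)


class TestRankCernaNodes:
    def test_star_center_ranked_first(self):
        g = nx.star_graph(6)
        g = nx.relabel_nodes(g, {0: "miR:hub", **{i: f"mRNA:{i}" for i in range(1, 7)}})
        nx.set_node_attributes(
            g, {n: ("miRNA" if n.startswith("miR") else "mRNA") for n in g}, "node_type")
        out = cerna.rank_cerna_nodes(g, k=1)
        assert out.loc[0, "node"] == "miR:hub" and out.loc[0, "degree"] == 6

    def test_schema_matches_published_metric_columns(self):
        g = nx.path_graph(3)
        nx.set_node_attributes(g, "miRNA", "node_type")
        out = cerna.rank_cerna_nodes(g, k=5)
        assert list(out.columns) == [
            "node", "degree", "avg_shortest_path", "betweenness", "closeness",
            "neighborhood_connectivity", "radiality", "topological_coef"]

    def test_empty_network_gives_empty_table(self):
        assert len(cerna.rank_cerna_nodes(nx.Graph(), k=5)) == 0


def test_planted_sequences_round_trip(small_study):
    """Every planted pair is rediscovered at its class; decoys stay clean."""
    _, _, _, truth = small_study
    mirnas, utrs = synthetic.generate_sequences(truth.target_pairs, seed=11, n_decoys=50)
    sites = cerna.predict_targets(mirnas, utrs)
    found = {(r.mirna, r.target, r.site_class) for r in sites.itertuples(index=False)}
    assert found == set(map(tuple, truth.target_pairs))
    assert not any(t.startswith("decoy:") for t in sites["target"])


def test_sequence_generation_deterministic(small_study):
    _, _, _, truth = small_study
    a = synthetic.generate_sequences(truth.target_pairs, seed=5)
    b = synthetic.generate_sequences(truth.target_pairs, seed=5)
    assert a == b
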