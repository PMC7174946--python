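"""Synthetic study generator: design, counts, truth closure, determinism."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernapipe import reference, synthetic


class TestDesign:
    def test_study_scale_matches_cohort(self):
        design = synthetic.generate_design(10, seed=0)
        assert len(design) == 50
        assert design["group"].value_counts().eq(10).all()

    def test_deterministic_for_fixed_seed(self):
        a = synthetic.generate_design(2, seed=1).to_csv()
        b = synthetic.generate_design(2, seed=1).to_csv()
        assert a == b

    def test_replicates_contiguous_within_group(self):
        design = synthetic.generate_design(3, seed=0)
        for g, sub in design.groupby("group"):
            assert sorted(sub["replicate"]) == [1, 2, 3]
        assert design["sample_id"].is_unique

    def test_too_few_replicates_rejected(self):
        with pytest.raises(synthetic.ConfigError):
            synthetic.generate_design(1)


class TestMultiomics:
    def test_zero_de_fraction_empties_truth(self, design):
        config = synthetic.SimulationConfig(
            n_features={"mRNA": 100, "ncRNA": 20, "circRNA": 20, "miRNA": 20},
            de_fraction=0.0)
        _, truth = synthetic.generate_multiomics(design, config, seed=3)
        assert all(len(v) == 0 for v in truth.de_features.values())
        assert all(len(v) == 0 for v in truth.efficacy_features.values())

    def test_counts_are_nonnegative_integers_without_gaps(self, small_study):
        _, _, matrices, _ = small_study
        for counts in matrices.values():
            arr = counts.to_numpy()
            assert np.issubdtype(arr.dtype, np.integer)
            assert (arr >= 0).all()
            assert not counts.isna().any().any()

    def test_truth_closed_over_emitted_features(self, small_study):
        _, _, matrices, truth = small_study
        emitted = set()
        for counts in matrices.values():
            emitted |= set(counts.index)
        referenced = {f for pairs in truth.de_features.values() for f, _ in pairs}
        referenced |= {f for s in truth.efficacy_features.values() for f in s}
        referenced |= {f for pair in truth.target_pairs for f in pair[:2]}
        assert referenced <= emitted

    def test_byte_identical_for_fixed_seed(self, design):
        config = synthetic.SimulationConfig(
            n_features={"mRNA": 60, "ncRNA": 15, "circRNA": 15, "miRNA": 15})
        m1, _ = synthetic.generate_multiomics(design, config, seed=9)
        m2, _ = synthetic.generate_multiomics(design, config, seed=9)
        for cat in m1:
            assert m1[cat].to_csv() == m2[cat].to_csv()

    def test_planted_fold_change_realized_in_group_means(self, design):
        """At near-zero dispersion the DM/NC mean ratio approaches 2^log2fc."""
        config = synthetic.SimulationConfig(
            n_features={"mRNA": 150, "ncRNA": 10, "circRNA": 10, "miRNA": 10},
            de_fraction=0.2, log2fc=2.0, dispersion=1e-4, libsize_sigma=0.0,
            baseline_log_mean=7.0, baseline_log_sigma=0.5, efficacy_fraction=0.0)
        ratios = []
        for seed in range(20):
            matrices, truth = synthetic.generate_multiomics(design, config, seed=seed)
            counts = matrices["mRNA"]
            dm = counts[[s for s in counts if s.startswith("DM")]].mean(axis=1)
            nc = counts[[s for s in counts if s.startswith("NC")]].mean(axis=1)
            for f, direction in truth.de_features["DM vs NC"]:
                if not f.startswith("mRNA:"):
                    continue
                ratio = dm[f] / nc[f]
                ratios.append(ratio if direction == "up" else 1.0 / ratio)
        assert np.mean(np.abs(np.array(ratios) / 4.0 - 1.0) < 0.10) > 0.95

    def test_configured_de_counts_are_emitted_exactly(self, design):
        de_targets = reference.DEG_CATEGORY_TOTALS
        config = synthetic.SimulationConfig(
            n_features={cat: 2 * n for cat, n in de_targets.items()},
            de_fraction=0.5)
        _, truth = synthetic.generate_multiomics(design, config, seed=0)
        dm = truth.de_features["DM vs NC"]
        prefix = {"mRNA": "mRNA:", "ncRNA": "nc:", "circRNA": "circ:", "miRNA": "miR:"}
        for cat, expected in de_targets.items():
            got = sum(1 for f, _ in dm if f.startswith(prefix[cat]))
            assert got == expected

    def test_bad_fraction_rejected(self):
        with pytest.raises(synthetic.ConfigError):
            synthetic.SimulationConfig(de_fraction=1.5)

    def test_truth_json_round_trip(self, small_study, tmp_path):
        _, _, _, truth = small_study
        path = tmp_path / "truth.json"
        truth.to_json(path)
        payload = json.loads(path.read_text())
        assert set(payload["efficacy_features"]) == set(synthetic.TREATMENTS)
        assert len(payload["target_pairs"]) == len(truth.target_pairs)


class TestAnnotations:
    def test_universe_set_boundary(self):
        feats = [f"g{i}" for i in range(30)]
        sets, dag, _ = synthetic.generate_annotations(feats, n_sets=1, seed=0, set_size=30)
        from cernapipe import enrich
        out = enrich.hypergeom_enrich(feats[:8], sets, feats)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_dag_is_acyclic(self):
        feats = [f"g{i}" for i in range(50)]
        _, dag, _ = synthetic.generate_annotations(feats, n_sets=8, seed=2)
        g = nx.DiGraph(dag)
        assert nx.is_directed_acyclic_graph(g)
        assert list(nx.topological_sort(g))

    def test_planted_set_overrepresents_de_list(self):
        feats = [f"g{i}" for i in range(200)]
        de = feats[:40]
        sets, _, truth = synthetic.generate_annotations(
            feats, n_sets=5, seed=4, de_features=de)
        planted = truth["enriched"][0]
        members = sets[planted]
        assert len(members & set(de)) / len(members) >= 0.5

    def test_empty_features_rejected(self):
        with pytest.raises(synthetic.ConfigError):
            synthetic.generate_annotations([], n_sets=1)


class TestPpi:
    def test_preferential_attachment_is_heavy_tailed(self):
        feats = [f"g{i}" for i in range(1000)]
        ok = 0
        for seed in range(20):
            edges, _ = synthetic.generate_ppi(feats, seed=seed)
            from cernapipe import topology
            g = topology.build_graph(edges)
            degrees = np.array([d for _, d in g.degree()])
            ok += degrees.max() >= 5 * np.median(degrees)
        assert ok == 20

    def test_hub_truth_equals_degree_sort(self):
        feats = [f"g{i}" for i in range(10)]
        edges, hubs = synthetic.generate_ppi(feats, model="erdos_renyi",
                                             seed=1, edge_prob=0.4, n_hubs=10)
        g = nx.Graph(list(edges[["node1", "node2"]].itertuples(index=False)))
        expect = [n for n, _ in sorted(g.degree(), key=lambda nd: (-nd[1], nd[0]))]
        assert hubs == expect[: len(hubs)]

    def test_simple_graph_invariants(self):
        feats = [f"g{i}" for i in range(100)]
        edges, _ = synthetic.generate_ppi(feats, seed=5)
        assert not (edges["node1"] == edges["node2"]).any()
        keys = {frozenset(t) for t in edges[["node1", "node2"]].itertuples(index=False)}
        assert len(keys) == len(edges)

    def test_unknown_model_rejected(self):
        with pytest.raises(synthetic.ConfigError):
            synthetic.generate_ppi([f"g{i}" for i in range(20)], model="smallworld")


class TestPhenotypes:
    def test_zero_noise_reproduces_group_means(self, design):
        tidy = synthetic.generate_phenotypes(design, seed=0, noise_scale=0.0)
        nc_ogtt = tidy[(tidy["group"] == "NC") & (tidy["variable"] == "OGTT")]
        by_time = nc_ogtt.groupby("time_min")["value"].unique()
        for t, (mean, _) in zip((0, 30, 60, 120), reference.GLUCOSE_CURVES["OGTT"]["NC"]):
            assert list(by_time[t]) == [mean]

    def test_identical_csv_for_fixed_seed(self, design):
        a = synthetic.generate_phenotypes(design, seed=3).to_csv()
        b = synthetic.generate_phenotypes(design, seed=3).to_csv()
        assert a == b

    def test_control_curve_recovered_within_two_se(self):
        """Sample means over 100 seeds sit within 2 SE of the published means."""
        design = synthetic.generate_design(5, seed=0)
        sums = np.zeros(4)
        n_seeds = 100
        for seed in range(n_seeds):
            tidy = synthetic.generate_phenotypes(design, seed=seed)
            nc = tidy[(tidy["group"] == "NC") & (tidy["variable"] == "OGTT")]
            sums += nc.groupby("time_min")["value"].mean().reindex([0, 30, 60, 120]).to_numpy()
        means = sums / n_seeds
        for got, (mean, sd) in zip(means, reference.GLUCOSE_CURVES["OGTT"]["NC"]):
            se = sd / np.sqrt(5 * n_seeds)
            assert abs(got - mean) <= 2 * se + 0.02


class TestBlockExpression:
    def test_within_block_correlation_near_target(self):
        expr, truth = synthetic.generate_block_expression(
            {"b1": 30}, n_noise=0, n_samples=2000, within_cor=0.7, seed=0)
        cors = np.corrcoef(expr.to_numpy())
        off = cors[~np.eye(30, dtype=bool)]
        assert off.mean() == pytest.approx(0.7, abs=0.03)

    def test_labels_cover_blocks_and_noise(self):
        expr, truth = synthetic.generate_block_expression(
            {"b1": 5, "b2": 4}, n_noise=3, n_samples=10, seed=1)
        counts = truth.value_counts()
        assert counts["b1"] == 5 and counts["b2"] == 4 and counts["grey"] == 3
        assert len(expr) == 12
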