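"""End-to-end orchestration of the multi-omic pharmacodynamics pipeline.

Runs differential screening → trend profiling → enrichment → target
prediction → ceRNA assembly → coexpression → topology on either
user-supplied files or the bundled synthetic study, writing one table
per stage plus a reproducibility manifest (config hash, seed,
versions) into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cerna, diffexpr, enrich, io, phenotypes, synthetic, topology, trends, wgcna

log = logging.getLogger("cernapipe")


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run; unknown keys rejected."""

    outdir: str = "results/pipeline"
    seed: int = 0
    n_per_group: int = 5
    fc_hi: float = 1.5
    fc_lo: float = 0.667
    fdr_max: float = 0.05
    logfc_gate: float | None = None
    de_method: str = "moderated"
    min_r: float = 0.85
    alpha: float = 0.5
    enrich_p_max: float = 0.05
    min_jaccard: float = 0.2
    soft_power: int | None = None
    min_module_size: int = 10
    cut_height: float = 0.95
    string_cutoff: float = 0.4
    top_k_cerna: int = 5
    top_k_hubs: int = 20
    simulation: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in [0, 1]")
        if not 0 <= self.min_r <= 1:
            raise ValueError("min_r must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def demo_synthetic(seed: int = 0, outdir: str | Path = "results/pipeline", config: PipelineConfig | None = None):
    """Generate a synthetic study and run the full pipeline on it."""
    config = config or PipelineConfig()
    config.seed = int(seed)
    config.outdir = str(outdir)
    sim = synthetic.SimulationConfig(**config.simulation)
    design = synthetic.generate_design(config.n_per_group, seed=seed)
    matrices, truth = synthetic.generate_multiomics(design, sim, seed=seed)
    phen = synthetic.generate_phenotypes(design, seed=seed)
    return run_pipeline(config, design, matrices, phenotype_table=phen, truth=truth)


def run_pipeline(
    config: PipelineConfig,
    design: pd.DataFrame,
    matrices: dict[str, pd.DataFrame],
    phenotype_table: pd.DataFrame | None = None,
    gene_sets: dict[str, set] | None = None,
    ppi_edges: pd.DataFrame | None = None,
    truth: synthetic.TruthBundle | None = None,
) -> dict:
    """Execute every stage and write the report bundle.

    Missing optional inputs (gene sets, PPI) are synthesized from the
    run's own features so the bundle is always complete. Returns a dict
    of the in-memory stage outputs.
    """
    outdir = io.ensure_dir(config.outdir)
    t0 = time.time()
    stage_times = {}
    results: dict = {"outdir": outdir}

    def stage(name):
        stage_times[name] = time.time()
        log.info("stage %s", name)

    try:
        stage("phenotypes")
        if phenotype_table is not None:
            phenotype_table.to_csv(outdir / "phenotypes.csv", index=False)
            glucose = phenotypes.summarize_glucose_tables(
                phenotype_table, group_order=list(synthetic.GROUPS))
            glucose.to_csv(outdir / "glucose_summary.csv", index=False)
            results["glucose_summary"] = glucose
            panels = []
            for variable in sorted(set(phenotype_table["variable"]) - {"OGTT", "ITT"}):
                sub = phenotype_table[phenotype_table["variable"] == variable]
                by_group = {g: sub.loc[sub["group"] == g, "value"].to_numpy()
                            for g in synthetic.GROUPS if (sub["group"] == g).any()}
                summary = phenotypes.group_summary(by_group)
                summary.insert(0, "variable", variable)
                f_stat, p = phenotypes.one_way_anova(by_group)
                summary["anova_F"] = f_stat
                summary["anova_p"] = p
                panels.append(summary)
            panel_table = pd.concat(panels, ignore_index=True)
            panel_table.to_csv(outdir / "phenotype_summary.csv", index=False)
            results["phenotype_summary"] = panel_table

        stage("differential")
        records = diffexpr.screen_all(
            matrices, design, synthetic.COMPARISONS,
            fc_hi=config.fc_hi, fc_lo=config.fc_lo, fdr_max=config.fdr_max,
            method=config.de_method, logfc_gate=config.logfc_gate,
        )
        records.to_csv(outdir / "differential_records.tsv", sep="\t", index=False)
        deg_table = diffexpr.summarize_deg_table(
            records[records["direction"] != "ns"] if len(records) else records)
        deg_table.to_csv(outdir / "deg_summary.tsv", sep="\t", index=False)
        results["records"], results["deg_table"] = records, deg_table

        stage("trends")
        de_union = sorted(set(records.loc[records["direction"] != "ns", "feature"]))
        logged = {cat: diffexpr.normalize_counts(m) for cat, m in matrices.items()}
        group_means = {}
        for cat, lm in logged.items():
            gm = pd.DataFrame({
                g: lm[list(design.loc[design["group"] == g, "sample_id"])].mean(axis=1)
                for g in synthetic.GROUPS
            })
            group_means[cat] = gm
        trend_frames, efficacy_sets = [], {}
        for treatment in synthetic.TREATMENTS:
            eff_all = set()
            for cat, gm in group_means.items():
                feats = [f for f in gm.index if f in set(de_union)]
                if not feats:
                    continue
                table = trends.trend_table(
                    gm.loc[feats], treatment, min_r=config.min_r,
                    alpha=config.alpha, category=cat)
                trend_frames.append(table)
                eff_all |= set(table.loc[table["efficacy"], "feature"])
            efficacy_sets[treatment] = eff_all
        trend_table_all = (pd.concat(trend_frames, ignore_index=True)
                           if trend_frames else pd.DataFrame())
        trend_table_all.to_csv(outdir / "trend_assignments.tsv", sep="\t", index=False)
        if all(t in efficacy_sets for t in synthetic.TREATMENTS):
            venn = trends.cross_treatment_overlap(
                {t: efficacy_sets[t] for t in synthetic.TREATMENTS})
            venn.to_csv(outdir / "efficacy_venn.csv", index=False)
            results["venn"] = venn
        results["trend_table"] = trend_table_all
        results["efficacy_sets"] = efficacy_sets

        stage("enrichment")
        universe = list(matrices["mRNA"].index)
        efficacy_union = sorted(set().union(*efficacy_sets.values()) if efficacy_sets else set())
        efficacy_mrna = [f for f in efficacy_union if f in set(universe)]
        if gene_sets is None:
            gene_sets, dag_edges, _ = synthetic.generate_annotations(
                universe, n_sets=12, seed=config.seed, de_features=efficacy_mrna)
        else:
            dag_edges = []
        enrichment = enrich.hypergeom_enrich(
            efficacy_mrna, gene_sets, universe, p_max=config.enrich_p_max)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        significant_sets = list(enrichment.loc[enrichment["significant"], "set_id"])
        if dag_edges:
            tree = enrich.go_tree(significant_sets, dag_edges)
            io.write_edges(tree["edges"], outdir / "go_tree_edges.tsv")
        pw_net = enrich.pathway_network(significant_sets, gene_sets, config.min_jaccard)
        io.write_sif(pw_net, outdir / "pathway_network.sif")
        enriched_genes = set().union(*(gene_sets[s] for s in significant_sets)) if significant_sets else set()
        results["enrichment"] = enrichment

        stage("cerna")
        trend_signs = {}
        for treatment, eff in efficacy_sets.items():
            for cat, gm in group_means.items():
                signs = trends.trend_sign(gm, treatment)
                for f in eff & set(gm.index):
                    trend_signs[f] = int(signs[f])
        if truth is not None and truth.target_pairs:
            mirnas, utrs = synthetic.generate_sequences(truth.target_pairs, seed=config.seed)
            io.write_fasta(mirnas, outdir / "mirna.fasta")
            io.write_fasta(utrs, outdir / "utr.fasta")
            sites = cerna.predict_targets(mirnas, utrs)
        else:
            sites = pd.DataFrame(columns=["mirna", "target", "site_class", "position", "score"])
        sites.to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
        pairs = cerna.anticorrelation_filter(sites, trend_signs)
        triads, network = cerna.assemble_cerna(pairs, trend_signs, enriched_genes | set(
            t for t in pairs["target"] if cerna._category(t) == "mRNA"))
        triads.to_csv(outdir / "cerna_triads.tsv", sep="\t", index=False)
        io.write_sif(network, outdir / "cerna_network.sif")
        if network.number_of_nodes():
            io.write_graphml(network, outdir / "cerna_network.graphml")
        cerna_rank = cerna.rank_cerna_nodes(network, k=config.top_k_cerna)
        cerna_rank.to_csv(outdir / "cerna_top_mirnas.tsv", sep="\t", index=False)
        results["triads"], results["cerna_rank"] = triads, cerna_rank

        stage("coexpression")
        wgcna_tables = {}
        for label, sponge_cat in (("ncRNA_mRNA", "ncRNA"), ("circRNA_mRNA", "circRNA")):
            expr = pd.concat([logged["mRNA"], logged[sponge_cat]])
            keep = [f for f in expr.index if f in set(de_union)]
            expr = expr.loc[keep] if len(keep) >= 30 else expr.iloc[:200]
            expr = expr[expr.std(axis=1) > 0]
            if expr.shape[0] < 20:
                continue
            beta = config.soft_power
            if beta is None:
                beta, _ = wgcna.pick_soft_power(expr)
            tom = wgcna.adjacency_tom(expr, beta)
            modules = wgcna.detect_modules(
                tom, min_size=config.min_module_size, cut_height=config.cut_height)
            mts = wgcna.module_trait_significance(modules, expr, design)
            modules.to_frame().to_csv(outdir / f"modules_{label}.tsv", sep="\t")
            mts.to_csv(outdir / f"module_trait_{label}.csv", index=False)
            wgcna_tables[label] = {"beta": beta, "modules": modules, "module_trait": mts}
        results["wgcna"] = wgcna_tables

        stage("topology")
        if ppi_edges is None:
            ppi_features = efficacy_mrna if len(efficacy_mrna) >= 10 else universe[:200]
            ppi_edges, _ = synthetic.generate_ppi(ppi_features, seed=config.seed)
        ppi_edges = ppi_edges[ppi_edges["score"] >= config.string_cutoff]
        graph = topology.build_graph(ppi_edges)
        metrics = topology.topology_metrics(graph)
        metrics.to_csv(outdir / "ppi_topology.tsv", sep="\t", index=False)
        hubs = topology.hub_ranking(metrics, k=config.top_k_hubs)
        hubs.to_csv(outdir / "ppi_hubs.tsv", sep="\t", index=False)
        results["ppi_metrics"], results["hubs"] = metrics, hubs

        if truth is not None:
            truth.to_json(outdir / "truth.json")
    except Exception as exc:
        failed = max(stage_times, key=stage_times.get) if stage_times else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "stage_seconds": {
            name: round(
                (sorted(stage_times.values())[i + 1] if i + 1 < len(stage_times) else time.time())
                - start, 3)
            for i, (name, start) in enumerate(sorted(stage_times.items(), key=lambda kv: kv[1]))
        },
        "total_seconds": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
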