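"""miRNA seed-match target prediction and ceRNA triad assembly.

Target sites are canonical seed matches found by scanning each target
sequence (5'→3') for the reverse complement of the miRNA seed:

* ``7mer-m8`` — Watson–Crick match to miRNA positions 2–8;
* ``7mer-A1`` — match to positions 2–7 with an A in the target opposite
  miRNA position 1 (the 3' end of the site);
* ``8mer``    — both at once.

U and T are equivalent. Pairs are then filtered to sign-opposed
expression trends (miRNA up ⇔ target down), and a ceRNA triad
(miRNA, mRNA, sponge) requires the miRNA to target both, the mRNA and
sponge trends to agree, and the mRNA to carry a significant functional
annotation.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from Bio import SeqIO

from . import topology

SITE_SCORES = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Invalid nucleotide sequence."""


def _normalize(seq: str, name: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if not s or any(c not in "ACGT" for c in s):
        raise SequenceError(f"record {name!r} contains characters outside ACGUT")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _read_fasta(source) -> dict[str, str]:
    if isinstance(source, dict):
        return dict(source)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}


def scan_sites(mirna: str, target: str, mirna_id: str = "miRNA", target_id: str = "target") -> list[dict]:
    """All seed sites of one miRNA in one target sequence.

    Positions are 1-based offsets of the site's 5' end in the target.
    At a given position the strongest matching class is reported
    (8mer > 7mer-m8 > 7mer-A1).
    """
    mir = _normalize(mirna, mirna_id)
    tgt = _normalize(target, target_id)
    if len(mir) < 8:
        raise SequenceError(f"miRNA {mirna_id!r} shorter than 8 nt")
    seed_m8 = _revcomp(mir[1:8])  # pairs positions 2-8
    seed_m7 = _revcomp(mir[1:7])  # pairs positions 2-7
    sites = []
    for pos in range(len(tgt) - 6):
        window8 = tgt[pos : pos + 7]
        a1 = pos + 7 < len(tgt) and tgt[pos + 7] == "A"
        if window8 == seed_m8:
            cls = "8mer" if a1 else "7mer-m8"
            sites.append({"mirna": mirna_id, "target": target_id, "site_class": cls,
                          "position": pos + 1, "score": SITE_SCORES[cls]})
        elif tgt[pos : pos + 6] == seed_m7 and pos + 6 < len(tgt) and tgt[pos + 6] == "A":
            sites.append({"mirna": mirna_id, "target": target_id, "site_class": "7mer-A1",
                          "position": pos + 1, "score": SITE_SCORES["7mer-A1"]})
    # an 8mer contains a nested 7mer-A1 pattern one base downstream;
    # report only the strongest site per seed region
    eightmer_pos = {s["position"] for s in sites if s["site_class"] == "8mer"}
    sites = [
        s for s in sites
        if not (s["site_class"] == "7mer-A1" and s["position"] - 1 in eightmer_pos)
    ]
    return sites


def predict_targets(mirna_fasta, target_fasta) -> pd.DataFrame:
    """Seed-site table for every miRNA × target sequence pair.

    Inputs are FASTA paths or id → sequence mappings. Columns:
    mirna, target, site_class, position (1-based), score.
    """
    mirnas = _read_fasta(mirna_fasta)
    targets = _read_fasta(target_fasta)
    rows = []
    for mir_id, mir_seq in mirnas.items():
        for tgt_id, tgt_seq in targets.items():
            rows.extend(scan_sites(mir_seq, tgt_seq, mir_id, tgt_id))
    return pd.DataFrame(rows, columns=["mirna", "target", "site_class", "position", "score"])


def anticorrelation_filter(sites: pd.DataFrame, trends: dict) -> pd.DataFrame:
    """Retain (miRNA, target) pairs with opposed non-zero trend signs.

    ``trends`` maps feature id → trend sign (−1/0/+1). Pairs with a
    missing or flat trend on either side are dropped and recorded in the
    ``skipped`` attribute of the result.
    """
    kept, skipped = [], []
    pairs = sites[["mirna", "target"]].drop_duplicates()
    for mir, tgt in pairs.itertuples(index=False):
        s_mir = trends.get(mir)
        s_tgt = trends.get(tgt)
        if not s_mir or not s_tgt:
            skipped.append((mir, tgt, "missing or flat trend"))
            continue
        if s_mir == -s_tgt:
            kept.append({"mirna": mir, "target": tgt, "mirna_trend": int(s_mir),
                         "target_trend": int(s_tgt)})
    out = pd.DataFrame(kept, columns=["mirna", "target", "mirna_trend", "target_trend"])
    out.attrs["skipped"] = skipped
    return out


def _category(feature: str) -> str:
    prefix = feature.split(":", 1)[0] if ":" in feature else ""
    return {"mRNA": "mRNA", "nc": "ncRNA", "circ": "circRNA", "miR": "miRNA"}.get(prefix, "gene")


def assemble_cerna(
    pairs: pd.DataFrame,
    trends: dict,
    enriched_genes,
    sponge_categories: tuple = ("circRNA", "ncRNA"),
) -> tuple[pd.DataFrame, nx.Graph]:
    """Triads (miRNA, mRNA, sponge) and the typed ceRNA graph.

    A triad needs one miRNA with retained anti-correlated pairs to both
    an mRNA and a sponge (circRNA or ncRNA), equal mRNA/sponge trend
    signs, and the mRNA present in ``enriched_genes``. The graph holds
    exactly the edges supporting emitted triads.
    """
    enriched = set(enriched_genes)
    triads = []
    for mir in sorted(set(pairs["mirna"])) if len(pairs) else []:
        sub = pairs[pairs["mirna"] == mir]
        mrnas = sorted(t for t in sub["target"] if _category(t) == "mRNA" and t in enriched)
        sponges = sorted(t for t in sub["target"] if _category(t) in sponge_categories)
        for mrna in mrnas:
            for sponge in sponges:
                if trends.get(mrna) == trends.get(sponge):
                    triads.append(
                        {"mirna": mir, "mrna": mrna, "sponge": sponge,
                         "mirna_trend": int(trends[mir]), "mrna_trend": int(trends[mrna]),
                         "sponge_trend": int(trends[sponge])}
                    )
    triad_df = pd.DataFrame(
        triads, columns=["mirna", "mrna", "sponge", "mirna_trend", "mrna_trend", "sponge_trend"]
    )
    graph = nx.Graph()
    for row in triad_df.itertuples(index=False):
        for node in (row.mirna, row.mrna, row.sponge):
            graph.add_node(node, node_type=_category(node), trend=int(trends[node]))
        graph.add_edge(row.mirna, row.mrna, interaction="miRNA-mRNA")
        graph.add_edge(row.mirna, row.sponge, interaction="miRNA-sponge")
    return triad_df, graph


def rank_cerna_nodes(network: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Top-k miRNA nodes by degree with the 7-metric topology vector.

    Column order matches the published ceRNA hub table: degree, average
    shortest path length, betweenness, closeness, neighborhood
    connectivity, radiality, topological coefficient.
    """
    cols = ["node", "degree", "avg_shortest_path", "betweenness", "closeness",
            "neighborhood_connectivity", "radiality", "topological_coef"]
    if network.number_of_nodes() == 0:
        return pd.DataFrame(columns=cols)
    metrics = topology.topology_metrics(network)
    mirna_nodes = {n for n, d in network.nodes(data=True) if d.get("node_type") == "miRNA"}
    table = metrics[metrics["node"].isin(mirna_nodes)] if mirna_nodes else metrics
    ranked = topology.hub_ranking(table, k=k)
    return ranked[cols].reset_index(drop=True)
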