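"""Gene-set over-representation, GO-tree pruning and pathway networks.

Over-representation uses the one-sided upper-tail hypergeometric test
(equivalently a one-sided Fisher exact test) with BH FDR across sets.
The GO tree is the sub-DAG induced by the significant terms plus the
ancestors needed to connect them to the roots; pathway–pathway edges
are drawn when the member-gene Jaccard overlap reaches a threshold.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr


class EnrichError(ValueError):
    """Invalid enrichment input."""


def hypergeom_enrich(
    gene_list,
    gene_sets: dict[str, set],
    universe,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``gene_list``.

    Every set is first intersected with the universe; p is the
    probability of drawing ≥ k annotated genes in n = |list| draws from
    N = |universe| containing m = |set| annotated genes. k = 0 gives
    p = 1 exactly. ``significant`` applies the raw-p gate ``p_max``;
    BH FDR across sets is reported alongside.
    """
    universe = set(universe)
    if not universe:
        raise EnrichError("empty universe")
    genes = set(gene_list) & universe
    n = len(genes)
    rows = []
    for set_id, members in gene_sets.items():
        members = set(members) & universe
        m = len(members)
        k = len(genes & members)
        p = float(hypergeom.sf(k - 1, len(universe), m, n)) if k > 0 else 1.0
        rows.append(
            {"set_id": set_id, "k": k, "m": m, "n": n, "N": len(universe),
             "pvalue": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
        out["significant"] = out["pvalue"] < p_max
        out = out.sort_values(["pvalue", "set_id"], kind="stable").reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=["set_id", "k", "m", "n", "N", "pvalue", "fdr", "significant"])
    return out


def go_tree(significant_terms, dag_edges) -> dict:
    """Sub-DAG connecting the significant terms through their ancestors.

    ``dag_edges`` are (parent, child) pairs of an acyclic ontology
    graph. The node set is the significant terms plus every ancestor on
    a path to them; edges are the induced parent→child relations.
    A two-term component in which one significant term merely subsumes
    the other and neither relates to anything else is dropped from the
    display edge set, but both terms stay in the record list.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(dag_edges)
    if not nx.is_directed_acyclic_graph(dag):
        raise EnrichError("ontology edge list contains a cycle")
    significant = set(significant_terms)
    keep = set(significant)
    for term in significant:
        if term in dag:
            keep |= nx.ancestors(dag, term)
    sub = dag.subgraph(keep)
    edges = list(sub.edges())
    display = nx.DiGraph()
    display.add_nodes_from(keep)
    display.add_edges_from(edges)
    pruned = []
    for u, v in edges:
        if (
            u in significant and v in significant
            and display.degree(u) == 1 and display.degree(v) == 1
        ):
            pruned.append((u, v))
    display.remove_edges_from(pruned)
    records = [
        {"term": t, "significant": t in significant, "ancestor_only": t not in significant}
        for t in sorted(keep)
    ]
    return {
        "nodes": records,
        "edges": sorted(display.edges()),
        "pruned_edges": sorted(pruned),
    }


def pathway_network(
    enriched_pathways,
    membership: dict[str, set],
    min_jaccard: float = 0.2,
) -> nx.Graph:
    """Pathway graph: undirected edge when member Jaccard ≥ ``min_jaccard``.

    Nodes are the significant pathways; edge weight is the Jaccard index
    of the two pathways' member-gene sets.
    """
    graph = nx.Graph()
    pathways = list(dict.fromkeys(enriched_pathways))
    graph.add_nodes_from(pathways)
    for a, b in combinations(pathways, 2):
        set_a = set(membership.get(a, ()))
        set_b = set(membership.get(b, ()))
        union = set_a | set_b
        if not union:
            continue
        jac = len(set_a & set_b) / len(union)
        if jac >= min_jaccard and jac > 0:
            graph.add_edge(a, b, weight=jac)
    return graph
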