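"""Readers/writers for the pipeline's plain-text interchange formats.

Counts: TSV with feature ids in the first column and sample ids as the
header. Gene sets: GMT (id, description, tab-separated members). DAG:
two-column parent/child TSV. Sequences: FASTA. PPI: three-column TSV.
Networks: SIF and GraphML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gmt(gene_sets: dict[str, set], path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            desc = (descriptions or {}).get(set_id, "na")
            members = "\t".join(sorted(gene_sets[set_id]))
            fh.write(f"{set_id}\t{desc}\t{members}\n")


def read_gmt(path) -> dict[str, set]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_edges(edges, path, columns=("parent", "child")) -> None:
    pd.DataFrame(edges, columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sif(graph: nx.Graph, path, interaction_key: str = "interaction") -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{data.get(interaction_key, 'pp')}\t{v}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
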