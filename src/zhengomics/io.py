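"""Readers/writers for the plain-text knowledge-base formats.

GMT (gene-matrix-transposed) files hold named annotation sets, one per line:
``term<TAB>description<TAB>member1<TAB>member2...``.  SIF edge lists hold one
edge per line: ``node1<TAB>relation<TAB>node2``; edge weights travel in a
parallel TSV (node1, node2, weight).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            desc = (descriptions or {}).get(term, term)
            members = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def read_sif(path: str | Path, weights_path: str | Path | None = None) -> nx.Graph:
    """Load an undirected graph from a SIF edge list.

    Node kinds are taken from the relation column when it has the form
    ``kind1-kind2`` (e.g. ``gene-metabolite``); otherwise nodes default to
    kind ``gene``.
    """
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                continue
            a, rel, b = parts
            kinds = rel.split("-")
            ka = kinds[0] if len(kinds) == 2 else "gene"
            kb = kinds[1] if len(kinds) == 2 else "gene"
            g.add_node(a, kind=g.nodes[a].get("kind", ka) if a in g else ka)
            g.add_node(b, kind=g.nodes[b].get("kind", kb) if b in g else kb)
            g.add_edge(a, b, weight=1.0)
    if weights_path is not None:
        w = pd.read_csv(weights_path, sep="\t")
        for _, row in w.iterrows():
            a, b = str(row.iloc[0]), str(row.iloc[1])
            if g.has_edge(a, b):
                g[a][b]["weight"] = float(row.iloc[2])
    return g


def write_sif(g: nx.Graph, path: str | Path, weights_path: str | Path | None = None) -> None:
    rows = []
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            ka = g.nodes[a].get("kind", "gene")
            kb = g.nodes[b].get("kind", "gene")
            fh.write(f"{a}\t{ka}-{kb}\t{b}\n")
            rows.append((a, b, data.get("weight", 1.0)))
    if weights_path is not None:
        pd.DataFrame(rows, columns=["node1", "node2", "weight"]).to_csv(
            weights_path, sep="\t", index=False
        )
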