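"""SIF interaction-network parsing and degree-based hub detection.

Hub genes follow the common protein-protein interaction convention: nodes
with degree (number of distinct interaction partners) of at least ten.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_HUB_DEGREE = 10


def read_sif(path: str | Path) -> nx.Graph:
    """Parse SIF lines ``A <tab> relation <tab> B [<tab> C ...]``.

    Multi-target lines expand to pairwise (A,B), (A,C) edges; duplicate and
    reversed-duplicate edges collapse; self-loops are dropped with a warning.
    Lines with fewer than 3 fields are an error.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: SIF line needs >= 3 tab-separated fields")
            source, _relation, *targets = fields
            if not source or any(not t for t in targets):
                raise ValueError(f"{path}:{lineno}: empty node identifier")
            for target in targets:
                if target == source:
                    log.warning("%s:%d: self-loop %s dropped", path, lineno,
                                source)
                    g.add_node(source)
                    continue
                g.add_edge(source, target)
    return g


def write_sif(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Canonical SIF: one line per edge, endpoints sorted, edges sorted."""
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{relation}\t{b}\n")


def find_hubs(g: nx.Graph, min_degree: int = DEFAULT_HUB_DEGREE) -> list[str]:
    """Nodes with degree >= min_degree, descending degree then name."""
    hubs = [(n, d) for n, d in g.degree() if d >= min_degree]
    hubs.sort(key=lambda nd: (-nd[1], nd[0]))
    return [n for n, _ in hubs]


def node_table(g: nx.Graph, min_degree: int = DEFAULT_HUB_DEGREE) -> pd.DataFrame:
    """Per-node degree table with hub flag (descending degree then name)."""
    rows = [{"node": n, "degree": d, "is_hub": d >= min_degree}
            for n, d in g.degree()]
    return (pd.DataFrame(rows, columns=["node", "degree", "is_hub"])
            .sort_values(["degree", "node"], ascending=[False, True],
                         kind="mergesort")
            .reset_index(drop=True))


def edge_table(g: nx.Graph) -> pd.DataFrame:
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    return pd.DataFrame(edges, columns=["node_a", "node_b"])
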