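"""Hypergeometric over-representation analysis against GMT gene sets.

Given a signature (the "hits"), a gene universe (by default every gene on the
collapsed expression matrix) and a named gene-set collection, each set is
tested with the one-sided hypergeometric upper tail
P(X >= found | population=|universe|, successes=|set ∩ universe|,
draws=|hits|), followed by Benjamini-Hochberg FDR across sets — the entity
ratio / FDR table familiar from Reactome-style reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions and a collection-level universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if not self.universe:
            self.universe = {g for members in self.sets.values() for g in members}

    def __len__(self) -> int:
        return len(self.sets)

    def harmonize(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with an external universe; drop emptied sets."""
        kept = {}
        for name, members in self.sets.items():
            inter = sorted(set(members) & universe)
            if inter:
                kept[name] = inter
            else:
                log.info("set %s has no genes in the universe; dropped", name)
        return GeneSetCollection(sets=kept,
                                 descriptions={n: self.descriptions.get(n, "")
                                               for n in kept},
                                 universe=set(universe))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                log.info("set %s: %d duplicate genes removed", name,
                         len(genes) - len(deduped))
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in gsc.sets:
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *gsc.sets[name]]) + "\n")


def hypergeom_tail(found: int, universe_size: int, set_size: int,
                   n_hits: int) -> float:
    """P(X >= found) for X ~ Hypergeometric(universe_size, set_size, n_hits)."""
    return float(stats.hypergeom.sf(found - 1, universe_size, set_size, n_hits))


def ora(hits: list[str], universe: list[str],
        gsc: GeneSetCollection) -> pd.DataFrame:
    """Over-representation table: one row per set, ascending p then name.

    Columns: name, found, set_size, entities_ratio (set size over universe
    size), p (hypergeometric upper tail), fdr (BH across all tested sets).
    """
    uni = set(universe)
    hit_set = set(hits)
    if not hit_set or not uni:
        raise ValueError("hits and universe must be non-empty")
    stray = hit_set - uni
    if stray:
        raise ValueError(f"hits outside universe: {sorted(stray)[:5]}")
    harmonized = gsc.harmonize(uni)
    if not harmonized.sets:
        raise ValueError("no gene set overlaps the universe")
    rows = []
    for name, members in harmonized.sets.items():
        found = len(hit_set & set(members))
        p = hypergeom_tail(found, len(uni), len(members), len(hit_set))
        rows.append({"name": name, "found": found, "set_size": len(members),
                     "entities_ratio": len(members) / len(uni), "p": p})
    table = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(table["p"], method="fdr_bh")
    table["fdr"] = fdr
    return (table.sort_values(["p", "name"], kind="mergesort")
            .reset_index(drop=True))


def pathway_gene_counts(hits: list[str], gsc: GeneSetCollection) -> pd.DataFrame:
    """Per-set hit counts (no testing), sorted descending count then name —
    the bar-chart export."""
    hit_set = set(hits)
    rows = [{"name": name, "found": len(hit_set & set(members))}
            for name, members in gsc.sets.items()]
    return (pd.DataFrame(rows)
            .sort_values(["found", "name"], ascending=[False, True],
                         kind="mergesort")
            .reset_index(drop=True))


def set_overlap_edges(gsc: GeneSetCollection,
                      min_jaccard: float = 0.25) -> pd.DataFrame:
    """Jaccard-overlap edge list between sets, for external network viewers."""
    rows = []
    names = sorted(gsc.sets)
    for a, b in combinations(names, 2):
        sa, sb = set(gsc.sets[a]), set(gsc.sets[b])
        j = len(sa & sb) / len(sa | sb)
        if j > min_jaccard:
            rows.append({"set_a": a, "set_b": b, "jaccard": j})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard"])
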