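"""Lowest-common-ancestor taxonomic assignment of hit-bearing reads.

Implements the MEGAN-style LCA: per query, discard hits below a minimum
bit score or above a maximum e-value, retain hits whose bit score is
within ``top_percent`` (multiplicative) of the best, and assign the read
to the lowest common ancestor of the retained subjects' taxa.  Defaults
follow the common parameterization for short-read protein searches:
min score 50 bits, max expected 0.01, top percent 10.

Taxonomies are read in the NCBI ``nodes.dmp``/``names.dmp`` dialect
(pipe-and-tab separated); only the scientific name is kept per node.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .search import SearchHit


@dataclass
class TaxNode:
    tax_id: int
    parent_id: int
    rank: str
    name: str = ""


@dataclass
class LcaParams:
    min_score: float = 50.0
    max_expected: float = 0.01
    top_percent: float = 10.0
    min_support: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")


class Taxonomy:
    """Rooted taxonomy; the root is its own parent (NCBI convention)."""

    def __init__(self, nodes: list[TaxNode]):
        self.nodes: dict[int, TaxNode] = {}
        for n in nodes:
            if n.tax_id in self.nodes:
                raise ValueError(f"duplicate tax_id {n.tax_id}")
            self.nodes[n.tax_id] = n
        for n in nodes:
            if n.parent_id not in self.nodes:
                raise ValueError(
                    f"tax_id {n.tax_id} has unknown parent {n.parent_id}")

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def path_to_root(self, tax_id: int) -> list[int]:
        """tax_id first, root last."""
        path = []
        seen = set()
        while tax_id not in seen:
            seen.add(tax_id)
            path.append(tax_id)
            parent = self.nodes[tax_id].parent_id
            if parent == tax_id:
                break
            tax_id = parent
        return path

    def lca(self, tax_ids: list[int]) -> int:
        paths = [self.path_to_root(t) for t in tax_ids]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node = first along any path
        for t in paths[0]:
            if t in common:
                return t
        raise ValueError("disjoint paths in a rooted taxonomy")

    def ancestor_at_rank(self, tax_id: int, rank: str) -> int | None:
        for t in self.path_to_root(tax_id):
            if self.nodes[t].rank == rank:
                return t
        return None

    def name(self, tax_id: int) -> str:
        return self.nodes[tax_id].name or str(tax_id)


def parse_nodes_dmp(text: str) -> list[tuple[int, int, str]]:
    """(tax_id, parent_id, rank) triples from nodes.dmp."""
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        cols = [c.strip() for c in line.rstrip("|\n").split("|")]
        out.append((int(cols[0]), int(cols[1]), cols[2]))
    return out


def parse_names_dmp(text: str) -> dict[int, str]:
    """tax_id -> scientific name from names.dmp."""
    names: dict[int, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        cols = [c.strip() for c in line.rstrip("|\n").split("|")]
        if len(cols) >= 4 and cols[3] == "scientific name" and int(cols[0]) not in names:
            names[int(cols[0])] = cols[1]
        elif len(cols) < 4 and int(cols[0]) not in names:
            names[int(cols[0])] = cols[1]
    return names


def load_taxonomy(nodes_text: str, names_text: str = "") -> Taxonomy:
    names = parse_names_dmp(names_text) if names_text else {}
    return Taxonomy([TaxNode(t, p, r, names.get(t, ""))
                     for t, p, r in parse_nodes_dmp(nodes_text)])


@dataclass
class LcaStats:
    unknown_taxid_hits: int = 0
    unassigned_queries: int = 0
    notes: list[str] = field(default_factory=list)


def assign_lca(hits: list[SearchHit], taxonomy: Taxonomy,
               p: LcaParams | None = None,
               stats: LcaStats | None = None) -> int | None:
    """LCA taxon for one query's hits, or None when no hit is retained.

    Retention: bit >= min_score, evalue <= max_expected, then bit >=
    (1 - top_percent/100) * best bit.  Hits with unknown subject taxa are
    ignored and counted in ``stats``.
    """
    p = p or LcaParams()
    qid = hits[0].query_id if hits else None
    if any(h.query_id != qid for h in hits):
        raise ValueError("hits do not share a query_id")
    kept = [h for h in hits
            if h.bit_score >= p.min_score and h.evalue <= p.max_expected]
    taxa = []
    for h in kept:
        if h.subject_tax_id is None or h.subject_tax_id not in taxonomy:
            if stats is not None:
                stats.unknown_taxid_hits += 1
            continue
        taxa.append(h)
    if not taxa:
        if stats is not None:
            stats.unassigned_queries += 1
        return None
    best = max(h.bit_score for h in taxa)
    floor = (1.0 - p.top_percent / 100.0) * best
    retained = [h.subject_tax_id for h in taxa if h.bit_score >= floor]
    return taxonomy.lca(retained)


def assign_all(hits_by_query: dict[str, list[SearchHit]], taxonomy: Taxonomy,
               p: LcaParams | None = None) -> tuple[dict[str, int], LcaStats]:
    stats = LcaStats()
    out = {}
    for qid, hits in hits_by_query.items():
        t = assign_lca(hits, taxonomy, p, stats)
        if t is not None:
            out[qid] = t
    return out, stats


def rollup_phylum(assignments: dict[str, int], taxonomy: Taxonomy,
                  min_support: int = 1) -> pd.Series:
    """Phylum-level fractions over assigned queries (summing to 1).

    Assignments with no phylum-rank ancestor, and phyla supported by
    fewer than ``min_support`` queries, are pooled as "unclassified".
    """
    if not assignments:
        raise ValueError("no assignments")
    counts: Counter[str] = Counter()
    for tax_id in assignments.values():
        phylum = taxonomy.ancestor_at_rank(tax_id, "phylum")
        counts[taxonomy.name(phylum) if phylum is not None else "unclassified"] += 1
    if min_support > 1:
        pooled: Counter[str] = Counter()
        for name, c in counts.items():
            pooled["unclassified" if c < min_support and name != "unclassified"
                   else name] += c
        counts = pooled
    total = sum(counts.values())
    return pd.Series({k: v / total for k, v in sorted(counts.items())},
                     name="fraction")
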