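"""Family-level inventories from search hits.

The counting unit is the fold family.  Each hit-bearing query contributes
exactly one unit of weight per metal, split fractionally among the
references sharing the (rounded) best bit score; family weights are then
aggregated per sample, the multidomain cupredoxin family b.6.1.3 is split
into nirK vs. multicopper oxidases by subject description, families below
4% of the metal's total are clustered as "others", and counts are
normalized per 100,000 protein-coding sequences.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .search import SearchHit

CUPREDOXIN_FAMILY = "b.6.1.3"
NIRK_LABEL = "b.6.1.3/nirK"
MCO_LABEL = "b.6.1.3/MCO"
OTHERS_LABEL = "others"
TOTAL_LABEL = "total"

#: Ordered, case-insensitive description patterns; first match wins.
#: Editable configuration: the split is by gene description text.
DEFAULT_CUPREDOXIN_RULES: list[tuple[str, list[str]]] = [
    (NIRK_LABEL, ["nirk", "nitrite reductase (copper", "copper-containing nitrite reductase",
                  "cu-nir", "copper nitrite reductase"]),
    (MCO_LABEL, ["multicopper oxidase", "multi-copper oxidase", "laccase",
                 "ceruloplasmin", "ascorbate oxidase", "bilirubin oxidase",
                 "cuo", "copper oxidase"]),
]


@dataclass
class AssignmentPart:
    label: str            # family sccs, split label, or "others"
    metal: str
    weight: float
    description: str = ""


@dataclass
class HitAssignment:
    query_id: str
    parts: list[AssignmentPart]

    def total_weight(self) -> float:
        return sum(p.weight for p in self.parts)


@dataclass
class InventoryTable:
    sample_id: str
    metal: str
    rows: pd.DataFrame    # columns: label, weighted_count, per_100k
    total_protein_coding: int
    warnings: list[str] = field(default_factory=list)


def group_hits_by_query(hits: Iterable[SearchHit], metal: str | None = None) \
        -> Iterator[list[SearchHit]]:
    """Group hits per (query, metal); queries hitting both metals are
    assigned within each metal independently."""
    grouped: dict[tuple[str, str], list[SearchHit]] = defaultdict(list)
    order: list[tuple[str, str]] = []
    for h in hits:
        if metal is not None and h.metal != metal:
            continue
        key = (h.query_id, h.metal)
        if key not in grouped:
            order.append(key)
        grouped[key].append(h)
    for key in order:
        yield grouped[key]


def assign_top_hits(hits: list[SearchHit], tie_decimals: int = 1) -> HitAssignment:
    """Fractional top-hit weights: the k hits sharing the best bit score
    (compared after rounding to ``tie_decimals``) each get weight 1/k."""
    if not hits:
        raise ValueError("empty hit list")
    qid = hits[0].query_id
    if any(h.query_id != qid for h in hits):
        raise ValueError("hits do not share a query_id")
    rounded = [round(h.bit_score, tie_decimals) for h in hits]
    best = max(rounded)
    top = [h for h, r in zip(hits, rounded) if r == best]
    w = 1.0 / len(top)
    parts = [AssignmentPart(h.family_sccs, h.metal, w, h.subject_description)
             for h in top]
    return HitAssignment(qid, parts)


def split_cupredoxins(
    assignments: Iterable[HitAssignment],
    rules: list[tuple[str, list[str]]] | None = None,
) -> Iterator[HitAssignment]:
    """Relabel b.6.1.3 parts as nirK or MCO by their subject description.

    First matching pattern wins; parts matching neither keep the plain
    b.6.1.3 label (and are later routed into "others" by
    :func:`cluster_minor`).  Other families pass through unchanged.
    Weights are never altered.
    """
    rules = DEFAULT_CUPREDOXIN_RULES if rules is None else rules
    compiled = [(label, [re.compile(re.escape(pat), re.IGNORECASE)
                         for pat in pats]) for label, pats in rules]
    for a in assignments:
        parts = []
        for p in a.parts:
            if p.label != CUPREDOXIN_FAMILY:
                parts.append(p)
                continue
            new_label = CUPREDOXIN_FAMILY
            for label, pats in compiled:
                if any(rx.search(p.description or "") for rx in pats):
                    new_label = label
                    break
            parts.append(AssignmentPart(new_label, p.metal, p.weight,
                                        p.description))
        yield HitAssignment(a.query_id, parts)


def aggregate(assignments: Iterable[HitAssignment], metal: str) \
        -> dict[str, float]:
    """Sum part weights per label for one metal.

    The grand total equals the number of queries contributing to that
    metal (each query carries total weight 1 within a metal).
    """
    counts: dict[str, float] = defaultdict(float)
    for a in assignments:
        for p in a.parts:
            if p.metal == metal:
                counts[p.label] += p.weight
    return dict(counts)


def cluster_minor(counts: dict[str, float],
                  threshold_fraction: float = 0.04) -> dict[str, float]:
    """Merge families below ``threshold_fraction`` of the total into "others".

    Labels at exactly the threshold are retained; the unsplit b.6.1.3
    remainder always merges into "others".  Total weight is conserved
    exactly (merged weights are summed, never rescaled).
    """
    if not counts:
        raise ValueError("empty counts")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold must be in (0, 1)")
    total = sum(counts.values())
    out: dict[str, float] = {}
    others = counts.get(OTHERS_LABEL, 0.0)
    for label, c in counts.items():
        if label == OTHERS_LABEL:
            continue
        if label == CUPREDOXIN_FAMILY or (total > 0 and c / total < threshold_fraction):
            others += c
        else:
            out[label] = c
    if others > 0 or not out:
        out[OTHERS_LABEL] = others if out else total
    return out


def normalize_per_100k(counts: dict[str, float], total_protein_coding: int,
                       sample_id: str = "", metal: str = "") -> InventoryTable:
    """Normalize weighted counts per 100,000 protein-coding sequences.

    ``total_protein_coding`` is the external per-sample denominator (the
    number of protein-coding sequences); it is never inferred from the
    metal hits themselves.
    """
    if total_protein_coding <= 0:
        raise ValueError("total_protein_coding must be positive")
    total = sum(counts.values())
    if total_protein_coding < total:
        raise ValueError(
            f"denominator {total_protein_coding} smaller than total weighted "
            f"count {total:.3f}")
    labels = sorted(counts)
    rows = pd.DataFrame({
        "label": labels + [TOTAL_LABEL],
        "weighted_count": [counts[l] for l in labels] + [total],
    })
    rows["per_100k"] = rows["weighted_count"] / total_protein_coding * 100_000
    return InventoryTable(sample_id=sample_id, metal=metal, rows=rows,
                          total_protein_coding=total_protein_coding)


def profile_sample(
    hits: Iterable[SearchHit],
    total_protein_coding: int,
    sample_id: str = "",
    metals: tuple[str, ...] = ("Fe", "Cu"),
    threshold_fraction: float = 0.04,
    tie_decimals: int = 1,
    split_rules: list[tuple[str, list[str]]] | None = None,
) -> dict[str, InventoryTable]:
    """hits -> per-metal inventory: assign, split, cluster, normalize."""
    hits = list(hits)
    tables = {}
    for metal in metals:
        assignments = [assign_top_hits(group, tie_decimals)
                       for group in group_hits_by_query(hits, metal)]
        assignments = list(split_cupredoxins(assignments, split_rules))
        counts = aggregate(assignments, metal)
        if counts:
            counts = cluster_minor(counts, threshold_fraction)
        tables[metal] = normalize_per_100k(counts, total_protein_coding,
                                           sample_id, metal)
    return tables


def inventory_matrix(tables: dict[str, dict[str, InventoryTable]],
                     value: str = "per_100k") -> pd.DataFrame:
    """Combine {sample: {metal: InventoryTable}} into a samples x labels
    matrix (labels prefixed by metal, totals excluded)."""
    records = {}
    for sample_id, by_metal in tables.items():
        row = {}
        for metal, tab in by_metal.items():
            body = tab.rows[tab.rows["label"] != TOTAL_LABEL]
            for _, r in body.iterrows():
                row[f"{metal}:{r['label']}"] = r[value]
        records[sample_id] = row
    return pd.DataFrame.from_dict(records, orient="index").fillna(0.0).sort_index(axis=1)


def write_inventory_tsv(tab: InventoryTable, handle) -> None:
    handle.write("label\tmetal\tweighted_count\tper_100k\n")
    for _, r in tab.rows.iterrows():
        handle.write(f"{r['label']}\t{tab.metal}\t{r['weighted_count']:.6f}\t"
                     f"{r['per_100k']:.6f}\n")
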