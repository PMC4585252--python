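"""Structural-classification hierarchy parsing and Fe/Cu reference building.

The reference database is derived from a SCOP-style hierarchy: a rooted
tree of nodes keyed by an integer identifier (sunid) with dotted
class.fold.superfamily.family labels (sccs, e.g. ``b.6.1.3``), whose
domain-level leaves carry amino-acid sequences.  Metal references are
built by recursively expanding seed sunids for curated lists of Fe- and
Cu-binding fold families, with family-level exclusions (e.g. the Fe
regulatory protein aconitase, c.83.1.1, which is removed to restrict the
inventory to catalytic Fe proteins).

File dialect
------------
Two tab-separated tables are read, both tolerating ``#`` comment lines
and trailing extra columns:

* description ("des") rows: ``sunid  level  sccs  identifier  description``
  with level codes ``cl`` (class), ``cf`` (fold), ``sf`` (superfamily),
  ``fa`` (family) and ``dm`` (domain).  Tree topology is recovered from
  the sccs: a fold's parent is the class with the same leading component,
  and so on; a domain's parent is the family sharing its full sccs.
* classification ("cla") rows: ``domain_id  source  region  sccs  sunid
  ancestry`` where ancestry is a comma-separated ``code=sunid`` list.
  These are cross-checked against the des-derived tree; disagreements
  are recorded as warnings, never silently dropped.

Domain sequences come from a protein FASTA whose record ids match the
domain identifiers in the des table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO

ROOT_SUNID = 0

LEVELS = ("root", "class", "fold", "superfamily", "family", "domain")
_LEVEL_CODES = {"cl": "class", "cf": "fold", "sf": "superfamily",
                "fa": "family", "dm": "domain"}
_SCCS_DEPTH = {"class": 1, "fold": 2, "superfamily": 3, "family": 4}

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class ParseError(ValueError):
    """Malformed input row; the message names the offending line."""


class HierarchyError(ValueError):
    """Structural inconsistency (duplicate sunid, missing parent, bad seed)."""


@dataclass
class HierarchyNode:
    sunid: int
    sccs: str                 # "" for root and (optionally) class level
    level: str                # one of LEVELS
    parent_sunid: int | None  # None only for root
    description: str = ""
    identifier: str = ""      # domain id for leaves
    sequence: str | None = None


@dataclass
class Hierarchy:
    nodes: dict[int, HierarchyNode]
    root: int = ROOT_SUNID
    children: dict[int, list[int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def node(self, sunid: int) -> HierarchyNode:
        try:
            return self.nodes[sunid]
        except KeyError:
            raise HierarchyError(f"unknown sunid {sunid}") from None

    def domains(self) -> list[HierarchyNode]:
        """All domain-level leaves, in ascending sunid order."""
        return sorted(
            (n for n in self.nodes.values() if n.level == "domain"),
            key=lambda n: n.sunid,
        )

    def find_by_sccs(self, sccs: str) -> list[HierarchyNode]:
        return sorted(
            (n for n in self.nodes.values() if n.sccs == sccs and n.level != "domain"),
            key=lambda n: n.sunid,
        )


@dataclass
class ReferenceEntry:
    protein_id: str
    family_sccs: str
    metal: str                # "Fe" or "Cu"
    sequence: str
    description: str = ""
    dual_metal: bool = False  # reachable from both Fe and Cu seeds


@dataclass
class MetalReference:
    entries: list[ReferenceEntry]
    excluded_families: list[tuple[str, str, int]] = field(default_factory=list)
    # (sccs, reason, n_removed)
    warnings: list[str] = field(default_factory=list)

    def by_metal(self, metal: str) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.metal == metal]

    def total_residues(self) -> int:
        return sum(len(e.sequence) for e in self.entries)


def _split_row(line: str, line_no: int, min_cols: int, what: str) -> list[str]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < min_cols:
        raise ParseError(
            f"{what} line {line_no}: expected >= {min_cols} columns, got {len(cols)}"
        )
    return cols


def parse_hierarchy(cla_text: str, des_text: str, fasta_text: str) -> Hierarchy:
    """Parse des/cla tables plus a domain FASTA into a rooted Hierarchy.

    Raises :class:`ParseError` on malformed rows (naming the line) and
    :class:`HierarchyError` on duplicate sunids or unresolvable parents.
    Domains without a FASTA sequence are retained, flagged sequence-less,
    with a recorded warning.
    """
    sequences = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(fasta_text), "fasta")
    }

    root = HierarchyNode(ROOT_SUNID, "", "root", None, "hierarchy root")
    nodes: dict[int, HierarchyNode] = {ROOT_SUNID: root}
    warnings: list[str] = []
    # sccs -> sunid per internal level, for parent resolution
    by_sccs: dict[str, dict[str, int]] = {lv: {} for lv in LEVELS[1:5]}

    rows: list[tuple[int, HierarchyNode]] = []
    for line_no, line in enumerate(des_text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = _split_row(line, line_no, 5, "des")
        try:
            sunid = int(cols[0])
        except ValueError:
            raise ParseError(f"des line {line_no}: non-integer sunid {cols[0]!r}")
        code = cols[1]
        if code not in _LEVEL_CODES:
            raise ParseError(f"des line {line_no}: unknown level code {code!r}")
        level = _LEVEL_CODES[code]
        sccs, identifier, description = cols[2], cols[3], cols[4]
        if sunid in nodes or any(n.sunid == sunid for _, n in rows):
            raise HierarchyError(f"duplicate sunid {sunid} (des line {line_no})")
        node = HierarchyNode(sunid, sccs, level, None, description, identifier)
        rows.append((line_no, node))
        if level in by_sccs:
            by_sccs[level][sccs] = sunid

    for line_no, node in rows:
        if node.level == "class":
            node.parent_sunid = ROOT_SUNID
        elif node.level == "domain":
            parent = by_sccs["family"].get(node.sccs)
            if parent is None:
                warnings.append(
                    f"des line {line_no}: domain {node.sunid} has no family "
                    f"with sccs {node.sccs!r}; attached to root"
                )
                node.parent_sunid = ROOT_SUNID
            else:
                node.parent_sunid = parent
            seq = sequences.get(node.identifier)
            if seq is None:
                warnings.append(
                    f"domain {node.identifier} (sunid {node.sunid}) has no "
                    "sequence in FASTA; retained sequence-less"
                )
            node.sequence = seq
        else:
            parent_level = LEVELS[LEVELS.index(node.level) - 1]
            parent_sccs = ".".join(node.sccs.split(".")[: _SCCS_DEPTH[parent_level]])
            parent = by_sccs[parent_level].get(parent_sccs)
            if parent is None:
                warnings.append(
                    f"des line {line_no}: {node.level} {node.sccs} has no "
                    f"{parent_level} parent {parent_sccs!r}; attached to root"
                )
                node.parent_sunid = ROOT_SUNID
            else:
                node.parent_sunid = parent
        nodes[node.sunid] = node

    # cla rows cross-check the des-derived topology.
    for line_no, line in enumerate(cla_text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = _split_row(line, line_no, 6, "cla")
        try:
            sunid = int(cols[4])
        except ValueError:
            raise ParseError(f"cla line {line_no}: non-integer sunid {cols[4]!r}")
        if sunid not in nodes:
            warnings.append(f"cla line {line_no}: sunid {sunid} not in des table")
            continue
        node = nodes[sunid]
        if node.sccs != cols[3]:
            warnings.append(
                f"cla line {line_no}: sccs {cols[3]!r} disagrees with des "
                f"{node.sccs!r} for sunid {sunid}"
            )
        for part in cols[5].split(","):
            if "=" not in part:
                raise ParseError(f"cla line {line_no}: bad ancestry field {part!r}")
            code, _, value = part.partition("=")
            if code in _LEVEL_CODES and int(value) not in nodes:
                warnings.append(
                    f"cla line {line_no}: ancestry {part} names unknown sunid"
                )

    children: dict[int, list[int]] = {sunid: [] for sunid in nodes}
    for node in nodes.values():
        if node.parent_sunid is not None:
            children[node.parent_sunid].append(node.sunid)
    for kids in children.values():
        kids.sort()

    return Hierarchy(nodes=nodes, root=ROOT_SUNID, children=children,
                     warnings=warnings)


def expand_sunids(h: Hierarchy, seeds: list[int]) -> list[str]:
    """Protein ids of all domain-level descendants of ``seeds``.

    The union is duplicate-free and ordered by ascending domain sunid.
    Unknown seeds raise :class:`HierarchyError` naming the sunid.
    """
    seen: set[int] = set()
    hits: dict[int, str] = {}
    for seed in seeds:
        if seed not in h.nodes:
            raise HierarchyError(f"unknown seed sunid {seed}")
        stack = [seed]
        while stack:
            sunid = stack.pop()
            if sunid in seen:
                continue
            seen.add(sunid)
            node = h.nodes[sunid]
            if node.level == "domain":
                hits[sunid] = node.identifier
            else:
                stack.extend(h.children.get(sunid, ()))
    return [hits[s] for s in sorted(hits)]


def _family_of(h: Hierarchy, sunid: int) -> str:
    """sccs of the family ancestor of a domain node (its own sccs)."""
    return h.nodes[sunid].sccs


def build_metal_reference(
    h: Hierarchy,
    fe_seeds: list[int],
    cu_seeds: list[int],
    exclusions: list[str] | None = None,
) -> MetalReference:
    """Expand Fe and Cu seed sunids into a labeled metal reference.

    Entries whose family sccs appears in ``exclusions`` are removed and the
    exclusion recorded with its removal count; an exclusion matching nothing
    is a warning, not an error.  A protein reachable from both Fe and Cu
    seeds is kept once per metal and flagged ``dual_metal``.
    """
    exclusions = list(exclusions or [])
    domains_by_id = {n.identifier: n for n in h.domains()}

    def expand(seeds: list[int], metal: str) -> list[ReferenceEntry]:
        out = []
        for pid in expand_sunids(h, seeds):
            node = domains_by_id[pid]
            out.append(ReferenceEntry(
                protein_id=pid,
                family_sccs=node.sccs,
                metal=metal,
                sequence=node.sequence or "",
                description=node.description,
            ))
        return out

    fe_entries = expand(fe_seeds, "Fe")
    cu_entries = expand(cu_seeds, "Cu")
    dual = {e.protein_id for e in fe_entries} & {e.protein_id for e in cu_entries}
    entries = fe_entries + cu_entries
    for e in entries:
        if e.protein_id in dual:
            e.dual_metal = True

    warnings = []
    excluded_families: list[tuple[str, str, int]] = []
    for sccs in exclusions:
        n_before = len(entries)
        entries = [e for e in entries if e.family_sccs != sccs]
        n_removed = n_before - len(entries)
        if n_removed == 0:
            warnings.append(f"exclusion {sccs!r} matched no reference entries")
        excluded_families.append((sccs, "configured family exclusion", n_removed))

    for e in entries:
        if e.sequence:
            bad = set(e.sequence) - VALID_AA
            if bad:
                warnings.append(
                    f"{e.protein_id}: nonstandard residues {sorted(bad)} kept as-is"
                )

    return MetalReference(entries=entries, excluded_families=excluded_families,
                          warnings=warnings)


def write_reference_fasta(ref: MetalReference, handle) -> None:
    """Write the reference with ``>protein_id|family_sccs|metal description``."""
    for e in sorted(ref.entries, key=lambda e: (e.metal, e.protein_id)):
        handle.write(f">{e.protein_id}|{e.family_sccs}|{e.metal} {e.description}\n")
        seq = e.sequence
        for i in range(0, len(seq), 60):
            handle.write(seq[i:i + 60] + "\n")


def read_reference_fasta(text: str) -> MetalReference:
    """Inverse of :func:`write_reference_fasta`."""
    entries = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        pid, sccs, metal = rec.id.split("|")
        entries.append(ReferenceEntry(
            protein_id=pid, family_sccs=sccs, metal=metal,
            sequence=str(rec.seq), description=rec.description.partition(" ")[2],
        ))
    return MetalReference(entries=entries)


def write_exclusion_report(ref: MetalReference, handle) -> None:
    handle.write("sccs\treason\tn_removed\n")
    for sccs, reason, n in ref.excluded_families:
        handle.write(f"{sccs}\t{reason}\t{n}\n")


def load_seed_list(text: str) -> list[int]:
    """Seed sunids, one per line, ``#`` comments allowed."""
    seeds = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            seeds.append(int(line))
    return seeds
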