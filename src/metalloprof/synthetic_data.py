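"""Synthetic inputs for every pipeline stage.

Everything here is synthetic and seeded: a small fold-family hierarchy
with Fe and Cu families (including the families that exercise the
pipeline's special rules: multidomain cupredoxins b.6.1.3 with nirK- and
MCO-styled domain descriptions, formate dehydrogenase c.81.1.1, the
aconitase exclusion target c.83.1.1, and cytochrome c oxidase subunit
I-like f.24.1.1), reads drawn from known family mixtures with
substitution errors, a ~40-node NCBI-dialect taxonomy, depth profiles in
which O2 declines to anoxia while dissolved Fe rises sharply at the
oxic–anoxic transition and dissolved Cu stays near-constant
(0.9–1.6 nM), and community matrices tied to a known O2 gradient.

Identical configs (same seed) produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .reference_db import MetalReference, ReferenceEntry
from .search import revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# inverse codon table (standard code), deterministic codon order
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)

# (sccs, metal, family description); descriptions echo the field's naming
DEFAULT_FE_FAMILIES = [
    ("c.81.1.1", "Formate dehydrogenase/DMSO reductase domains 1-3 (Nar/Nxr)"),
    ("c.83.1.1", "Aconitase, Fe regulatory protein"),
    ("f.24.1.1", "Cytochrome c oxidase subunit I-like"),
    ("a.93.1.3", "Catalase-peroxidase KatG"),
    ("d.15.4.2", "2Fe-2S ferredoxin domains"),
    ("f.26.1.1", "Photosystem II reaction centre"),
    ("f.21.1.2", "Cytochrome b of cytochrome bc1 complex"),
    ("a.25.1.2", "Ribonucleotide reductase-like"),
]
DEFAULT_CU_FAMILIES = [
    ("b.6.1.3", "Multidomain cupredoxins"),
    ("b.6.1.2", "Cytochrome c oxidase subunit II-like"),
    ("b.6.1.1", "Plastocyanin/azurin-like"),
    ("b.69.3.1", "Nitrous oxide reductase NosZ"),
    ("b.1.8.1", "Cu,Zn superoxide dismutase"),
]

# domain descriptions cycled within b.6.1.3 so the nirK/MCO split is exercised
_CUPREDOXIN_DESCRIPTIONS = [
    "copper-containing nitrite reductase NirK",
    "multicopper oxidase (laccase)",
    "uncharacterized multidomain cupredoxin",
]


@dataclass
class SimConfig:
    seed: int = 0
    n_fe_families: int = 6
    n_cu_families: int = 4
    domains_per_family: tuple[int, int] = (2, 4)
    protein_length: tuple[int, int] = (120, 240)
    n_reads: int = 2000
    read_length: int = 150
    substitution_rate: float = 0.005
    family_mixture: dict[str, float] | None = None  # None = uniform
    taxon_map: dict[str, int] | None = None
    # depth-profile shape parameters
    o2_surface: float = 220.0       # µM
    o2_noise: float = 0.5           # µM, additive
    dfe_background: float = 0.15    # nM above the transition
    dfe_plateau: float = 1.9        # nM below it
    dfe_transition_depth: float = 90.0
    dfe_noise: float = 0.05
    dcu_range: tuple[float, float] = (0.9, 1.6)  # near-constant dissolved Cu

    def __post_init__(self) -> None:
        if self.family_mixture is not None:
            total = sum(self.family_mixture.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"mixture fractions sum to {total}, not 1")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if min(self.n_fe_families, self.n_cu_families, self.n_reads,
               self.read_length) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class HierarchyFixture:
    cla_text: str
    des_text: str
    fasta_text: str
    truth: pd.DataFrame              # domain_id, sunid, family_sccs, metal, description
    family_sunids: dict[str, int]    # sccs -> family sunid
    fe_seeds: list[int] = field(default_factory=list)
    cu_seeds: list[int] = field(default_factory=list)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def make_hierarchy_fixture(cfg: SimConfig) -> HierarchyFixture:
    """Emit parseable cla/des/FASTA texts for a small Fe/Cu hierarchy."""
    rng = np.random.default_rng(cfg.seed)
    fe = DEFAULT_FE_FAMILIES[: cfg.n_fe_families]
    cu = DEFAULT_CU_FAMILIES[: cfg.n_cu_families]
    if len(fe) < cfg.n_fe_families or len(cu) < cfg.n_cu_families:
        raise ValueError("more families requested than the built-in catalog")

    next_sunid = 1
    des_rows: list[str] = []
    cla_rows: list[str] = []
    fasta: list[str] = []
    truth_rows = []
    internal: dict[tuple[str, str], int] = {}  # (level_code, sccs) -> sunid
    family_sunids: dict[str, int] = {}
    seeds = {"Fe": [], "Cu": []}

    def ensure(level_code: str, sccs: str, description: str) -> int:
        nonlocal next_sunid
        key = (level_code, sccs)
        if key not in internal:
            internal[key] = next_sunid
            des_rows.append(
                f"{next_sunid}\t{level_code}\t{sccs}\t-\t{description}")
            next_sunid += 1
        return internal[key]

    for metal, families in (("Fe", fe), ("Cu", cu)):
        for sccs, fam_desc in families:
            parts = sccs.split(".")
            cl = ensure("cl", parts[0], f"class {parts[0]}")
            cf = ensure("cf", ".".join(parts[:2]), f"fold {'.'.join(parts[:2])}")
            sf = ensure("sf", ".".join(parts[:3]),
                        f"superfamily {'.'.join(parts[:3])}")
            fa = ensure("fa", sccs, fam_desc)
            family_sunids[sccs] = fa
            seeds[metal].append(fa)
            n_dom = int(rng.integers(cfg.domains_per_family[0],
                                     cfg.domains_per_family[1] + 1))
            for k in range(n_dom):
                sunid = next_sunid
                next_sunid += 1
                dom_id = f"d{sunid:06d}"
                length = int(rng.integers(cfg.protein_length[0],
                                          cfg.protein_length[1] + 1))
                seq = _random_protein(rng, length)
                if sccs == "b.6.1.3":
                    desc = _CUPREDOXIN_DESCRIPTIONS[k % len(_CUPREDOXIN_DESCRIPTIONS)]
                else:
                    desc = f"{fam_desc} domain {k + 1}"
                des_rows.append(f"{sunid}\tdm\t{sccs}\t{dom_id}\t{desc}")
                cla_rows.append(
                    f"{dom_id}\tsynth\tA:\t{sccs}\t{sunid}\t"
                    f"cl={cl},cf={cf},sf={sf},fa={fa},dm={sunid}")
                fasta.append(f">{dom_id} {desc}")
                for i in range(0, length, 60):
                    fasta.append(seq[i:i + 60])
                truth_rows.append({
                    "domain_id": dom_id, "sunid": sunid, "family_sccs": sccs,
                    "metal": metal, "description": desc, "sequence": seq,
                })

    header = "# synthetic structural-classification fixture\n"
    return HierarchyFixture(
        cla_text=header + "\n".join(cla_rows) + "\n",
        des_text=header + "\n".join(des_rows) + "\n",
        fasta_text="\n".join(fasta) + "\n",
        truth=pd.DataFrame(truth_rows),
        family_sunids=family_sunids,
        fe_seeds=seeds["Fe"],
        cu_seeds=seeds["Cu"],
    )


def reference_from_fixture(fx: HierarchyFixture,
                           exclude: tuple[str, ...] = ()) -> MetalReference:
    """Truth-table route to a MetalReference (bypasses parsing)."""
    entries = [
        ReferenceEntry(r.domain_id, r.family_sccs, r.metal, r.sequence,
                       r.description)
        for r in fx.truth.itertuples()
        if r.family_sccs not in exclude
    ]
    return MetalReference(entries=entries)


# ---------------------------------------------------------------------------
# Read simulation

def back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform choice among synonymous codons (no organism bias)."""
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide)


def simulate_reads(ref: MetalReference, cfg: SimConfig) \
        -> tuple[str, pd.DataFrame]:
    """FASTQ text plus a truth table of each read's source family/taxon.

    Each read: a family drawn from the mixture, a domain uniformly within
    it, a random in-frame window back-translated with uniform codon
    usage, per-base substitutions at ``cfg.substitution_rate``, a random
    strand, and constant Phred qualities consistent with the rate.
    """
    rng = np.random.default_rng(cfg.seed)
    by_family: dict[str, list[ReferenceEntry]] = {}
    for e in ref.entries:
        by_family.setdefault(e.family_sccs, []).append(e)
    if cfg.family_mixture is None:
        labels = sorted(by_family)
        probs = np.full(len(labels), 1.0 / len(labels))
    else:
        labels = sorted(cfg.family_mixture)
        missing = [l for l in labels if l not in by_family]
        if missing:
            raise ValueError(f"mixture families absent from reference: {missing}")
        probs = np.array([cfg.family_mixture[l] for l in labels])

    window_aa = cfg.read_length // 3 + (cfg.read_length % 3 > 0)
    min_len = min(len(e.sequence) for fam in labels for e in by_family[fam])
    if window_aa > min_len:
        raise ValueError(
            f"read_length {cfg.read_length} nt needs {window_aa} aa windows "
            f"but the shortest mixture protein has {min_len} aa")

    q = 40 if cfg.substitution_rate == 0 else min(
        40, int(round(-10 * math.log10(cfg.substitution_rate))))
    qual_line = chr(q + 33) * cfg.read_length
    bases = np.array(list("ACGT"))

    fastq: list[str] = []
    truth_rows = []
    taxon_map = cfg.taxon_map or {}
    for i in range(cfg.n_reads):
        fam = labels[rng.choice(len(labels), p=probs)]
        entry = by_family[fam][rng.integers(len(by_family[fam]))]
        start = int(rng.integers(0, len(entry.sequence) - window_aa + 1))
        pep = entry.sequence[start:start + window_aa]
        nt = back_translate(pep, rng)[: cfg.read_length]
        if cfg.substitution_rate > 0:
            arr = np.array(list(nt))
            hit = rng.random(len(arr)) < cfg.substitution_rate
            for j in np.nonzero(hit)[0]:
                choices = [b for b in "ACGT" if b != arr[j]]
                arr[j] = choices[rng.integers(3)]
            nt = "".join(arr)
        strand = "+"
        if rng.random() < 0.5:
            nt = revcomp(nt)
            strand = "-"
        rid = f"read{i:06d}"
        fastq += [f"@{rid}", nt, "+", qual_line[: len(nt)]]
        truth_rows.append({
            "read_id": rid, "family_sccs": fam, "metal": entry.metal,
            "domain_id": entry.protein_id, "strand": strand,
            "tax_id": taxon_map.get(fam),
        })
    return "\n".join(fastq) + "\n", pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Geochemical depth profiles

# anchor depths (m) and O2 (µM, scaled to o2_surface/220) spanning all zones
_O2_ANCHORS = np.array([
    (0, 220), (15, 218), (30, 212), (50, 180), (70, 95), (85, 40),
    (100, 6.5), (125, 3.8), (150, 2.5), (200, 2.0), (250, 1.8), (300, 1.8),
    (400, 5.5), (500, 12.0), (700, 25.0), (800, 32.0), (1000, 45.0),
], dtype=float)

DEFAULT_DEPTHS = (15, 25, 30, 50, 70, 85, 100, 125, 200, 250, 300,
                  500, 700, 800, 1000)


def simulate_profiles(cfg: SimConfig,
                      depths: tuple[float, ...] = DEFAULT_DEPTHS) -> pd.DataFrame:
    """Seeded depth profiles spanning all five oxygen zones.

    O2 declines through an oxycline to < 5 µM at core depths and partly
    recovers below; dissolved Fe rises sigmoidally across the
    oxic–anoxic transition from ``dfe_background`` to ``dfe_plateau``;
    dissolved Cu is drawn near-constant within ``dcu_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = np.asarray(depths, float)
    scale = cfg.o2_surface / 220.0
    o2 = np.interp(d, _O2_ANCHORS[:, 0], _O2_ANCHORS[:, 1] * scale)
    o2 = np.clip(o2 + rng.normal(0, cfg.o2_noise, len(d)), 0.05, None)
    dfe = cfg.dfe_background + (cfg.dfe_plateau - cfg.dfe_background) / (
        1.0 + np.exp(-(d - cfg.dfe_transition_depth) / 10.0))
    dfe = np.clip(dfe + rng.normal(0, cfg.dfe_noise, len(d)), 0.02, None)
    dcu = rng.uniform(*cfg.dcu_range, len(d))
    temperature = 4.0 + 21.0 * np.exp(-d / 250.0)
    no3 = 36.0 * (1 - np.exp(-d / 150.0)) - 8.0 * np.exp(-((d - 250.0) / 80.0) ** 2)
    no2 = 5.5 * np.exp(-((d - 250.0) / 70.0) ** 2) + 0.2 * np.exp(-((d - 40) / 25) ** 2)
    po4 = 0.2 + 2.8 * (1 - np.exp(-d / 250.0))
    df = pd.DataFrame({
        "sample_id": [f"P{int(x):04d}m" for x in d],
        "depth": d, "temperature": temperature, "o2": o2,
        "no3": np.clip(no3, 0, None), "no2": np.clip(no2, 0, None),
        "po4": po4, "dfe": dfe, "dcu": dcu,
    })
    from .geochem_stats import annotate_geochem
    return annotate_geochem(df)


# ---------------------------------------------------------------------------
# Community matrices on a known environmental gradient

def simulate_community(cfg: SimConfig, profiles: pd.DataFrame | None = None) \
        -> tuple[pd.DataFrame, pd.DataFrame]:
    """(counts, env): samples x labels counts tied to the O2 gradient.

    The summed Fe labels decrease with O2 (anaerobic metal demand) while
    the cytochrome-c-oxidase-like Cu label increases with O2 (aerobic
    respiration); remaining labels carry seeded noise only.  Counts are
    on a per-100,000 protein-coding scale, so rows can be read directly
    as per-100k inventories or rounded for count-based methods.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if profiles is None:
        profiles = simulate_profiles(cfg)
    o2 = profiles["o2"].to_numpy(float)
    rel = o2 / max(cfg.o2_surface, 1e-9)
    n = len(o2)
    fe_total = 800.0 + 1100.0 * (1 - rel) + rng.normal(0, 80, n)
    cox = 40.0 + 180.0 * rel + rng.normal(0, 15, n)
    # catalytic Fe families only (the aconitase family is excluded upstream)
    fe_labels = ("c.81.1.1", "f.24.1.1", "a.93.1.3", "d.15.4.2")
    fe_split = np.array([0.35, 0.25, 0.2, 0.2])
    data = {
        f"Fe:{lab}": np.clip(fe_total * w * rng.lognormal(0, 0.08, n), 1, None)
        for lab, w in zip(fe_labels, fe_split)
    }
    data["Cu:f.24.1.1"] = np.clip(cox, 1, None)
    data["Cu:b.6.1.1"] = np.clip(rng.normal(60, 10, n), 1, None)
    counts = pd.DataFrame(data, index=profiles["sample_id"]).round().astype(int)
    env = profiles.set_index("sample_id")[
        ["depth", "temperature", "o2", "no3", "no2", "po4", "dfe", "dcu"]]
    return counts, env


# ---------------------------------------------------------------------------
# Tiny NCBI-dialect taxonomy (synthetic)

_PHYLA = [
    ("Proteobacteria", 1224, 2), ("Planctomycetes", 203682, 2),
    ("Bacteroidetes", 976, 2), ("Cyanobacteria", 1117, 2),
    ("Thaumarchaeota", 651137, 2157),
]


def make_taxonomy_fixture() -> tuple[str, str, pd.DataFrame]:
    """Synthetic ~40-node nodes.dmp/names.dmp pair with 5 phyla.

    Ranks run root -> superkingdom -> phylum -> class -> genus ->
    species, two species per genus.  Returns (nodes_text, names_text,
    table) where the table lists every node with its rank and phylum.
    """
    rows = [(1, 1, "no rank", "root"),
            (2, 1, "superkingdom", "Bacteria"),
            (2157, 1, "superkingdom", "Archaea")]
    next_id = 3000
    table = []
    for name, pid, parent in _PHYLA:
        rows.append((pid, parent, "phylum", name))
        cls = next_id; next_id += 1
        rows.append((cls, pid, "class", f"{name} classis"))
        for g in range(2):
            genus = next_id; next_id += 1
            rows.append((genus, cls, "genus", f"{name[:6]}genus{g + 1}"))
            for s in range(2):
                sp = next_id; next_id += 1
                rows.append((sp, genus, "species",
                             f"{name[:6]}genus{g + 1} species{s + 1}"))
                table.append({"tax_id": sp, "rank": "species", "phylum": name})
    nodes_text = "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r, _ in rows)
    names_text = "".join(
        f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, p, r, n in rows)
    for t, p, r, n in rows:
        if r != "species":
            table.append({"tax_id": t, "rank": r,
                          "phylum": n if r == "phylum" else None})
    return nodes_text, names_text, pd.DataFrame(table)


def default_taxon_map(fx: HierarchyFixture, tax_table: pd.DataFrame) \
        -> dict[str, int]:
    """Cu families -> Thaumarchaeota species, Fe families -> Planctomycetes.

    Mirrors the study design used for the metal-vs-bulk taxonomy
    contrast: on synthetic reads, Cu-family reads should roll up to the
    archaeal phylum and Fe-family reads to Planctomycetes.
    """
    species = tax_table[tax_table["rank"] == "species"]
    thaum = species[species["phylum"] == "Thaumarchaeota"]["tax_id"].tolist()
    planc = species[species["phylum"] == "Planctomycetes"]["tax_id"].tolist()
    out = {}
    fams = fx.truth[["family_sccs", "metal"]].drop_duplicates()
    fe_i = cu_i = 0
    for r in fams.itertuples():
        if r.metal == "Cu":
            out[r.family_sccs] = thaum[cu_i % len(thaum)]
            cu_i += 1
        else:
            out[r.family_sccs] = planc[fe_i % len(planc)]
            fe_i += 1
    return out


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
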