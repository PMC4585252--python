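"""Read QC/merging and translated local-alignment search against a metal reference.

The search emulates a translated protein search (BLASTX-style): each
nucleotide read is translated in six frames, low-complexity regions are
masked, and every stop-free peptide segment is aligned locally (affine
gaps, BLOSUM62 by default) against every reference entry.  Raw scores S
are converted to bit scores with the Karlin–Altschul rescaling

    bits = (lambda * S - ln k) / ln 2

and expectation E = m * n * 2^(-bits) over an effective search space of
m query residues by n database residues.  Hits are kept when the bit
score reaches ``bit_cutoff`` (default 50) and the e-value is at most
``evalue_cutoff`` (default 0.1).  Protein ("genome mode") input skips
translation and reports frame 0.

Externally produced 12-column tabular hits can be substituted for the
built-in search via :func:`parse_tabular_hits`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .reference_db import MetalReference, ReferenceEntry


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int] | None = None  # per-base Phred, None for FASTA/protein
    mate: str = "unpaired"              # {"1", "2", "unpaired", "merged"}

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return float("nan")
        return sum(self.qualities) / len(self.qualities)


@dataclass
class SearchParams:
    """Scoring defaults follow gapped BLASTX conventions."""
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11          # cost of opening a gap (first residue costs open+extend)
    gap_extend: int = 1
    lam: float = 0.267          # Karlin-Altschul lambda for these penalties
    k: float = 0.041
    bit_cutoff: float = 50.0
    evalue_cutoff: float = 0.1
    search_space: float | None = None  # db residues; derived from ref if None

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.bit_cutoff < 0:
            raise ValueError("bit_cutoff must be >= 0")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)

    def evalue(self, bit_score: float, query_len: int, db_residues: float) -> float:
        m = max(query_len, 1)
        n = self.search_space if self.search_space is not None else db_residues
        return m * n * 2.0 ** (-bit_score)


@dataclass
class SearchHit:
    query_id: str
    subject_id: str
    family_sccs: str
    metal: str
    raw_score: float
    bit_score: float
    evalue: float
    pct_identity: float
    q_start: int   # 1-based inclusive, on the translated peptide
    q_end: int
    s_start: int
    s_end: int
    frame: int     # -3..-1, +1..+3; 0 for protein input
    subject_description: str = ""
    aln_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    subject_tax_id: int | None = None


# ---------------------------------------------------------------------------
# FASTQ/FASTA I/O

def read_fastq(handle_or_text, mate: str = "unpaired") -> Iterator[ReadRecord]:
    """Parse FASTQ into ReadRecords (Phred+33 via Biopython)."""
    from Bio import SeqIO
    handle = io.StringIO(handle_or_text) if isinstance(handle_or_text, str) \
        else handle_or_text
    for rec in SeqIO.parse(handle, "fastq"):
        yield ReadRecord(rec.id, str(rec.seq).upper(),
                         list(rec.letter_annotations["phred_quality"]), mate)


def read_fasta_records(handle_or_text) -> Iterator[ReadRecord]:
    from Bio import SeqIO
    handle = io.StringIO(handle_or_text) if isinstance(handle_or_text, str) \
        else handle_or_text
    for rec in SeqIO.parse(handle, "fasta"):
        yield ReadRecord(rec.id, str(rec.seq).upper(), None, "unpaired")


# ---------------------------------------------------------------------------
# Quality filtering and pair merging

@dataclass
class MergeStats:
    pairs_in: int = 0
    dropped_quality: int = 0
    merged: int = 0
    unmerged: int = 0
    notes: list[str] = field(default_factory=list)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def quality_filter_merge(
    r1: Iterable[ReadRecord],
    r2: Iterable[ReadRecord] | None,
    phred_min: float = 25.0,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[list[ReadRecord], MergeStats]:
    """Drop low-mean-quality pairs and merge overlapping mates.

    A pair survives when both mates have mean Phred >= ``phred_min``.
    Mate 2 is reverse-complemented and the 3' overlap with mate 1 is
    scanned from longest to shortest; the first overlap of length >=
    ``min_overlap`` with a mismatch fraction <= ``max_mismatch_frac``
    merges the pair with the higher-quality base winning at conflicts.
    Single-end input (``r2 is None``) bypasses merging with a note.
    """
    stats = MergeStats()
    if r2 is None:
        out = []
        for rec in r1:
            stats.pairs_in += 1
            if rec.qualities and rec.mean_quality < phred_min:
                stats.dropped_quality += 1
                continue
            out.append(rec)
        stats.unmerged = 0
        stats.notes.append("single-end input: merging bypassed")
        stats.merged = len(out)
        return out, stats

    merged: list[ReadRecord] = []
    it2 = iter(r2)
    for a in r1:
        try:
            b = next(it2)
        except StopIteration:
            raise ValueError("mate streams have unequal length") from None
        if _pair_stem(a.read_id) != _pair_stem(b.read_id):
            raise ValueError(f"mate order mismatch: {a.read_id} vs {b.read_id}")
        stats.pairs_in += 1
        if (a.qualities and a.mean_quality < phred_min) or \
           (b.qualities and b.mean_quality < phred_min):
            stats.dropped_quality += 1
            continue
        rec = _merge_pair(a, b, min_overlap, max_mismatch_frac)
        if rec is None:
            stats.unmerged += 1
        else:
            stats.merged += 1
            merged.append(rec)
    if next(it2, None) is not None:
        raise ValueError("mate streams have unequal length")
    return merged, stats


def _pair_stem(read_id: str) -> str:
    for sep in ("/", " "):
        if sep in read_id:
            read_id = read_id.split(sep)[0]
    return read_id


def _merge_pair(a: ReadRecord, b: ReadRecord, min_overlap: int,
                max_mismatch_frac: float) -> ReadRecord | None:
    s2 = revcomp(b.sequence)
    q2 = list(reversed(b.qualities)) if b.qualities else None
    s1, q1 = a.sequence, a.qualities
    best = None
    for ov in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        tail, head = s1[-ov:], s2[:ov]
        mism = sum(x != y for x, y in zip(tail, head))
        if mism <= max_mismatch_frac * ov:
            best = (ov, mism)
            break
    if best is None:
        return None
    ov, _ = best
    off = len(s1) - ov
    seq = list(s1[:off])
    qual = list(q1[:off]) if q1 else None
    for i in range(ov):
        b1, b2 = s1[off + i], s2[i]
        p1 = q1[off + i] if q1 else 0
        p2 = q2[i] if q2 else 0
        if b1 == b2:
            seq.append(b1)
            if qual is not None:
                qual.append(max(p1, p2))
        else:
            seq.append(b1 if p1 >= p2 else b2)
            if qual is not None:
                qual.append(abs(p1 - p2))
    seq += list(s2[ov:])
    if qual is not None:
        qual += list(q2[ov:]) if q2 else [0] * (len(s2) - ov)
    return ReadRecord(_pair_stem(a.read_id), "".join(seq), qual, "merged")


# ---------------------------------------------------------------------------
# Translation

_STANDARD = None


def translate_six_frames(seq: str) -> list[str]:
    """Translate all six frames: +1..+3 forward, -1..-3 on the reverse complement.

    Codons containing N translate to X; stops render as ``*``.  An empty
    sequence yields six empty strings.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    frames = []
    rc = revcomp(seq)
    for strand_seq in (seq, rc):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()))
    return frames


def frame_labels() -> list[int]:
    return [1, 2, 3, -1, -2, -3]


# ---------------------------------------------------------------------------
# Local alignment

@dataclass
class AlignmentResult:
    raw_score: float
    bit_score: float
    q_start: int  # 1-based inclusive; 0 when the optimal alignment is empty
    q_end: int
    s_start: int
    s_end: int
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int


_aligner_cache: dict[tuple, PairwiseAligner] = {}


def _get_aligner(p: SearchParams) -> PairwiseAligner:
    key = (p.substitution_matrix, p.gap_open, p.gap_extend)
    aligner = _aligner_cache.get(key)
    if aligner is None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(
            p.substitution_matrix)
        # gap of length L costs gap_open + L * gap_extend
        aligner.open_gap_score = -(p.gap_open + p.gap_extend)
        aligner.extend_gap_score = -p.gap_extend
        _aligner_cache[key] = aligner
    return aligner


def local_score(query_pep: str, subject: str, p: SearchParams) -> float:
    """Optimal local alignment raw score (0 when nothing scores positive)."""
    if not query_pep or not subject:
        return 0.0
    return float(_get_aligner(p).score(query_pep, subject))


def align_local(query_pep: str, subject: str, p: SearchParams) -> AlignmentResult:
    """Optimal affine-gap local alignment with coordinates and identity.

    Score 0 (empty alignment) is allowed and reported with zeroed
    coordinates.  Ties in the traceback are resolved deterministically by
    the aligner; the score is unique regardless.
    """
    if not query_pep or not subject:
        return AlignmentResult(0.0, p.bit_score(0.0), 0, 0, 0, 0, 0.0, 0, 0, 0)
    aligner = _get_aligner(p)
    score = float(aligner.score(query_pep, subject))
    if score <= 0:
        return AlignmentResult(0.0, p.bit_score(0.0), 0, 0, 0, 0, 0.0, 0, 0, 0)
    aln = aligner.align(query_pep, subject)[0]
    qa, sa = aln.aligned
    q_start, q_end = int(qa[0][0]) + 1, int(qa[-1][1])
    s_start, s_end = int(sa[0][0]) + 1, int(sa[-1][1])
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        for i in range(qe - qs):
            aligned_cols += 1
            if query_pep[qs + i] == subject[ss + i]:
                matches += 1
    gap_opens = len(qa) - 1
    gap_cols = (q_end - q_start + 1) - aligned_cols + \
               (s_end - s_start + 1) - aligned_cols
    aln_length = aligned_cols + gap_cols
    pct = 100.0 * matches / aln_length if aln_length else 0.0
    return AlignmentResult(score, p.bit_score(score), q_start, q_end,
                           s_start, s_end, pct, aln_length,
                           aligned_cols - matches, gap_opens)


# ---------------------------------------------------------------------------
# Low-complexity masking (DUST-style approximation of a min-complexity filter)

def dust_mask(seq: str, window: int = 64, threshold: float = 2.0) -> str:
    """Mask low-complexity nucleotide windows with N.

    Score of a window is sum over triplet counts c of c*(c-1)/2, divided
    by (w - 2); windows scoring above ``threshold`` are masked.  This is a
    deliberately simple stand-in for a read-complexity pre-filter.
    """
    n = len(seq)
    if n < 6:
        return seq
    masked = list(seq)
    step = max(window // 2, 1)
    for start in range(0, n, step):
        sub = seq[start:start + window]
        if len(sub) < 6:
            break
        counts: dict[str, int] = {}
        for i in range(len(sub) - 2):
            t = sub[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = sum(c * (c - 1) / 2 for c in counts.values()) / (len(sub) - 2)
        if score > threshold:
            for i in range(start, min(start + window, n)):
                masked[i] = "N"
    return "".join(masked)


# ---------------------------------------------------------------------------
# The search itself

def _segments(peptide: str) -> Iterator[tuple[int, str]]:
    """Stop-free segments of a translated frame with their 0-based offsets."""
    start = 0
    for i, ch in enumerate(peptide):
        if ch == "*":
            if i > start:
                yield start, peptide[start:i]
            start = i + 1
    if len(peptide) > start:
        yield start, peptide[start:]


def search_reads(
    reads: Iterable[ReadRecord],
    ref: MetalReference,
    p: SearchParams | None = None,
    protein_input: bool = False,
    mask_low_complexity: bool = True,
    prefilter_kmer: int | None = 4,
) -> Iterator[SearchHit]:
    """Translated (or protein-mode) local search of reads against the reference.

    Every read is compared with every reference entry; all entries whose
    best segment alignment passes both the bit-score and e-value cutoffs
    yield a hit, so downstream fractional top-hit assignment sees ties.

    ``prefilter_kmer`` enables a shared-k-mer prescreen (seed-and-extend
    style): entries sharing no exact peptide k-mer with any query segment
    are not aligned.  Any alignment long enough to clear a 50-bit cutoff
    shares k-mers with overwhelming probability, so this is an
    accelerator, not a change of contract; pass ``None`` to disable.
    """
    p = p or SearchParams()
    if not ref.entries:
        raise ValueError("reference is empty")
    db_residues = ref.total_residues()
    # segments too short to reach the raw score behind bit_cutoff even as
    # perfect matches of the matrix's best diagonal cannot yield a hit
    matrix = substitution_matrices.load(p.substitution_matrix)
    max_diag = max(matrix[a, a] for a in "ACDEFGHIKLMNPQRSTVWY")
    raw_min = (p.bit_cutoff * math.log(2.0) + math.log(p.k)) / p.lam
    min_seg = max(5, math.ceil(max(raw_min, 0.0) / max_diag))

    def kmers(s: str) -> set[str]:
        k = prefilter_kmer
        return {s[i:i + k] for i in range(len(s) - k + 1)} if k else set()

    entry_kmers = {e.protein_id: kmers(e.sequence) for e in ref.entries} \
        if prefilter_kmer else {}
    for read in reads:
        if protein_input:
            peptides = [(0, 0, read.sequence.upper())]
            qlen = len(read.sequence)
        else:
            seq = dust_mask(read.sequence) if mask_low_complexity else read.sequence
            peptides = []
            for frame, pep in zip(frame_labels(), translate_six_frames(seq)):
                for off, seg in _segments(pep):
                    peptides.append((frame, off, seg))
            qlen = len(read.sequence) // 3
        peptides = [(f, o, s) for f, o, s in peptides if len(s) >= min_seg]
        if prefilter_kmer:
            query_kmers: set[str] = set()
            for _, _, seg in peptides:
                query_kmers |= kmers(seg)
        for entry in ref.entries:
            if not entry.sequence:
                continue
            if prefilter_kmer and query_kmers.isdisjoint(
                    entry_kmers[entry.protein_id]):
                continue
            best: tuple[float, int, int, str] | None = None
            for frame, off, seg in peptides:
                score = local_score(seg, entry.sequence, p)
                if best is None or score > best[0]:
                    best = (score, frame, off, seg)
            if best is None:
                continue
            score, frame, off, seg = best
            bits = p.bit_score(score)
            if bits < p.bit_cutoff:
                continue
            ev = p.evalue(bits, qlen, db_residues)
            if ev > p.evalue_cutoff:
                continue
            aln = align_local(seg, entry.sequence, p)
            yield SearchHit(
                query_id=read.read_id,
                subject_id=entry.protein_id,
                family_sccs=entry.family_sccs,
                metal=entry.metal,
                raw_score=aln.raw_score,
                bit_score=aln.bit_score,
                evalue=ev,
                pct_identity=aln.pct_identity,
                q_start=aln.q_start + off,
                q_end=aln.q_end + off,
                s_start=aln.s_start,
                s_end=aln.s_end,
                frame=0 if protein_input else frame,
                subject_description=entry.description,
                aln_length=aln.aln_length,
                mismatches=aln.mismatches,
                gap_opens=aln.gap_opens,
            )


# ---------------------------------------------------------------------------
# Tabular hit I/O (12-column dialect, plus family/metal columns on output)

TABULAR_COLUMNS = ("qseqid sseqid pident length mismatch gapopen "
                   "qstart qend sstart send evalue bitscore").split()


def parse_tabular_hits(text: str, ref: MetalReference) \
        -> tuple[list[SearchHit], int]:
    """Parse 12-column tabular alignments, joining subjects to the reference.

    Returns ``(hits, n_unknown)`` where rows whose subject is absent from
    the reference are dropped and counted in ``n_unknown``.
    """
    by_id: dict[str, ReferenceEntry] = {}
    for e in ref.entries:
        by_id.setdefault(e.protein_id, e)
    hits: list[SearchHit] = []
    unknown = 0
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise ValueError(
                f"tabular line {line_no}: expected 12 columns, got {len(cols)}")
        entry = by_id.get(cols[1])
        if entry is None:
            unknown += 1
            continue
        bits = float(cols[11])
        hits.append(SearchHit(
            query_id=cols[0], subject_id=cols[1],
            family_sccs=entry.family_sccs, metal=entry.metal,
            raw_score=float("nan"), bit_score=bits, evalue=float(cols[10]),
            pct_identity=float(cols[2]),
            q_start=int(cols[6]), q_end=int(cols[7]),
            s_start=int(cols[8]), s_end=int(cols[9]),
            frame=0, subject_description=entry.description,
            aln_length=int(cols[3]), mismatches=int(cols[4]),
            gap_opens=int(cols[5]),
        ))
    return hits, unknown


def write_tabular_hits(hits: Iterable[SearchHit], handle) -> None:
    """12-column tabular dialect plus family_sccs and metal columns."""
    for h in hits:
        handle.write("\t".join(str(x) for x in (
            h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_length,
            h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end,
            f"{h.evalue:.3g}", f"{h.bit_score:.1f}", h.family_sccs, h.metal,
        )) + "\n")
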