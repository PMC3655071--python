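"""Conserved-ortholog completeness scoring for de novo assemblies.

The completeness question: of a set of conserved single-copy gene clusters
(KOG/CEGMA-style — one cluster per gene, one reference protein per
species), how many can be *detected* in an assembly by translated local
alignment, and for how many can a *full-length* protein be extracted?

The scorer mirrors a tblastn-based protocol:

1. every cluster member protein is aligned (Smith–Waterman, BLOSUM62,
   affine gaps, all six contig frames) against the assembly; alignments
   are gated by a Karlin–Altschul E-value at 1e-6;
2. for the best alignments, the hit region is extended to the enclosing
   open reading frame; a coding sequence is kept only if both a start
   (ATG) and a stop codon are found;
3. the best-scoring alignment with an extractable CDS wins, and its
   protein is classified by length against the cluster's size range.

The size range is ratio-extended beyond the observed member lengths: with
S1 <= S2 the two shortest member lengths and L1 >= L2 the two largest,
the bounds are floor(S1*(S1/S2)) and ceil(L1*(L1/L2)) — allowing for
proteins that could become the new shortest or longest member (shortest 80
and second-shortest 100 give a lower bound of 64 residues).

Extracted proteins fall in exactly one of five length classes:

1. ``WITHIN_RANGE`` — inside the bounds, alignment covers >= 90% of the
   protein (only this class counts as full-length);
2. ``WITHIN_RANGE_SHORT_ALIGN`` — inside the bounds but alignment < 90%;
3. ``TOO_LONG`` — above the upper bound;
4. ``TOO_SHORT`` — below the lower bound but at least as long as the
   alignment;
5. ``SHORTER_THAN_ALIGNMENT`` — below the lower bound and shorter than
   the alignment, typically a stop codon bridged by the alignment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

# Karlin–Altschul constants for gapped BLOSUM62 (gap open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041
DEFAULT_EVALUE = 1e-6

STOP = "*"


# ---------------------------------------------------------------------------
# reference clusters and size bounds


def size_bounds(member_lengths: Sequence[int]) -> tuple[int, int]:
    """Ratio-extended full-length size range from member protein lengths.

    lower = floor(S1 * S1/S2) for the two shortest lengths S1 <= S2;
    upper = ceil(L1 * L1/L2) for the two largest L1 >= L2. The extension
    accounts for proteins that could become the new extreme member.
    """
    if len(member_lengths) < 2:
        raise ValueError("need at least 2 member lengths")
    ordered = sorted(member_lengths)
    s1, s2 = ordered[0], ordered[1]
    l1, l2 = ordered[-1], ordered[-2]
    lower = math.floor(s1 * (s1 / s2))
    upper = math.ceil(l1 * (l1 / l2))
    return lower, upper


@dataclass
class OrthologCluster:
    """One conserved gene: reference proteins keyed by species, plus bounds."""

    cluster_id: str
    members: dict[str, str]
    lower_bound_aa: int
    upper_bound_aa: int

    @classmethod
    def from_members(cls, cluster_id: str, members: Mapping[str, str]) -> "OrthologCluster":
        if len(members) < 2:
            raise ValueError(f"cluster {cluster_id}: need >= 2 members")
        lower, upper = size_bounds([len(p) for p in members.values()])
        return cls(cluster_id, dict(members), lower, upper)


def read_cluster_fasta(records: Iterable[tuple[str, str]]) -> list[OrthologCluster]:
    """Group ``>clusterID|species`` protein records into clusters."""
    grouped: dict[str, dict[str, str]] = {}
    for name, seq in records:
        cid, _, species = name.partition("|")
        grouped.setdefault(cid, {})[species or f"m{len(grouped.get(cid, {}))}"] = seq
    return [OrthologCluster.from_members(cid, members)
            for cid, members in grouped.items()]


# ---------------------------------------------------------------------------
# translated search


def six_frame_translate(sequence: str) -> list[tuple[int, str]]:
    """Translate all six frames; stops appear as ``*``.

    Returns ``(frame, peptide)`` with frames +1,+2,+3 on the given strand
    and -1,-2,-3 on the reverse complement; trailing partial codons are
    dropped.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    rc = str(Seq(sequence).reverse_complement())
    for strand_label, strand_seq in ((1, sequence), (-1, rc)):
        for off in range(3):
            usable = (len(strand_seq) - off) // 3 * 3
            if usable == 0:
                out.append((strand_label * (off + 1), ""))
                continue
            pep = str(Seq(strand_seq[off:off + usable]).translate())
            out.append((strand_label * (off + 1), pep))
    return out


@dataclass
class TranslatedAlignment:
    """One protein-vs-translated-contig local alignment.

    ``subject_span_nt`` is in 0-based half-open coordinates on the strand
    being translated (the contig itself for + frames, its reverse
    complement for - frames).
    """

    cluster_id: str
    contig_id: str
    species: str
    frame: int
    score: float
    evalue: float
    query_span_aa: tuple[int, int]
    subject_span_nt: tuple[int, int]
    aligned_length_aa: int
    percent_identity: float


def make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0   # gap of length L costs 11 + L
    aligner.extend_gap_score = -1.0
    return aligner


def evalue_from_score(score: float, query_len: int, search_space_aa: int) -> float:
    """Karlin–Altschul expectation E = K * m * n * exp(-lambda * S)."""
    return KA_K * query_len * search_space_aa * math.exp(-KA_LAMBDA * score)


def _word_set(seq: str, word_size: int) -> set[str]:
    return {seq[i:i + word_size] for i in range(len(seq) - word_size + 1)}


def translated_search(
    cluster: OrthologCluster,
    contigs: Mapping[str, str],
    evalue_cutoff: float = DEFAULT_EVALUE,
    word_size: int = 4,
    min_words: int = 2,
    aligner: Optional[PairwiseAligner] = None,
) -> list[TranslatedAlignment]:
    """Align every cluster member against all six frames of every contig.

    A BLAST-like exact-word prefilter (``min_words`` shared ``word_size``-mers
    between query and frame) skips hopeless frame/query combinations;
    ``word_size=0`` disables it and the search is exhaustive. Alignments
    with E-value <= cutoff are returned sorted by descending score (ties:
    higher identity, longer alignment, contig id).
    """
    if not contigs:
        raise ValueError("no contigs to search")
    if aligner is None:
        aligner = make_aligner()

    frames: list[tuple[str, int, str]] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        if len(seq) < 3:
            continue
        for frame, pep in six_frame_translate(seq):
            if pep:
                frames.append((cid, frame, pep))
    search_space = sum(len(p) for _, _, p in frames)
    frame_words = ([_word_set(p, word_size) for _, _, p in frames]
                   if word_size else None)

    hits: list[TranslatedAlignment] = []
    for species in sorted(cluster.members):
        query = cluster.members[species]
        qwords = _word_set(query, word_size) if word_size else None
        for idx, (cid, frame, pep) in enumerate(frames):
            if len(pep) < 1:
                continue
            if qwords is not None and len(qwords & frame_words[idx]) < min_words:
                continue
            score = aligner.score(query, pep)
            if score <= 0:
                continue
            ev = evalue_from_score(score, len(query), search_space)
            if ev > evalue_cutoff:
                continue
            aln = aligner.align(query, pep)[0]
            qblocks, sblocks = aln.aligned
            qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
            sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
            counts = aln.counts()
            ncols = counts.identities + counts.mismatches + counts.internal_gaps
            pid = 100.0 * counts.identities / ncols if ncols else 0.0
            off = abs(frame) - 1
            hits.append(TranslatedAlignment(
                cluster_id=cluster.cluster_id, contig_id=cid, species=species,
                frame=frame, score=float(score), evalue=ev,
                query_span_aa=(qstart, qend),
                subject_span_nt=(off + 3 * sstart, off + 3 * send),
                aligned_length_aa=qend - qstart,
                percent_identity=pid,
            ))
    hits.sort(key=_alignment_rank)
    return hits


def _alignment_rank(a: TranslatedAlignment):
    return (-a.score, -a.percent_identity, -a.aligned_length_aa, a.contig_id)


# ---------------------------------------------------------------------------
# CDS extraction and classification


def extract_cds(contig_seq: str, alignment: TranslatedAlignment) -> Optional[str]:
    """Extend a hit to its enclosing ORF; require both start and stop codons.

    On the aligned strand/frame, scan 5' from the alignment start for the
    nearest in-frame ATG, stopping (and failing) at an in-frame stop codon
    or the contig edge; then translate from that ATG to the first in-frame
    stop codon. Returns the protein (Met..stop-exclusive), or ``None`` if
    either terminus is missing. The first stop may lie inside the aligned
    span, in which case the protein is shorter than the alignment.
    """
    strand = (contig_seq if alignment.frame > 0
              else str(Seq(contig_seq).reverse_complement()))
    span_start, _ = alignment.subject_span_nt

    start_nt = None
    pos = span_start
    while pos >= 0:
        codon = strand[pos:pos + 3]
        if codon == "ATG":
            start_nt = pos
            break
        if codon in ("TAA", "TAG", "TGA"):
            return None
        pos -= 3
    if start_nt is None:
        return None

    pos = start_nt
    while pos + 3 <= len(strand):
        codon = strand[pos:pos + 3]
        if codon in ("TAA", "TAG", "TGA"):
            cds = strand[start_nt:pos]
            return str(Seq(cds).translate()) if cds else None
        pos += 3
    return None


class SizeClass(enum.Enum):
    WITHIN_RANGE = 1
    WITHIN_RANGE_SHORT_ALIGN = 2
    TOO_LONG = 3
    TOO_SHORT = 4
    SHORTER_THAN_ALIGNMENT = 5


def classify_length(protein_len_aa: int, aligned_length_aa: int,
                    bounds: tuple[int, int]) -> SizeClass:
    """Assign exactly one of the five length classes (see module docstring)."""
    if protein_len_aa <= 0:
        raise ValueError("protein length must be positive")
    lower, upper = bounds
    if protein_len_aa > upper:
        return SizeClass.TOO_LONG
    if protein_len_aa < lower:
        if protein_len_aa < aligned_length_aa:
            return SizeClass.SHORTER_THAN_ALIGNMENT
        return SizeClass.TOO_SHORT
    if aligned_length_aa >= 0.9 * protein_len_aa:
        return SizeClass.WITHIN_RANGE
    return SizeClass.WITHIN_RANGE_SHORT_ALIGN


def select_best(
    candidates: Sequence[tuple[TranslatedAlignment, str]],
) -> tuple[TranslatedAlignment, str]:
    """Best alignment-with-CDS: highest score, then identity, aligned
    length, and lexicographic contig id."""
    if not candidates:
        raise ValueError("no candidates")
    return min(candidates, key=lambda c: _alignment_rank(c[0]))


@dataclass
class KogHitRecord:
    """Per-cluster scoring result for one assembly."""

    cluster_id: str
    detected: bool
    protein: Optional[str] = None
    size_class: Optional[SizeClass] = None
    best_alignment: Optional[TranslatedAlignment] = None
    canonical_match: Optional[dict] = None

    @property
    def full_length(self) -> bool:
        return self.size_class is SizeClass.WITHIN_RANGE

    @property
    def within_length(self) -> bool:
        return self.size_class in (SizeClass.WITHIN_RANGE,
                                   SizeClass.WITHIN_RANGE_SHORT_ALIGN)


@dataclass
class CompletenessSummary:
    n_clusters: int
    n_detected: int
    n_within_length: int
    n_full_length: int


def score_assembly(
    contigs: Mapping[str, str],
    clusters: Sequence[OrthologCluster],
    evalue_cutoff: float = DEFAULT_EVALUE,
    canonical_proteins: Optional[Mapping[str, str]] = None,
    word_size: int = 4,
    min_words: int = 2,
) -> tuple[list[KogHitRecord], CompletenessSummary]:
    """Score one assembly against every reference cluster.

    A cluster is *detected* if any member alignment passes the E-value
    gate. Among passing alignments (best first) the first with an
    extractable CDS supplies the cluster's protein, which is classified
    against the cluster's size bounds.
    """
    aligner = make_aligner()
    records: list[KogHitRecord] = []
    for cluster in clusters:
        if not contigs:
            records.append(KogHitRecord(cluster.cluster_id, detected=False))
            continue
        alignments = translated_search(cluster, contigs, evalue_cutoff,
                                       word_size=word_size, min_words=min_words,
                                       aligner=aligner)
        rec = KogHitRecord(cluster.cluster_id, detected=bool(alignments))
        for aln in alignments:  # sorted best-first: first extractable wins
            protein = extract_cds(contigs[aln.contig_id], aln)
            if protein:
                rec.protein = protein
                rec.best_alignment = aln
                rec.size_class = classify_length(
                    len(protein), aln.aligned_length_aa,
                    (cluster.lower_bound_aa, cluster.upper_bound_aa))
                break
        if rec.protein and canonical_proteins:
            rec.canonical_match = compare_canonical(rec.protein, canonical_proteins)
        records.append(rec)
    summary = CompletenessSummary(
        n_clusters=len(clusters),
        n_detected=sum(r.detected for r in records),
        n_within_length=sum(r.within_length for r in records),
        n_full_length=sum(r.full_length for r in records),
    )
    return records, summary


def compare_canonical(protein: str, canonical_proteins: Mapping[str, str]) -> dict:
    """Global edit distance to the nearest canonical protein.

    ``identical`` requires zero mismatches and equal length (i.e. edit
    distance 0 to some canonical sequence).
    """
    if not canonical_proteins:
        raise ValueError("canonical protein set is empty")
    best_id, best_dist = None, None
    for name in sorted(canonical_proteins):
        dist = edlib.align(protein, canonical_proteins[name], task="distance")["editDistance"]
        if best_dist is None or dist < best_dist:
            best_id, best_dist = name, dist
    return {"identical": best_dist == 0, "n_mismatches": int(best_dist),
            "best_match": best_id}


def saturation_table(
    rows: Sequence[tuple[int, "Assembly"]],
    clusters: Sequence[OrthologCluster],
    evalue_cutoff: float = DEFAULT_EVALUE,
    canonical_proteins: Optional[Mapping[str, str]] = None,
) -> "pd.DataFrame":
    """Combine assembly metrics and completeness counts across a depth ladder.

    One row per ``(depth, assembly)`` pair, depths ascending; columns are
    the :class:`~depthsat.assembly_metrics.MetricsRow` fields plus
    ``n_detected``, ``n_within_length`` and ``n_full_length``.
    """
    import pandas as pd

    from .assembly_metrics import summarize

    depths = [d for d, _ in rows]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly ascending")
    table = []
    for depth, assembly in rows:
        metrics = summarize(assembly, depth).as_dict()
        _, summary = score_assembly(assembly.contig_map(), clusters,
                                    evalue_cutoff,
                                    canonical_proteins=canonical_proteins)
        metrics.update(n_detected=summary.n_detected,
                       n_within_length=summary.n_within_length,
                       n_full_length=summary.n_full_length)
        table.append(metrics)
    return pd.DataFrame(table)
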