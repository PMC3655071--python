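"""Ground-truth simulator for depth-saturation experiments.

Emulates the statistical structure the downstream analysis assumes:

* a transcriptome whose expression levels span several orders of magnitude
  (log-uniform by default);
* conserved-ortholog reference clusters whose member protein lengths vary
  on average ~11.8% from longest to shortest, diverged by i.i.d. per-site
  amino-acid substitution with terminal truncation/extension only;
* paired-end reads (default 2x100 bp, insert 180+/-20) with per-base
  substitution errors, plus three planted artifact classes — adapter
  read-through, polyT-tract reads, and low-quality reads — each recorded in
  a ground-truth ledger so filter recall can be measured exactly.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .io_formats import ReadPair, ReadRecord
from .kog_completeness import OrthologCluster
from .sequtils import reverse_complement

# Illumina TruSeq read-1 adapter (configurable everywhere it is used).
TRUSEQ_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# amino acid -> list of codons, from the standard genetic code
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()
STOP_CODONS = sorted(standard_dna_table.stop_codons)

# Baseline quality model: Normal(38, 2); planted low-quality reads use
# Normal(20, 3). Both clamped to [2, 41]; the two modes straddle the
# mean-Phred-28 filtering threshold by many standard errors.
GOOD_QUAL_MEAN, GOOD_QUAL_SD = 38.0, 2.0
LOWQ_QUAL_MEAN, LOWQ_QUAL_SD = 20.0, 3.0


@dataclass
class SyntheticTranscript:
    """One simulated transcript; optionally carries a conserved gene's CDS."""

    id: str
    sequence: str
    expression_weight: float
    gc_target: float
    kog_cluster_id: Optional[str] = None
    cds_interval: Optional[tuple[int, int, str]] = None  # 0-based half-open, strand

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated read library."""

    transcripts: list[SyntheticTranscript]
    read_provenance: dict[str, str]            # read id -> source transcript id
    read_category: dict[str, str]              # read id -> clean|adapter|polyt|lowq
    read_start: dict[str, int]                 # read id -> 0-based start on transcript
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "params": self.params,
            "transcripts": [
                {
                    "id": t.id, "length": len(t.sequence),
                    "expression_weight": t.expression_weight,
                    "gc_target": t.gc_target,
                    "kog_cluster_id": t.kog_cluster_id,
                    "cds_interval": t.cds_interval,
                }
                for t in self.transcripts
            ],
            "read_provenance": self.read_provenance,
            "read_category": self.read_category,
            "read_start": self.read_start,
        }
        return json.dumps(payload, indent=1)


def _random_seq_with_gc(length: int, gc_target: float, rng: random.Random) -> str:
    """Sequence with realized GC within half a base of ``gc_target``."""
    n_gc = round(gc_target * length)
    bases = [rng.choice("GC") for _ in range(n_gc)]
    bases += [rng.choice("AT") for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


def gen_transcriptome(
    n_genes: int,
    length_dist: tuple[int, int] = (400, 800),
    gc_dist: tuple[float, float] = (0.45, 0.05),
    seed: int = 0,
) -> list[SyntheticTranscript]:
    """Random transcripts with per-transcript GC targets.

    Lengths are uniform over ``length_dist`` (inclusive); GC targets are
    Normal(mean, sd) clipped to [0.05, 0.95]. Realized GC equals the target
    to within half a base because the GC base count is fixed, not sampled.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_dist
    if lo < 3 or hi < lo:
        raise ValueError(f"bad length range ({lo}, {hi})")
    gc_mean, gc_sd = gc_dist
    if not 0.0 <= gc_mean <= 1.0:
        raise ValueError(f"infeasible GC target mean {gc_mean}")
    rng = random.Random(seed)
    out = []
    for i in range(n_genes):
        length = rng.randint(lo, hi)
        gc = min(0.95, max(0.05, rng.gauss(gc_mean, gc_sd)))
        out.append(SyntheticTranscript(
            id=f"tx{i:04d}",
            sequence=_random_seq_with_gc(length, gc, rng),
            expression_weight=1.0 / n_genes,
            gc_target=gc,
        ))
    return out


def gen_expression(n: int, orders_of_magnitude: float, seed: int = 0) -> list[float]:
    """Relative abundances spanning the requested dynamic range.

    Log-uniform: log10-weights are uniform on [0, orders]; the two endpoints
    are pinned so the realized log10(max/min) equals ``orders_of_magnitude``
    exactly before normalization. Weights are shuffled and sum to 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if orders_of_magnitude < 0:
        raise ValueError("orders_of_magnitude must be >= 0")
    rng = random.Random(seed)
    if n == 1:
        return [1.0]
    exponents = [0.0, float(orders_of_magnitude)]
    exponents += [rng.uniform(0.0, orders_of_magnitude) for _ in range(n - 2)]
    rng.shuffle(exponents)
    weights = [10.0 ** e for e in exponents]
    total = sum(weights)
    return [w / total for w in weights]


def _mutate_protein(protein: str, substitution_rate: float,
                    length_jitter: float, rng: random.Random) -> str:
    """Derive a lineage from an ancestral protein.

    Per-site i.i.d. substitution to a uniformly chosen different residue;
    length jitter as C-terminal truncation/extension by a uniform factor in
    [1 - jitter/2, 1 + jitter/2] (the N-terminal Met is preserved).
    """
    length = max(10, round(len(protein) * (1.0 + rng.uniform(-length_jitter / 2,
                                                             length_jitter / 2))))
    if length <= len(protein):
        derived = list(protein[:length])
    else:
        derived = list(protein) + [rng.choice(AMINO_ACIDS)
                                   for _ in range(length - len(protein))]
    for i in range(1, len(derived)):
        if rng.random() < substitution_rate:
            choices = AMINO_ACIDS.replace(derived[i], "")
            derived[i] = rng.choice(choices)
    return "".join(derived)


def _random_protein(length: int, rng: random.Random) -> str:
    return "M" + "".join(rng.choice(AMINO_ACIDS) for _ in range(length - 1))


def gen_kog_cluster(
    ancestral_protein_length: int,
    n_species: int = 6,
    substitution_rate: float = 0.10,
    length_jitter: float = 0.118,
    seed: int = 0,
    cluster_id: str = "KOG0001",
) -> OrthologCluster:
    """One conserved-gene reference cluster.

    ``n_species`` lineages are derived independently from a random ancestral
    protein. With the default jitter the expected longest/shortest length
    ratio is ~1.09–1.12, matching the variability reported for six-species
    reference sets.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = random.Random(seed)
    ancestral = _random_protein(ancestral_protein_length, rng)
    members = {
        f"sp{i + 1}": _mutate_protein(ancestral, substitution_rate, length_jitter, rng)
        for i in range(n_species)
    }
    return OrthologCluster.from_members(cluster_id, members)


def back_translate(protein: str, rng: random.Random) -> str:
    """A CDS encoding ``protein``: random synonymous codons plus a stop."""
    return "".join(rng.choice(_CODONS[aa]) for aa in protein) + rng.choice(STOP_CODONS)


def _draw_qualities(n: int, mean: float, sd: float, rng: random.Random) -> list[int]:
    return [max(2, min(41, round(rng.gauss(mean, sd)))) for _ in range(n)]


def _apply_errors(seq: str, error_rate: float, rng: random.Random) -> str:
    if error_rate <= 0:
        return seq
    bases = list(seq)
    for i, b in enumerate(bases):
        if rng.random() < error_rate:
            bases[i] = rng.choice("ACGT".replace(b, "") if b in "ACGT" else "ACGT")
    return "".join(bases)


def gen_reads(
    transcripts: Sequence[SyntheticTranscript],
    weights: Optional[Sequence[float]],
    n_pairs: int,
    read_len: int = 100,
    insert_mean: int = 180,
    insert_sd: int = 20,
    error_rate: float = 0.001,
    adapter_seq: str = TRUSEQ_ADAPTER,
    adapter_rate: float = 0.004,
    polyt_rate: float = 0.002,
    lowq_rate: float = 0.11,
    seed: int = 0,
) -> tuple[list[ReadPair], SyntheticTruth]:
    """Simulate a paired-end library with planted, ledgered artifacts.

    Fragments are sampled with probability proportional to expression
    weight x transcript length; mate 1 reads the fragment 5'->3', mate 2
    reads the reverse-complement strand from the other end; which physical
    strand is mate 1 is a fair coin. Artifact categories are drawn per read
    (not per pair) and are mutually exclusive:

    ``adapter``
        the read contains ``adapter_seq`` verbatim (read-through),
    ``polyt``
        >= 95% of the read is T,
    ``lowq``
        qualities from the low-quality model (mean ~20),
    ``clean``
        genomic sequence, baseline qualities, per-base errors at
        ``error_rate``.

    Sequencing errors are applied only to genomic bases of clean/lowq
    reads, so planted adapter and polyT signals are never corrupted.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    for name, rate in (("adapter_rate", adapter_rate), ("polyt_rate", polyt_rate),
                       ("lowq_rate", lowq_rate), ("error_rate", error_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if read_len > insert_mean:
        raise ValueError("read_len must be <= insert_mean")
    rng = random.Random(seed)
    if weights is None:
        weights = [t.expression_weight for t in transcripts]
    sampling = [w * len(t) for w, t in zip(weights, transcripts)]

    pairs: list[ReadPair] = []
    provenance: dict[str, str] = {}
    category: dict[str, str] = {}
    start_of: dict[str, int] = {}

    def make_read(rid: str, genomic: str, tstart: int, source: str) -> ReadRecord:
        u = rng.random()
        if u < adapter_rate:
            cat = "adapter"
            pos = rng.randint(0, read_len - len(adapter_seq))
            tail_len = read_len - pos - len(adapter_seq)
            tail = "".join(rng.choice("ACGT") for _ in range(tail_len))
            seq = genomic[:pos] + adapter_seq + tail
            qual = _draw_qualities(read_len, GOOD_QUAL_MEAN, GOOD_QUAL_SD, rng)
        elif u < adapter_rate + polyt_rate:
            cat = "polyt"
            seq_l = ["T"] * read_len
            for _ in range(rng.randint(0, read_len // 20)):
                seq_l[rng.randrange(read_len)] = rng.choice("ACG")
            seq = "".join(seq_l)
            qual = _draw_qualities(read_len, GOOD_QUAL_MEAN, GOOD_QUAL_SD, rng)
        elif u < adapter_rate + polyt_rate + lowq_rate:
            cat = "lowq"
            seq = _apply_errors(genomic, error_rate, rng)
            qual = _draw_qualities(read_len, LOWQ_QUAL_MEAN, LOWQ_QUAL_SD, rng)
        else:
            cat = "clean"
            seq = _apply_errors(genomic, error_rate, rng)
            qual = _draw_qualities(read_len, GOOD_QUAL_MEAN, GOOD_QUAL_SD, rng)
        provenance[rid] = source
        category[rid] = cat
        start_of[rid] = tstart
        mate = 1 if rid.endswith("/1") else 2
        return ReadRecord(rid[:-2], seq, qual, mate)

    for i in range(n_pairs):
        tx = rng.choices(range(len(transcripts)), weights=sampling, k=1)[0]
        t = transcripts[tx]
        tlen = len(t.sequence)
        insert = round(rng.gauss(insert_mean, insert_sd))
        insert = max(read_len, min(insert, tlen))
        start = rng.randint(0, tlen - insert)
        fragment = t.sequence[start:start + insert]
        fwd = fragment[:read_len]
        rev = reverse_complement(fragment)[:read_len]
        fwd_start = start
        rev_start = start + insert - read_len
        if rng.random() < 0.5:
            g1, s1, g2, s2 = fwd, fwd_start, rev, rev_start
        else:
            g1, s1, g2, s2 = rev, rev_start, fwd, fwd_start
        base = f"sim{i:07d}"
        r1 = make_read(f"{base}/1", g1, s1, t.id)
        r2 = make_read(f"{base}/2", g2, s2, t.id)
        pairs.append(ReadPair(r1, r2))

    truth = SyntheticTruth(
        transcripts=list(transcripts),
        read_provenance=provenance,
        read_category=category,
        read_start=start_of,
        params={
            "n_pairs": n_pairs, "read_len": read_len, "insert_mean": insert_mean,
            "insert_sd": insert_sd, "error_rate": error_rate,
            "adapter_seq": adapter_seq, "adapter_rate": adapter_rate,
            "polyt_rate": polyt_rate, "lowq_rate": lowq_rate, "seed": seed,
        },
    )
    return pairs, truth


@dataclass
class SyntheticStudy:
    """A full simulated experiment: transcriptome, references, and truth.

    ``sample_proteins`` are the proteins of the simulated organism itself —
    an extra diverged lineage that is NOT a member of its reference cluster
    (the assembled organism is absent from the references, as a non-model
    species would be). ``plantable`` marks genes whose sample protein length
    falls inside the cluster's ratio-extended size bounds; only those can
    ever be recovered as full-length.
    """

    transcripts: list[SyntheticTranscript]
    clusters: list[OrthologCluster]
    sample_proteins: dict[str, str]        # cluster id -> planted protein
    plantable: dict[str, bool]             # cluster id -> within cluster bounds
    weights: list[float]


def simulate_study(
    n_genes: int = 60,
    n_kog: int = 50,
    n_species: int = 6,
    ancestral_len_range: tuple[int, int] = (150, 250),
    substitution_rate: float = 0.10,
    length_jitter: float = 0.118,
    utr_range: tuple[int, int] = (150, 300),
    orders_of_magnitude: float = 1.0,
    gc_dist: tuple[float, float] = (0.45, 0.05),
    noise_length_range: tuple[int, int] = (400, 800),
    seed: int = 0,
) -> SyntheticStudy:
    """Simulate a transcriptome in which ``n_kog`` genes carry ortholog CDSs.

    Each conserved gene gets a reference cluster of ``n_species`` lineages
    plus one extra lineage — the sampled organism — whose protein is
    back-translated with random synonymous codons and embedded between
    UTRs. The remaining ``n_genes - n_kog`` transcripts are random
    non-coding sequence.
    """
    if not 0 <= n_kog <= n_genes:
        raise ValueError("need 0 <= n_kog <= n_genes")
    rng = random.Random(seed)
    transcripts: list[SyntheticTranscript] = []
    clusters: list[OrthologCluster] = []
    sample_proteins: dict[str, str] = {}
    plantable: dict[str, bool] = {}

    for g in range(n_kog):
        cid = f"KOG{g:04d}"
        ancestral = _random_protein(rng.randint(*ancestral_len_range), rng)
        members = {
            f"sp{i + 1}": _mutate_protein(ancestral, substitution_rate,
                                          length_jitter, rng)
            for i in range(n_species)
        }
        cluster = OrthologCluster.from_members(cid, members)
        sample = _mutate_protein(ancestral, substitution_rate, length_jitter, rng)
        cds = back_translate(sample, rng)
        gc = min(0.95, max(0.05, rng.gauss(*gc_dist)))
        utr5 = _random_seq_with_gc(rng.randint(*utr_range), gc, rng)
        utr3 = _random_seq_with_gc(rng.randint(*utr_range), gc, rng)
        seq = utr5 + cds + utr3
        transcripts.append(SyntheticTranscript(
            id=f"tx{g:04d}", sequence=seq, expression_weight=0.0, gc_target=gc,
            kog_cluster_id=cid,
            cds_interval=(len(utr5), len(utr5) + len(cds), "+"),
        ))
        clusters.append(cluster)
        sample_proteins[cid] = sample
        plantable[cid] = cluster.lower_bound_aa <= len(sample) <= cluster.upper_bound_aa

    for g in range(n_kog, n_genes):
        gc = min(0.95, max(0.05, rng.gauss(*gc_dist)))
        transcripts.append(SyntheticTranscript(
            id=f"tx{g:04d}",
            sequence=_random_seq_with_gc(rng.randint(*noise_length_range), gc, rng),
            expression_weight=0.0, gc_target=gc,
        ))

    weights = gen_expression(n_genes, orders_of_magnitude, seed=rng.randrange(2 ** 31))
    for t, w in zip(transcripts, weights):
        t.expression_weight = w
    return SyntheticStudy(transcripts, clusters, sample_proteins, plantable, weights)


def clusters_to_fasta_records(clusters: Sequence[OrthologCluster]) -> list[tuple[str, str]]:
    """``>clusterID|species`` records for the reference-cluster FASTA."""
    return [(f"{c.cluster_id}|{sp}", prot)
            for c in clusters for sp, prot in sorted(c.members.items())]
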