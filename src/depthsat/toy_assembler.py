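"""A minimal de Bruijn assembler with a static k-mer coverage cutoff.

This is a deliberately small stand-in for a production transcriptome
assembler: k-mers are counted on canonical (strand-collapsed) form, those
below the coverage cutoff are discarded, and contigs are the maximal
non-branching paths (unitigs) of the surviving k-mer graph. There is no
paired-end scaffolding, bubble resolution, or splice-graph traversal, so
"transcripts per locus" here reflects unitig fragmentation rather than
isoform structure. Loci are connected components of the graph linking
contigs that share at least one canonical k-mer. Real assemblies can be
supplied as FASTA anywhere an :class:`Assembly` is consumed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .io_formats import ReadRecord
from .sequtils import reverse_complement


@dataclass
class AssemblyParams:
    k: int = 25
    coverage_cutoff: int = 3
    min_contig_length: int = 100

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be an odd integer >= 15")
        if self.coverage_cutoff < 1:
            raise ValueError("coverage_cutoff must be >= 1")


@dataclass
class ContigRecord:
    id: str
    sequence: str
    locus_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    contigs: list[ContigRecord]
    loci: dict[str, list[str]]        # locus id -> contig ids
    n_input_reads: int = 0
    params: Optional[AssemblyParams] = None   # None marks an external assembly

    def contig_map(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self.contigs}

    @classmethod
    def from_contigs(cls, records: Iterable[tuple[str, str]],
                     loci: Optional[Mapping[str, Sequence[str]]] = None,
                     n_input_reads: int = 0) -> "Assembly":
        """Wrap an externally assembled contig set.

        Without an explicit locus table each contig is its own locus.
        """
        contigs = [ContigRecord(name, seq) for name, seq in records]
        if loci is None:
            loci_map = {f"L{i:05d}": [c.id] for i, c in enumerate(contigs)}
        else:
            loci_map = {lid: list(cids) for lid, cids in loci.items()}
        by_locus = {cid: lid for lid, cids in loci_map.items() for cid in cids}
        for c in contigs:
            c.locus_id = by_locus.get(c.id, "")
        return cls(contigs, loci_map, n_input_reads, params=None)


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[ReadRecord | str], k: int) -> Counter:
    """Canonical k-mer counts over a read set; k-mers containing N are skipped."""
    counts: Counter = Counter()
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        if len(seq) < k:
            continue
        rc = reverse_complement(seq)
        n = len(seq)
        for i in range(n - k + 1):
            fwd = seq[i:i + k]
            if "N" in fwd:
                continue
            rev = rc[n - k - i:n - i]
            counts[fwd if fwd <= rev else rev] += 1
    return counts


def _unitigs_from_kmers(kmers: set[str], k: int) -> list[str]:
    """Maximal non-branching paths over the k-mer set (both strands).

    The directed graph has one node per k-mer orientation and an edge for
    every (k-1)-overlap; each unitig and its reverse complement are
    discovered twice and deduplicated to the lexicographically smaller
    orientation.
    """
    nodes: set[str] = set()
    for km in kmers:
        nodes.add(km)
        nodes.add(reverse_complement(km))

    def successors(km: str) -> list[str]:
        return [km[1:] + b for b in "ACGT" if km[1:] + b in nodes]

    def predecessors(km: str) -> list[str]:
        return [b + km[:-1] for b in "ACGT" if b + km[:-1] in nodes]

    def is_path_start(km: str) -> bool:
        preds = predecessors(km)
        if len(preds) != 1:
            return True
        return len(successors(preds[0])) != 1

    unitigs: set[str] = set()
    visited: set[str] = set()
    for start in sorted(nodes):
        if start in visited or not is_path_start(start):
            continue
        path = [start]
        visited.add(start)
        current = start
        while True:
            succ = successors(current)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if is_path_start(nxt) or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            current = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        unitigs.add(min(seq, reverse_complement(seq)))

    # isolated cycles (every node has in/out degree 1) are left unvisited
    for km in sorted(nodes):
        if km not in visited:
            # walk the cycle once
            path = [km]
            visited.add(km)
            current = km
            while True:
                succ = successors(current)
                if not succ:
                    break
                nxt = succ[0]
                if nxt in visited:
                    break
                path.append(nxt)
                visited.add(nxt)
                current = nxt
            seq = path[0] + "".join(p[-1] for p in path[1:])
            unitigs.add(min(seq, reverse_complement(seq)))
    return sorted(unitigs)


def assemble(reads: Sequence[ReadRecord | str], params: AssemblyParams) -> Assembly:
    """Assemble reads into unitigs after applying the coverage cutoff.

    K-mers observed fewer than ``coverage_cutoff`` times are removed before
    graph construction; contigs shorter than ``min_contig_length`` are
    discarded. With no surviving k-mers the result is an empty assembly.
    """
    counts = count_kmers(reads, params.k)
    surviving = {km for km, c in counts.items() if c >= params.coverage_cutoff}
    n_input = len(reads)
    if not surviving:
        return Assembly([], {}, n_input, params)
    seqs = [s for s in _unitigs_from_kmers(surviving, params.k)
            if len(s) >= params.min_contig_length]
    contigs = [ContigRecord(f"contig{i:05d}", s) for i, s in enumerate(seqs)]
    loci = cluster_loci(contigs, params.k)
    by_locus = {cid: lid for lid, cids in loci.items() for cid in cids}
    for c in contigs:
        c.locus_id = by_locus[c.id]
    return Assembly(contigs, loci, n_input, params)


def cluster_loci(contigs: Sequence[ContigRecord], k: int) -> dict[str, list[str]]:
    """Group contigs into loci: connected components of the graph linking
    contigs that share at least one canonical k-mer."""
    graph = nx.Graph()
    kmer_owner: dict[str, str] = {}
    for contig in contigs:
        graph.add_node(contig.id)
        seen_here = set()
        for i in range(len(contig.sequence) - k + 1):
            km = canonical(contig.sequence[i:i + k])
            if "N" in km or km in seen_here:
                continue
            seen_here.add(km)
            owner = kmer_owner.get(km)
            if owner is None:
                kmer_owner[km] = contig.id
            elif owner != contig.id:
                graph.add_edge(owner, contig.id)
    loci: dict[str, list[str]] = {}
    components = sorted(nx.connected_components(graph),
                        key=lambda comp: min(comp))
    for i, comp in enumerate(components):
        loci[f"L{i:05d}"] = sorted(comp)
    return loci
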