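"""Per-assembly summary statistics and GC distributions.

One :class:`MetricsRow` per depth: contig count, total/mean/median length,
N50, locus count, per-million-read rates, transcripts per locus, and GC.
The scalar GC is pooled over bases (total G+C over total A+C+G+T across
all contigs); histograms are per-sequence so read pools and contig pools
are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .toy_assembler import Assembly


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that contigs >= L hold at least half the bases.

    Computed by descending-sort cumulative sum, returning the length at
    which the cumulative sum first reaches total/2.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    cum = 0
    for length in ordered:
        cum += length
        if cum >= half:
            return length
    raise AssertionError("unreachable")


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N positions are excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    gc = sum(sequence.count(b) for b in "GC")
    acgt = sum(sequence.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / acgt


def pooled_gc_percent(sequences: Iterable[str]) -> float:
    """GC over all bases pooled across sequences, as a percentage."""
    gc = acgt = 0
    for seq in sequences:
        gc += sum(seq.count(b) for b in "GC")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / acgt


def gc_histogram(sequences: Sequence[str], bin_width: float = 0.01) -> np.ndarray:
    """Normalized per-sequence GC histogram on [0, 1].

    ``bin_width`` must divide 1 evenly; bin masses sum to 1. Reads and
    contigs are binned identically, so the two histograms are comparable.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    if len(sequences) == 0:
        raise ValueError("no sequences")
    values = [gc_fraction(s) for s in sequences]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(values, bins=edges)
    return hist / hist.sum()


@dataclass
class MetricsRow:
    depth_reads: int
    n_transcripts: int
    total_length_bp: int
    mean_bp: float
    median_bp: float
    n50_bp: int
    n_loci: int
    loci_per_million_reads: float
    transcripts_per_million_reads: float
    transcripts_per_locus: float
    gc_percent: float

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["gc_percent"] = round(d["gc_percent"], 2) if not math.isnan(d["gc_percent"]) else float("nan")
        return d


def summarize(assembly: Assembly, depth_reads: int) -> MetricsRow:
    """All summary statistics for one assembly at one read depth.

    Per-million figures use ``depth_reads`` (the number of reads given to
    the assembler). An empty assembly yields zero counts with NaN means.
    """
    if depth_reads <= 0:
        raise ValueError("depth_reads must be > 0")
    lengths = [len(c) for c in assembly.contigs]
    n = len(lengths)
    millions = depth_reads / 1e6
    if n == 0:
        return MetricsRow(depth_reads, 0, 0, float("nan"), float("nan"), 0, 0,
                          0.0, 0.0, float("nan"), float("nan"))
    total = sum(lengths)
    n_loci = len(assembly.loci)
    return MetricsRow(
        depth_reads=depth_reads,
        n_transcripts=n,
        total_length_bp=total,
        mean_bp=total / n,
        median_bp=float(np.median(lengths)),
        n50_bp=n50(lengths),
        n_loci=n_loci,
        loci_per_million_reads=n_loci / millions,
        transcripts_per_million_reads=n / millions,
        transcripts_per_locus=n / n_loci if n_loci else float("nan"),
        gc_percent=pooled_gc_percent(c.sequence for c in assembly.contigs),
    )
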