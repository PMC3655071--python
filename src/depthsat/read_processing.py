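"""Read filtration and the randomized, nested depth ladder.

Filtering removes whole reads, never trims: a read fails on (in order)
mean Phred < threshold (strictly below; mean exactly at the threshold
passes), adapter content, or low complexity (mostly one repeated base,
e.g. polyT tracts). Pairs where one mate fails may either drop both reads
or salvage the good mate as an unpaired read.

Subsampling randomizes the order of pair units once, then cuts nested
prefixes: every read in a smaller subset is contained in every larger one,
so depth is the only variable along the ladder.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import ReadPair, ReadRecord, ReadUnit, unit_reads

DEFAULT_MIN_MEAN_PHRED = 28.0


@dataclass
class FilterParams:
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED
    adapter_seqs: list[str] = field(default_factory=list)
    low_complexity_fraction: float = 0.9
    salvage_singletons: bool = True
    # a homopolymer run of this fraction of the read length also fails
    homopolymer_run_fraction: float = 0.8
    max_n_fraction: float = 0.10
    # adapter prefixes at least this long are matched at the 3' end with
    # up to one mismatch (full-insert read-through)
    adapter_min_prefix: int = 12


@dataclass
class FilterReport:
    total_reads: int = 0
    kept: int = 0
    removed_low_quality: int = 0
    removed_adapter: int = 0
    removed_low_complexity: int = 0
    removed_broken_pair: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mean_phred(qualities: Sequence[int]) -> float:
    """Arithmetic mean of integer Phred scores; empty input is an error."""
    if len(qualities) == 0:
        raise ValueError("empty quality list")
    return sum(qualities) / len(qualities)


def _has_adapter(sequence: str, params: FilterParams) -> bool:
    for adapter in params.adapter_seqs:
        if not adapter:
            continue
        if adapter in sequence:
            return True
        # read-through: a >= adapter_min_prefix-nt adapter prefix at the
        # 3' end, tolerating one mismatch
        max_p = min(len(adapter), len(sequence))
        for p in range(params.adapter_min_prefix, max_p + 1):
            tail = sequence[-p:]
            prefix = adapter[:p]
            mismatches = sum(a != b for a, b in zip(tail, prefix))
            if mismatches <= 1:
                return True
    return False


def _is_low_complexity(sequence: str, params: FilterParams) -> bool:
    if not sequence:
        return True
    counts = Counter(sequence)
    n_n = counts.pop("N", 0)
    if n_n > params.max_n_fraction * len(sequence):
        return True
    non_n = sum(counts.values())
    if non_n == 0:
        return True
    if max(counts.values()) >= params.low_complexity_fraction * non_n:
        return True
    run_cut = params.homopolymer_run_fraction * len(sequence)
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best >= run_cut


def classify_read(read: ReadRecord, params: FilterParams) -> Optional[str]:
    """``None`` to keep, else the first failing rule:
    ``low_quality`` -> ``adapter`` -> ``low_complexity``."""
    if mean_phred(read.qualities) < params.min_mean_phred:
        return "low_quality"
    if _has_adapter(read.sequence, params):
        return "adapter"
    if _is_low_complexity(read.sequence, params):
        return "low_complexity"
    return None


def filter_pairs(
    pairs: Iterable[ReadPair],
    params: FilterParams,
) -> tuple[list[ReadUnit], FilterReport]:
    """Apply per-read rules pairwise.

    good/good -> both kept as a pair; bad/bad -> both dropped; mixed ->
    with ``salvage_singletons`` the good mate is kept unpaired, otherwise
    it is dropped and counted as ``removed_broken_pair``.
    """
    report = FilterReport()
    kept: list[ReadUnit] = []
    for pair in pairs:
        reasons = [classify_read(r, params) for r in pair]
        report.total_reads += 2
        for reason in reasons:
            if reason == "low_quality":
                report.removed_low_quality += 1
            elif reason == "adapter":
                report.removed_adapter += 1
            elif reason == "low_complexity":
                report.removed_low_complexity += 1
        n_bad = sum(r is not None for r in reasons)
        if n_bad == 0:
            kept.append(pair)
            report.kept += 2
        elif n_bad == 1:
            good = pair.r1 if reasons[0] is None else pair.r2
            if params.salvage_singletons:
                kept.append(ReadRecord(good.id, good.sequence,
                                       good.qualities, "unpaired"))
                report.kept += 1
            else:
                report.removed_broken_pair += 1
    return kept, report


def filter_reads(
    reads: Iterable[ReadRecord],
    params: FilterParams,
) -> tuple[list[ReadRecord], FilterReport]:
    """Single-end variant of :func:`filter_pairs`."""
    report = FilterReport()
    kept = []
    for read in reads:
        report.total_reads += 1
        reason = classify_read(read, params)
        if reason is None:
            kept.append(read)
            report.kept += 1
        else:
            setattr(report, f"removed_{reason}",
                    getattr(report, f"removed_{reason}") + 1)
    return kept, report


def randomize_order(units: Sequence[ReadUnit], seed: int) -> list[ReadUnit]:
    """Uniform random permutation of pair units (mates travel together)."""
    rng = random.Random(seed)
    shuffled = list(units)
    rng.shuffle(shuffled)
    return shuffled


def n_reads(units: Iterable[ReadUnit]) -> int:
    return sum(len(unit_reads(u)) for u in units)


def nested_subsets(
    units: Sequence[ReadUnit],
    depths: Sequence[int],
) -> list[list[ReadUnit]]:
    """Prefix-nested subsets of an (already randomized) unit sequence.

    ``depths`` count reads and must be strictly ascending; subset *i* is
    the shortest prefix of units whose read count reaches ``depths[i]``
    (units are never split), so smaller subsets are contained in larger
    ones by construction.
    """
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError(f"depths must be strictly ascending: {list(depths)}")
    total = n_reads(units)
    if depths and depths[-1] > total:
        raise ValueError(
            f"requested depth {depths[-1]} exceeds available reads "
            f"({total}; short by {depths[-1] - total})")
    subsets: list[list[ReadUnit]] = []
    cum = 0
    pos = 0
    prefix: list[ReadUnit] = []
    for depth in depths:
        while cum < depth:
            unit = units[pos]
            prefix.append(unit)
            cum += len(unit_reads(unit))
            pos += 1
        subsets.append(list(prefix))
    return subsets
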