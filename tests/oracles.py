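"""Independent brute-force oracles used only by the test suite.

Each oracle implements a definition directly and inefficiently, without
reusing any code path from the package under test.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11   # a gap of length L costs GAP_OPEN + L * GAP_EXTEND
GAP_EXTEND = 1


def brute_n50(lengths) -> int:
    """Definitional N50: the largest L in the list such that contigs of
    length >= L together hold at least half of the total bases."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) >= total / 2:
            return L
    raise AssertionError("unreachable")


def gotoh_local_score(query: str, subject: str,
                      gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND) -> float:
    """Plain-loop affine-gap Smith-Waterman (Gotoh) best local score."""
    m, n = len(query), len(subject)
    neg = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]   # gap in query (subject consumed)
    F = [[neg] * (n + 1) for _ in range(m + 1)]   # gap in subject
    best = 0.0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            sub = _BLOSUM62[qi, subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_loci(contigs, k):
    """Partition contig ids by shared canonical k-mers, via union-find."""
    comp = str.maketrans("ACGTN", "TGCAN")

    def canon(s):
        rc = s.translate(comp)[::-1]
        return s if s <= rc else rc

    uf = UnionFind([c.id for c in contigs])
    owners: dict[str, str] = {}
    for c in contigs:
        for i in range(len(c.sequence) - k + 1):
            km = canon(c.sequence[i:i + k])
            if km in owners:
                uf.union(owners[km], c.id)
            else:
                owners[km] = c.id
    groups: dict[str, set[str]] = {}
    for c in contigs:
        groups.setdefault(uf.find(c.id), set()).add(c.id)
    return sorted(frozenset(g) for g in groups.values())
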