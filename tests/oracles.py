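"""Independent reference implementations used only by the tests.

These deliberately use different machinery from the package: maximal runs
are found with a regex (the package walks the string), and clustering is an
all-pairs gap graph solved by union-find (the package chains in one pass).
"""

from __future__ import annotations

import re
from typing import List, Sequence, Tuple

import numpy as np


def regex_maximal_runs(sequence: str, core: str, repetitions: int = 2) -> List[Tuple[int, int, int]]:
    """(start, end, n_copies) of maximal non-overlapping runs of >= 2 copies."""
    pattern = re.compile(f"(?:{re.escape(core)}){{{repetitions},}}")
    out = []
    for m in pattern.finditer(sequence):
        n = (m.end() - m.start()) // len(core)
        out.append((m.start(), m.start() + n * len(core), n))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def unionfind_colonies(
    intervals: Sequence[Tuple[str, int, int]], gap_threshold: int, min_size: int = 2
) -> List[List[int]]:
    """Indices of colony members, grouped, via all-pairs union-find."""
    n = len(intervals)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            gap = max(sj - ei, si - ej)
            if gap < gap_threshold:
                uf.union(i, j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    out = [sorted(g) for g in groups.values() if len(g) >= min_size]
    out.sort(key=lambda g: (intervals[g[0]][0], intervals[g[0]][1]))
    return out


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


def random_hit_intervals(
    rng: np.random.Generator, n: int, span: int = 50_000, chromosomes: int = 2
) -> List[Tuple[str, int, int]]:
    """Sorted non-overlapping (chrom, start, end) intervals of width 6."""
    intervals = []
    for c in range(chromosomes):
        k = int(rng.integers(0, n + 1))
        starts = np.sort(rng.choice(span // 8, size=k, replace=False)) * 8
        intervals.extend((f"chr{c + 1}", int(s), int(s) + 6) for s in starts)
    return intervals
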