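"""Colony detection: chaining dyad hits under a gap threshold.

A *colony* is a maximal chain of dyad hits on one chromosome in which each
consecutive pair is separated (end of one to start of the next) by strictly
less than the gap threshold, 500 bp by default. Chains shorter than
``min_size`` (default 2) are not colonies. Clustering runs on the
motif-merged hit stream, so mixed GGC/GCC colonies arise naturally; the
composition *formula* is the run-length encoding of the ordered member
motifs, e.g. ``[(GGC)2]11 [(GCC)2]5``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .dyad_scan import DyadHit


@dataclass(frozen=True)
class ColonyConfig:
    gap_threshold: int = 500
    min_size: int = 2

    def __post_init__(self) -> None:
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be positive")
        if self.min_size < 2:
            raise ValueError("a colony has at least 2 members")


@dataclass
class Colony:
    """An ordered chain of dyad hits; size is the member count k."""

    chromosome: str
    start: int
    end: int
    size: int
    formula: str
    composition: Dict[str, int]
    members: Optional[Tuple[DyadHit, ...]] = None
    probability: Optional[float] = None
    log10_probability: Optional[float] = None

    @property
    def homogeneous(self) -> bool:
        return len(self.composition) == 1

    @property
    def name(self) -> str:
        # the field's C{k} naming (C99, C51, ...)
        return f"C{self.size}"

    @classmethod
    def from_members(cls, members: Sequence[DyadHit]) -> "Colony":
        members = tuple(members)
        if len(members) < 2:
            raise ValueError("a colony needs at least 2 members")
        composition = dict(Counter(h.motif.core for h in members))
        return cls(
            chromosome=members[0].chromosome,
            start=members[0].start,
            end=members[-1].end,
            size=len(members),
            formula=render_formula(members),
            composition=composition,
            members=members,
        )


def render_formula(members: Sequence[DyadHit]) -> str:
    """Run-length encode the ordered member motifs.

    A block of b > 1 consecutive same-motif members renders as
    ``[(CORE)2]b``; a lone member renders bare as ``(CORE)2``.
    """
    parts: List[str] = []
    block_label: Optional[str] = None
    block_len = 0
    for hit in list(members) + [None]:  # sentinel flushes the last block
        label = hit.motif.label if hit is not None else None
        if label == block_label:
            block_len += 1
            continue
        if block_label is not None:
            parts.append(
                f"[{block_label}]{block_len}" if block_len > 1 else block_label
            )
        block_label, block_len = label, 1
    return " ".join(parts)


def cluster_hits(hits: Sequence[DyadHit], config: ColonyConfig = ColonyConfig()) -> List[Colony]:
    """Single-linkage chaining of sorted, non-overlapping hits into colonies.

    A new chain starts whenever the gap (next.start - prev.end) reaches the
    threshold; the comparison is strict (<), so a gap of exactly 500 bp
    breaks the chain. A gap of 0 (abutting runs of different motifs) chains.
    Chains below ``min_size`` are discarded.
    """
    order = [(h.chromosome, h.start) for h in hits]
    if order != sorted(order):
        raise ValueError("hits must be sorted by (chromosome, start)")

    colonies: List[Colony] = []
    chain: List[DyadHit] = []

    def flush() -> None:
        if len(chain) >= config.min_size:
            colonies.append(Colony.from_members(chain))

    for h in hits:
        if chain and (
            h.chromosome != chain[-1].chromosome
            or h.start - chain[-1].end >= config.gap_threshold
        ):
            flush()
            chain = []
        chain.append(h)
    flush()
    return colonies


def colony_size_spectrum(colonies: Sequence[Colony]) -> Dict[int, int]:
    """Genome-wide abundance of each colony size (size -> number of colonies)."""
    return dict(sorted(Counter(c.size for c in colonies).items()))


def member_dyad_count(colonies: Sequence[Colony]) -> int:
    """Total dyads that belong to some colony (the paper-style N for lambda)."""
    return sum(c.size for c in colonies)
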