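"""Trinucleotide-dyad extraction.

A *dyad* is two tandem copies of a short core, e.g. (GGC)2 = ``GGCGGC``.
The scanner walks each chromosome left to right: at the first position
where a window of ``repetitions x len(core)`` bases equals the tandemly
repeated core, the match is extended rightward by whole core copies for as
long as they continue, the *maximal run* is recorded, and scanning resumes
at the run's end. Windows containing any character outside the core (N,
soft-masked lowercase, IUPAC ambiguity codes) never match, so assembly gaps
break runs naturally.

What a run longer than two copies yields is configurable (``RunPolicy``):
the default records the whole maximal run as one hit; alternatives report
only exact double-copy runs, or tile the run with floor(n/2) double-copy
hits. Strand handling is likewise configurable: the reverse-strand image
of a dyad motif is the dyad of the reverse-complemented core occupying the
same forward-strand interval (revcomp((GGC)2) = (GCC)2), so scanning both
strands for both default motifs would count every site twice. The default
therefore scans the forward strand for each configured motif;
``both_dedup`` adds reverse-strand images and merges duplicate intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

from Bio.Seq import reverse_complement

from .errors import DataError
from .sequence_io import ChromosomeRecord

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Motif:
    """A tandem-repeat pattern: ``repetitions`` head-to-tail copies of ``core``."""

    core: str
    repetitions: int = 2

    def __post_init__(self) -> None:
        if not self.core:
            raise ValueError("motif core must be non-empty")
        if set(self.core) - _VALID_BASES:
            raise ValueError(
                f"motif core {self.core!r} must be uppercase ACGT only"
            )
        if self.repetitions < 2:
            raise ValueError("a tandem repeat needs at least 2 repetitions")

    @property
    def window(self) -> int:
        """Initial match window: repetitions x core length (6 for a triplet dyad)."""
        return self.repetitions * len(self.core)

    @property
    def label(self) -> str:
        return f"({self.core}){self.repetitions}"

    def reverse_complement(self) -> "Motif":
        return Motif(core=reverse_complement(self.core), repetitions=self.repetitions)


_MOTIF_LABEL_RE = re.compile(r"^\(([ACGT]+)\)(\d+)$")


def parse_motif_label(label: str) -> Tuple[str, int]:
    """Parse "(GGC)2" -> ("GGC", 2)."""
    m = _MOTIF_LABEL_RE.match(label)
    if not m:
        raise DataError(f"cannot parse motif label {label!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class DyadHit:
    """One located dyad occurrence (0-based, half-open coordinates)."""

    chromosome: str
    start: int
    end: int
    motif: Motif
    run_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("hit interval must satisfy 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


class RunPolicy(str, Enum):
    """How a maximal run of n >= 2 core copies is reported."""

    MAXIMAL_RUN_ONE_HIT = "maximal"
    EXACT_TWO_ONLY = "exact"
    FLOOR_PAIRS = "floor_pairs"


class StrandPolicy(str, Enum):
    FORWARD_ONLY = "forward"
    BOTH_DEDUP = "both_dedup"


DEFAULT_MOTIFS = (Motif("GGC"), Motif("GCC"))


@dataclass(frozen=True)
class ScanConfig:
    motifs: Tuple[Motif, ...] = DEFAULT_MOTIFS
    run_policy: RunPolicy = RunPolicy.MAXIMAL_RUN_ONE_HIT
    strand_policy: StrandPolicy = StrandPolicy.FORWARD_ONLY
    skip_softmasked: bool = False

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("at least one motif is required")


def _find_maximal_runs(sequence: str, core: str, repetitions: int) -> Iterator[Tuple[int, int]]:
    """Yield (start, n_copies) for maximal runs of >= `repetitions` copies.

    Greedy left-to-right: the seed window (`repetitions` copies) is located
    with ``str.find`` (a character-by-character scan in C), extended by whole
    core copies, and the search resumes at the run end, so runs never
    overlap.
    """
    L = len(core)
    seed = core * repetitions
    i = 0
    n = len(sequence)
    while i <= n - repetitions * L:
        j = sequence.find(seed, i)
        if j < 0:
            return
        end = j + repetitions * L
        while sequence.startswith(core, end):
            end += L
        yield j, (end - j) // L
        i = end


def _runs_to_hits(
    chromosome: str, motif: Motif, runs: Iterable[Tuple[int, int]], policy: RunPolicy
) -> Iterator[DyadHit]:
    L = len(motif.core)
    r = motif.repetitions
    for start, n_copies in runs:
        if policy is RunPolicy.MAXIMAL_RUN_ONE_HIT:
            yield DyadHit(chromosome, start, start + n_copies * L, motif, n_copies)
        elif policy is RunPolicy.EXACT_TWO_ONLY:
            if n_copies == r:
                yield DyadHit(chromosome, start, start + r * L, motif, r)
        elif policy is RunPolicy.FLOOR_PAIRS:
            for k in range(n_copies // r):
                s = start + k * r * L
                yield DyadHit(chromosome, s, s + r * L, motif, r)
        else:  # pragma: no cover - exhaustive enum
            raise AssertionError(policy)


def scan_sequence(record: ChromosomeRecord, config: ScanConfig = ScanConfig()) -> List[DyadHit]:
    """Scan one chromosome for every configured motif; hits sorted by start.

    Each motif is scanned independently (a GGC run and a GCC run may abut
    but cannot overlap). With ``skip_softmasked`` the sequence keeps its
    case and lowercase (soft-masked) stretches never match; otherwise the
    record is expected to be uppercased already by :func:`read_fasta`.
    """
    seq = record.sequence
    hits: List[DyadHit] = []
    for motif in config.motifs:
        runs = _find_maximal_runs(seq, motif.core, motif.repetitions)
        hits.extend(_runs_to_hits(record.name, motif, runs, config.run_policy))
    if config.strand_policy is StrandPolicy.BOTH_DEDUP:
        seen = {(h.start, h.end) for h in hits}
        for motif in config.motifs:
            rc = motif.reverse_complement()
            runs = _find_maximal_runs(seq, rc.core, rc.repetitions)
            for h in _runs_to_hits(record.name, motif, runs, config.run_policy):
                if (h.start, h.end) not in seen:
                    seen.add((h.start, h.end))
                    hits.append(replace(h, strand="-"))
    hits.sort(key=lambda h: (h.start, h.motif.label))
    return hits


def reverse_strand_hits(record: ChromosomeRecord, motif: Motif, config: ScanConfig = ScanConfig()) -> List[DyadHit]:
    """Hits for ``motif`` on the reverse strand, in forward coordinates.

    Scans the reverse complement of the sequence and mirrors coordinates
    back (start' = L - end). By the reverse-complement identity these
    intervals coincide with forward-strand hits of the revcomp-core motif.
    """
    rc_seq = reverse_complement(record.sequence)
    mirrored = ChromosomeRecord(record.name, rc_seq)
    sub = ScanConfig(
        motifs=(motif,),
        run_policy=config.run_policy,
        strand_policy=StrandPolicy.FORWARD_ONLY,
        skip_softmasked=config.skip_softmasked,
    )
    n = record.length
    out = [
        DyadHit(record.name, n - h.end, n - h.start, motif, h.run_length, "-")
        for h in scan_sequence(mirrored, sub)
    ]
    out.sort(key=lambda h: h.start)
    return out


@dataclass
class GenomeScanResult:
    """Per-chromosome hits plus per-motif genome totals."""

    hits_by_chromosome: Dict[str, List[DyadHit]] = field(default_factory=dict)
    totals_by_motif: Dict[str, int] = field(default_factory=dict)

    @property
    def total_hits(self) -> int:
        return sum(self.totals_by_motif.values())

    def all_hits(self) -> List[DyadHit]:
        out: List[DyadHit] = []
        for name in self.hits_by_chromosome:
            out.extend(self.hits_by_chromosome[name])
        return out

    def counts_by_chromosome(self) -> Dict[str, int]:
        return {name: len(hits) for name, hits in self.hits_by_chromosome.items()}


def scan_genome(
    records: Iterable[ChromosomeRecord], config: ScanConfig = ScanConfig()
) -> GenomeScanResult:
    """Scan a genome one chromosome at a time (streaming memory contract)."""
    result = GenomeScanResult(
        totals_by_motif={m.label: 0 for m in config.motifs}
    )
    for record in records:
        if record.name in result.hits_by_chromosome:
            raise DataError(f"duplicate chromosome name: {record.name}")
        hits = scan_sequence(record, config)
        result.hits_by_chromosome[record.name] = hits
        for h in hits:
            result.totals_by_motif[h.motif.label] = (
                result.totals_by_motif.get(h.motif.label, 0) + 1
            )
    return result
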