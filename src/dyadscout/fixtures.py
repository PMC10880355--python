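"""Synthetic genomes with implanted dyads, colonies, and gene models.

The generator is truth-first: the expected hits, colonies and formulas are
derived arithmetically from the implant specification, never by running the
scanner, so tests that compare scanner/clustering output against the truth
tables are non-circular. After implanting, the random background is
*sanitized* — any accidental tandem run of a watched core that does not
coincide exactly with an implant is broken by a single-base substitution —
so the truth tables are exact, not merely probable.

Background composition defaults to a human-like GC fraction of 0.41.
Truth colonies are computed by an all-pairs gap graph + connected
components (a deliberately different algorithm from the production
single-pass chaining).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dyad_scan import DyadHit, Motif
from .errors import DataError
from .sequence_io import ChromosomeRecord, write_fasta, write_hits_bed

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class DyadImplant:
    """A single maximal run of ``run_length`` core copies at a fixed position."""

    chromosome: str
    position: int
    core: str = "GGC"
    run_length: int = 2

    @property
    def span(self) -> Tuple[int, int]:
        return self.position, self.position + self.run_length * len(self.core)


@dataclass(frozen=True)
class ColonyImplant:
    """A chain of dyad members with a fixed inter-member gap.

    ``member_cores`` lists the core of each member in genomic order; every
    member is an exact double-copy run. The gap must keep members separate
    (>= 1 bp) yet chained (< the clustering gap threshold).
    """

    chromosome: str
    start: int
    member_cores: Tuple[str, ...]
    gap: int = 100

    def member_spans(self) -> List[Tuple[int, int, str]]:
        spans = []
        pos = self.start
        for core in self.member_cores:
            w = 2 * len(core)
            spans.append((pos, pos + w, core))
            pos += w + self.gap
        return spans

    @property
    def span(self) -> Tuple[int, int]:
        spans = self.member_spans()
        return spans[0][0], spans[-1][1]


@dataclass(frozen=True)
class GeneImplant:
    """A gene with one transcript; exon coordinates are genomic (absolute)."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"
    gene_id: str = "GENE1"
    biotype: str = "protein_coding"
    exons: Tuple[Tuple[int, int], ...] = ()  # default: single exon = gene span
    utr5: Tuple[Tuple[int, int], ...] = ()
    utr3: Tuple[Tuple[int, int], ...] = ()
    transcript_id: Optional[str] = None


@dataclass
class FixtureSpec:
    chromosomes: Dict[str, int]
    seed: int = 0
    gc_fraction: float = 0.41
    dyad_implants: Tuple[DyadImplant, ...] = ()
    colony_implants: Tuple[ColonyImplant, ...] = ()
    gene_implants: Tuple[GeneImplant, ...] = ()
    gap_threshold: int = 500


@dataclass
class TruthColony:
    chromosome: str
    start: int
    end: int
    size: int
    formula: str
    member_cores: Tuple[str, ...]


@dataclass
class Fixture:
    records: List[ChromosomeRecord]
    truth_hits: List[DyadHit]
    truth_colonies: List[TruthColony]
    gff3_text: str


def _truth_formula(member_cores: Sequence[str]) -> str:
    # independent run-length encoding (groupby), mirroring the field's
    # "[(GGC)2]11 [(GCC)2]5" notation
    parts = []
    for core, group in itertools.groupby(member_cores):
        b = len(list(group))
        label = f"({core})2"
        parts.append(f"[{label}]{b}" if b > 1 else label)
    return " ".join(parts)


def _collect_implant_spans(spec: FixtureSpec) -> Dict[str, List[Tuple[int, int, str, int]]]:
    """Per chromosome: (start, end, core, run_length) for every implanted run."""
    spans: Dict[str, List[Tuple[int, int, str, int]]] = {
        name: [] for name in spec.chromosomes
    }
    for imp in spec.dyad_implants:
        if imp.chromosome not in spans:
            raise DataError(f"implant on unknown chromosome {imp.chromosome}")
        s, e = imp.span
        spans[imp.chromosome].append((s, e, imp.core, imp.run_length))
    for imp in spec.colony_implants:
        if imp.chromosome not in spans:
            raise DataError(f"implant on unknown chromosome {imp.chromosome}")
        if not (1 <= imp.gap < spec.gap_threshold):
            raise DataError(
                f"colony implant gap {imp.gap} must be in [1, {spec.gap_threshold})"
            )
        for s, e, core in imp.member_spans():
            spans[imp.chromosome].append((s, e, core, 2))
    for name, chrom_spans in spans.items():
        chrom_spans.sort()
        length = spec.chromosomes[name]
        prev_end = None
        for s, e, core, _rl in chrom_spans:
            if s < 0 or e > length:
                raise DataError(
                    f"implant [{s},{e}) exceeds chromosome {name} (length {length})"
                )
            if prev_end is not None and s < prev_end + 1:
                raise DataError(
                    f"overlapping/abutting implants near {name}:{s}"
                )
            prev_end = e
    return spans


def _safe_base(cores: Sequence[str], original: str) -> str:
    used = set("".join(cores))
    for base in "TAGC":
        if base not in used and base != original:
            return base
    for base in "TAGC":  # all four bases appear in cores: any change helps
        if base != original:
            return base
    raise AssertionError("unreachable")


def _sanitize(
    seq: np.ndarray,
    implant_spans: Sequence[Tuple[int, int, str, int]],
    cores: Sequence[str],
    max_rounds: int = 50,
) -> None:
    """Break every accidental tandem run in place (background bases only)."""
    implanted = {(s, e) for s, e, _c, _r in implant_spans}
    protected = np.zeros(len(seq), dtype=bool)
    for s, e, _c, _r in implant_spans:
        protected[s:e] = True
    patterns = {core: re.compile(f"(?:{core}){{2,}}") for core in set(cores)}
    for _ in range(max_rounds):
        text = seq.tobytes().decode("ascii")
        dirty = False
        for core, pattern in patterns.items():
            for m in pattern.finditer(text):
                if (m.start(), m.end()) in implanted:
                    continue
                # mutate the first unprotected base inside the run
                for pos in range(m.start(), m.end()):
                    if not protected[pos]:
                        original = seq[pos].decode("ascii")
                        seq[pos] = _safe_base(cores, original).encode("ascii")
                        dirty = True
                        break
                else:  # run entirely inside implants: spec violation
                    raise DataError(
                        f"implants jointly form an unplanned run at {m.start()}"
                    )
        if not dirty:
            return
    raise DataError("sanitization did not converge")


def _random_background(rng: np.random.Generator, length: int, gc_fraction: float) -> np.ndarray:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].copy()


def build_fixture(spec: FixtureSpec, out_dir: Optional[str | Path] = None) -> Fixture:
    """Generate the genome and its exact truth tables; optionally write files.

    Deterministic for a fixed seed (byte-identical FASTA). When ``out_dir``
    is given, writes genome.fa, truth_hits.bed, truth_colonies.tsv and,
    if genes are implanted, genes.gff3.
    """
    rng = np.random.default_rng(spec.seed)
    spans_by_chrom = _collect_implant_spans(spec)
    watched_cores = sorted(
        {core for spans in spans_by_chrom.values() for _s, _e, core, _r in spans}
        | {"GGC", "GCC"}
    )

    records: List[ChromosomeRecord] = []
    truth_hits: List[DyadHit] = []
    for name, length in spec.chromosomes.items():
        seq = _random_background(rng, length, spec.gc_fraction)
        for s, e, core, run_length in spans_by_chrom[name]:
            run = (core * run_length).encode("ascii")
            seq[s:e] = np.frombuffer(run, dtype="S1")
        _sanitize(seq, spans_by_chrom[name], watched_cores)
        records.append(ChromosomeRecord(name, seq.tobytes().decode("ascii")))
        for s, e, core, run_length in spans_by_chrom[name]:
            truth_hits.append(
                DyadHit(name, s, e, Motif(core), run_length)
            )

    truth_hits.sort(key=lambda h: (h.chromosome, h.start))
    truth_colonies = _truth_colonies(truth_hits, spec.gap_threshold)
    gff3_text = render_gff3(spec.gene_implants) if spec.gene_implants else ""

    fixture = Fixture(records, truth_hits, truth_colonies, gff3_text)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "genome.fa")
        write_hits_bed(truth_hits, out_dir / "truth_hits.bed")
        with open(out_dir / "truth_colonies.tsv", "wt", encoding="ascii") as fh:
            fh.write("chrom\tstart\tend\tsize\tformula\n")
            for c in truth_colonies:
                fh.write(f"{c.chromosome}\t{c.start}\t{c.end}\t{c.size}\t{c.formula}\n")
        if gff3_text:
            (out_dir / "genes.gff3").write_text(gff3_text, encoding="ascii")
    return fixture


def _truth_colonies(hits: Sequence[DyadHit], gap_threshold: int) -> List[TruthColony]:
    """Connected components of the all-pairs gap graph (brute force)."""
    colonies: List[TruthColony] = []
    by_chrom: Dict[str, List[DyadHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chromosome, []).append(h)
    for name in by_chrom:
        chrom_hits = by_chrom[name]
        n = len(chrom_hits)
        adj = [[] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                gap = max(
                    chrom_hits[j].start - chrom_hits[i].end,
                    chrom_hits[i].start - chrom_hits[j].end,
                )
                if gap < gap_threshold:
                    adj[i].append(j)
        seen = [False] * n
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], []
            seen[i] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            if len(comp) < 2:
                continue
            members = sorted((chrom_hits[u] for u in comp), key=lambda h: h.start)
            cores = tuple(h.motif.core for h in members)
            colonies.append(
                TruthColony(
                    chromosome=name,
                    start=members[0].start,
                    end=members[-1].end,
                    size=len(members),
                    formula=_truth_formula(cores),
                    member_cores=cores,
                )
            )
    colonies.sort(key=lambda c: (c.chromosome, c.start))
    return colonies


def render_gff3(gene_implants: Sequence[GeneImplant]) -> str:
    """Ensembl-dialect GFF3 for the implanted genes (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in gene_implants:
        tx_id = g.transcript_id or f"{g.gene_id}.t1"
        exons = g.exons or ((g.start, g.end),)
        attrs = f"ID=gene:{g.gene_id};Name={g.gene_id};biotype={g.biotype}"
        lines.append(
            f"{g.chromosome}\tdyadscout\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{g.chromosome}\tdyadscout\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID=transcript:{tx_id};Parent=gene:{g.gene_id};tag=canonical"
        )
        for i, (s, e) in enumerate(sorted(exons), 1):
            lines.append(
                f"{g.chromosome}\tdyadscout\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID=exon:{tx_id}.{i};Parent=transcript:{tx_id}"
            )
        for s, e in g.utr5:
            lines.append(
                f"{g.chromosome}\tdyadscout\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"Parent=transcript:{tx_id}"
            )
        for s, e in g.utr3:
            lines.append(
                f"{g.chromosome}\tdyadscout\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"Parent=transcript:{tx_id}"
            )
    return "\n".join(lines) + "\n"


def sample_dyad_positions(
    length: int,
    n_dyads: int,
    rng: np.random.Generator,
    window: int = 6,
    min_gap: int = 1,
) -> np.ndarray:
    """Uniform non-overlapping dyad start positions (sorted).

    Sampling uses the standard spacing transform: draw n distinct values
    uniformly, sort, and shift each by its rank times (window + min_gap),
    which yields uniform placement conditional on the minimum separation.
    """
    if n_dyads == 0:
        return np.empty(0, dtype=np.int64)
    pitch = window + min_gap
    if n_dyads * pitch > length // 2:
        raise DataError(
            f"infeasible density: {n_dyads} dyads of window {window} on {length} bp"
        )
    slack = length - window - (n_dyads - 1) * pitch
    picks = np.sort(rng.choice(slack + 1, size=n_dyads, replace=False))
    return picks + np.arange(n_dyads, dtype=np.int64) * pitch


def null_genome(
    length: int,
    n_dyads: int,
    seed: int,
    core: str = "GGC",
    gc_fraction: float = 0.41,
    path: Optional[str | Path] = None,
) -> Tuple[ChromosomeRecord, np.ndarray]:
    """A genome with dyads placed uniformly at random — the Poisson null.

    Returns the chromosome record and the sorted dyad start positions;
    writes FASTA when ``path`` is given. Every placed dyad is an exact
    double-copy run and the sanitized background contains no others.
    """
    rng = np.random.default_rng(seed)
    positions = sample_dyad_positions(length, n_dyads, rng, window=2 * len(core))
    seq = _random_background(rng, length, gc_fraction)
    w = 2 * len(core)
    spans = [(int(p), int(p) + w, core, 2) for p in positions]
    dyad = (core * 2).encode("ascii")
    for s, e, _c, _r in spans:
        seq[s:e] = np.frombuffer(dyad, dtype="S1")
    watched = sorted({core, "GGC", "GCC"})
    _sanitize(seq, spans, watched)
    record = ChromosomeRecord("null", seq.tobytes().decode("ascii"))
    if path is not None:
        write_fasta([record], path)
    return record, positions
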