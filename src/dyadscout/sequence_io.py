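"""FASTA streaming and BED/TSV serialization.

Coordinates are 0-based, half-open everywhere in memory and in BED output;
the human-readable TSV mirrors use 1-based inclusive coordinates (the
convention of genome-browser displays). Probabilities are printed with a
fixed format so repeated runs produce byte-identical files: ``%.9g`` at or
above 1e-4, ``%.8E`` below, and the literal ``0`` for values under the
double-precision floor (their magnitude is still carried by the log10
column).
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .errors import DataError, FastaParseError

GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class ChromosomeRecord:
    """One chromosome (or contig): FASTA header token plus its sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise DataError("chromosome name must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _check_leading_header(handle: IO[str]) -> None:
    # FASTA must open with '>' (after optional leading whitespace); report
    # the byte offset of the first offending character.
    offset = 0
    while True:
        ch = handle.read(1)
        if ch == "":
            return  # empty file: handled by the caller as a warning
        if ch.isspace():
            offset += 1
            continue
        if ch != ">":
            raise FastaParseError(
                f"not FASTA: expected '>' but found {ch!r}", offset
            )
        break
    handle.seek(0)


def read_fasta(
    path: str | Path,
    chromosome_filter: Optional[Sequence[str]] = None,
    uppercase: bool = True,
) -> Iterator[ChromosomeRecord]:
    """Stream chromosomes from a plain or gzip FASTA file.

    Yields records in file order, one at a time (the full genome is never
    held in memory). Sequences are uppercased unless ``uppercase=False``
    (soft-mask-aware mode keeps lowercase stretches for the scanner to
    skip). ``chromosome_filter`` restricts output to the named records; if
    none of them occur a warning is emitted and the iterator is empty.
    """
    wanted = set(chromosome_filter) if chromosome_filter is not None else None
    yielded = 0
    with _open_text(path) as handle:
        _check_leading_header(handle)
        for rec in SeqIO.parse(handle, "fasta"):
            if wanted is not None and rec.id not in wanted:
                continue
            seq = str(rec.seq)
            if uppercase:
                seq = seq.upper()
            yielded += 1
            yield ChromosomeRecord(name=rec.id, sequence=seq)
    if yielded == 0:
        if wanted is not None:
            warnings.warn(
                f"no chromosome matched filter {sorted(wanted)} in {path}",
                stacklevel=2,
            )
        else:
            warnings.warn(f"empty FASTA file: {path}", stacklevel=2)


def write_fasta(
    records: Iterable[ChromosomeRecord],
    path: str | Path,
    line_width: int = 60,
) -> None:
    with open(path, "wt", encoding="ascii") as out:
        for rec in records:
            out.write(f">{rec.name}\n")
            for i in range(0, rec.length, line_width):
                out.write(rec.sequence[i : i + line_width] + "\n")


def _require_sorted(items, key, what: str) -> None:
    prev = None
    for item in items:
        k = key(item)
        if prev is not None and k < prev:
            raise ValueError(f"{what} must be sorted by (chromosome, start)")
        prev = k


def write_hits_bed(hits: Sequence, path: str | Path) -> None:
    """Write dyad hits as BED6: name is the motif label, score the run length.

    Hits must already be sorted by (chromosome, start); unsorted input is
    the caller's bug and raises.
    """
    _require_sorted(hits, lambda h: (h.chromosome, h.start), "hits")
    with open(path, "wt", encoding="ascii") as out:
        for h in hits:
            out.write(
                f"{h.chromosome}\t{h.start}\t{h.end}\t{h.motif.label}"
                f"\t{h.run_length}\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path):
    """Read a BED6 file written by :func:`write_hits_bed` back into hits."""
    from .dyad_scan import DyadHit, Motif, parse_motif_label

    hits = []
    with open(path, "rt", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = fields[:6]
            core, reps = parse_motif_label(name)
            hits.append(
                DyadHit(
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    motif=Motif(core=core, repetitions=reps),
                    run_length=int(score),
                    strand=strand,
                )
            )
    return hits


def format_probability(probability: float, log10_probability: float) -> str:
    if probability == 0.0:
        return "0"
    if probability >= 1e-4:
        return f"{probability:.9g}"
    return f"{probability:.8E}"


def format_log10(log10_probability: float) -> str:
    return f"{log10_probability:.6f}"


HITS_TSV_COLUMNS = ["chrom", "start_1based", "end_1based", "motif", "run_length", "strand"]


def write_hits_tsv(hits: Sequence, path: str | Path) -> None:
    """1-based inclusive mirror of the BED output, with a header row."""
    _require_sorted(hits, lambda h: (h.chromosome, h.start), "hits")
    with open(path, "wt", encoding="ascii") as out:
        out.write("\t".join(HITS_TSV_COLUMNS) + "\n")
        for h in hits:
            out.write(
                f"{h.chromosome}\t{h.start + 1}\t{h.end}\t{h.motif.label}"
                f"\t{h.run_length}\t{h.strand}\n"
            )


def colony_tsv_columns(motif_cores: Sequence[str]) -> list[str]:
    return (
        ["name", "chrom", "start", "end", "size", "formula", "homogeneous"]
        + [f"n_{core}" for core in motif_cores]
        + ["probability", "log10_probability"]
    )


def write_colonies_tsv(
    colonies: Sequence,
    path: str | Path,
    motif_cores: Sequence[str] = ("GGC", "GCC"),
) -> None:
    with open(path, "wt", encoding="ascii") as out:
        out.write("\t".join(colony_tsv_columns(motif_cores)) + "\n")
        for c in colonies:
            counts = [str(c.composition.get(core, 0)) for core in motif_cores]
            if c.probability is None:
                prob, logp = "NA", "NA"
            else:
                prob = format_probability(c.probability, c.log10_probability)
                logp = format_log10(c.log10_probability)
            row = [
                c.name,
                c.chromosome,
                str(c.start),
                str(c.end),
                str(c.size),
                c.formula,
                str(c.homogeneous).lower(),
                *counts,
                prob,
                logp,
            ]
            out.write("\t".join(row) + "\n")


def read_colonies_tsv(path: str | Path):
    """Read a colony TSV written by :func:`write_colonies_tsv`.

    Members are not serialized, so the returned colonies carry size,
    composition and formula but ``members=None``.
    """
    from .colony import Colony

    colonies = []
    with open(path, "rt", encoding="ascii") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("chrom", "start", "end", "size", "formula"):
            if name not in idx:
                raise DataError(f"{path}: missing colony TSV column {name!r}")
        core_cols = [h for h in header if h.startswith("n_")]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            composition = {
                col[2:]: int(fields[idx[col]])
                for col in core_cols
                if int(fields[idx[col]]) > 0
            }
            colonies.append(
                Colony(
                    chromosome=fields[idx["chrom"]],
                    start=int(fields[idx["start"]]),
                    end=int(fields[idx["end"]]),
                    size=int(fields[idx["size"]]),
                    formula=fields[idx["formula"]],
                    composition=composition,
                )
            )
    return colonies


def write_colonies_bed(colonies: Sequence, path: str | Path) -> None:
    """Colony spans as BED: name is the composition formula, score the size."""
    with open(path, "wt", encoding="ascii") as out:
        for c in colonies:
            out.write(f"{c.chromosome}\t{c.start}\t{c.end}\t{c.formula}\t{c.size}\t+\n")
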