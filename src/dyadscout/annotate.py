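"""Gene-model annotation of colonies.

Each colony is classified against a gene model (GFF3, Ensembl dialect, or a
BED of gene spans): colonies overlapping a gene (or its promoter window)
are *intragenic* and labelled with the finest overlapped feature of the
gene's canonical transcript — 5'UTR / 3'UTR / exon / intron (with the
ordinal counted in transcript orientation, "Intron 25" style) or promoter.
All other colonies are *intergenic* and labelled with the nearest gene,
the edge-to-edge distance in bp, and the direction (upstream/downstream)
relative to that gene's strand.

All coordinates are 0-based half-open in memory; GFF3's 1-based inclusive
coordinates are converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils

from .colony import Colony
from .errors import DataError


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]  # genomic order
    utr5: Tuple[Tuple[int, int], ...] = ()
    utr3: Tuple[Tuple[int, int], ...] = ()
    canonical_tag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str = ""
    transcripts: Tuple[Transcript, ...] = ()


@dataclass
class GeneModel:
    genes: List[Gene]

    def __post_init__(self) -> None:
        self.by_chromosome: Dict[str, List[Gene]] = {}
        for g in self.genes:
            self.by_chromosome.setdefault(g.chromosome, []).append(g)
        for genes in self.by_chromosome.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))


@dataclass
class GenicContext:
    """A colony's relation to the gene model (one per colony)."""

    colony_id: str
    category: str  # "intragenic" | "intergenic"
    feature: Optional[str] = None  # intron / exon / 5'UTR / 3'UTR / promoter
    feature_ordinal: Optional[int] = None
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    biotype: Optional[str] = None
    nearest_gene: Optional[str] = None
    distance_bp: int = 0
    direction: Optional[str] = None  # "upstream" | "downstream"

    def location_text(self) -> str:
        """Human-readable location, "Intergenic (5 kb downstream of CDH4)" style."""
        if self.category == "intragenic":
            feat = self.feature or "gene body"
            if self.feature_ordinal is not None:
                feat = f"{feat} {self.feature_ordinal}"
            return f"{self.gene_id} ({feat})"
        if self.nearest_gene is None:
            return "Intergenic (no gene on chromosome)"
        return (
            f"Intergenic ({round(self.distance_bp / 1000)} kb "
            f"{self.direction} of {self.nearest_gene})"
        )


def _attr_first(feature, *names: str) -> str:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return ""


def _is_canonical(feature) -> bool:
    tags = feature.attributes.get("tag", [])
    return any("canonical" in t.lower() for t in tags)


_TRANSCRIPT_TYPES = {
    "mRNA",
    "transcript",
    "lnc_RNA",
    "lncRNA",
    "pseudogenic_transcript",
    "ncRNA",
    "snRNA",
    "snoRNA",
    "rRNA",
    "tRNA",
    "miRNA",
}


def load_gene_model(path: str | Path) -> GeneModel:
    """Load genes from GFF3 (via gffutils) or from a BED file.

    BED input (detected by extension .bed) yields one single-exon
    transcript per gene line, with an optional 7th column as biotype.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"gene model not found: {path}")
    if path.suffix.lower() == ".bed":
        return _load_bed_genes(path)
    return _load_gff3(path)


def _load_bed_genes(path: Path) -> GeneModel:
    genes = []
    with open(path, "rt", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            biotype = fields[6] if len(fields) > 6 else ""
            s, e = int(start), int(end)
            tx = Transcript(
                transcript_id=f"{name}.t1", start=s, end=e, strand=strand,
                exons=((s, e),),
            )
            genes.append(
                Gene(name, chrom, s, e, strand, biotype, transcripts=(tx,))
            )
    return GeneModel(genes)


def _load_gff3(path: Path) -> GeneModel:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[Gene] = []
    for g in db.features_of_type("gene"):
        transcripts: List[Transcript] = []
        for t in db.children(g, level=1):
            if t.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = tuple(
                sorted(
                    (e.start - 1, e.end)
                    for e in db.children(t, featuretype="exon")
                )
            )
            utr5 = tuple(
                sorted(
                    (u.start - 1, u.end)
                    for u in db.children(t, featuretype="five_prime_UTR")
                )
            )
            utr3 = tuple(
                sorted(
                    (u.start - 1, u.end)
                    for u in db.children(t, featuretype="three_prime_UTR")
                )
            )
            transcripts.append(
                Transcript(
                    transcript_id=t.id,
                    start=t.start - 1,
                    end=t.end,
                    strand=t.strand,
                    exons=exons or ((t.start - 1, t.end),),
                    utr5=utr5,
                    utr3=utr3,
                    canonical_tag=_is_canonical(t),
                )
            )
        genes.append(
            Gene(
                gene_id=_attr_first(g, "Name", "gene_name") or g.id,
                chromosome=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                biotype=_attr_first(g, "biotype", "gene_biotype"),
                transcripts=tuple(transcripts),
            )
        )
    if not genes:
        raise DataError(f"gene model {path} contains no gene features")
    return GeneModel(genes)


def select_canonical_transcript(gene: Gene) -> Transcript:
    """Deterministic representative transcript of a gene.

    A transcript tagged canonical wins; otherwise the longest span;
    remaining ties break lexicographically on the transcript ID.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return min(
        gene.transcripts,
        key=lambda t: (not t.canonical_tag, -t.length, t.transcript_id),
    )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _promoter_interval(tx: Transcript, promoter_bp: int) -> Tuple[int, int]:
    if tx.strand == "-":
        return tx.end, tx.end + promoter_bp
    return max(0, tx.start - promoter_bp), tx.start


def _transcript_segments(
    tx: Transcript, promoter_bp: int
) -> List[Tuple[int, str, Optional[int], int, int]]:
    """(class_rank, label, ordinal, start, end) for every feature segment.

    class_rank orders feature priority: UTR (0) and exon (1) before
    intron (2) before promoter (3). Ordinals count in transcript (5'->3')
    orientation.
    """
    segments: List[Tuple[int, str, Optional[int], int, int]] = []
    n_exons = len(tx.exons)
    for i, (s, e) in enumerate(tx.exons):
        ordinal = i + 1 if tx.strand == "+" else n_exons - i
        segments.append((1, "exon", ordinal, s, e))
    for i in range(n_exons - 1):
        s, e = tx.exons[i][1], tx.exons[i + 1][0]
        if s >= e:
            continue
        ordinal = i + 1 if tx.strand == "+" else n_exons - 1 - i
        segments.append((2, "intron", ordinal, s, e))
    for s, e in tx.utr5:
        segments.append((0, "5'UTR", None, s, e))
    for s, e in tx.utr3:
        segments.append((0, "3'UTR", None, s, e))
    ps, pe = _promoter_interval(tx, promoter_bp)
    if pe > ps:
        segments.append((3, "promoter", None, ps, pe))
    return segments


def _classify_within_transcript(
    colony: Colony, tx: Transcript, promoter_bp: int
) -> Optional[Tuple[str, Optional[int]]]:
    overlapped = [
        seg
        for seg in _transcript_segments(tx, promoter_bp)
        if _overlap(colony.start, colony.end, seg[3], seg[4]) > 0
    ]
    if not overlapped:
        return None

    def sort_key(seg):
        class_rank, _label, _ordinal, s, e = seg
        # 5'-most overlapped *region* wins within a class (exon/UTR together);
        # on a tie, UTR labels beat the exon that contains them
        ov_start = max(colony.start, s)
        ov_end = min(colony.end, e)
        five_prime_pos = ov_start if tx.strand == "+" else -ov_end
        group = 0 if class_rank <= 1 else class_rank
        return (group, five_prime_pos, class_rank)

    _rank, label, ordinal, _s, _e = min(overlapped, key=sort_key)
    return label, ordinal


def _gene_effective_span(gene: Gene, promoter_bp: int) -> Tuple[int, int]:
    spans = [(gene.start, gene.end)]
    for tx in gene.transcripts:
        spans.append(_promoter_interval(tx, promoter_bp))
    return min(s for s, _ in spans), max(e for _, e in spans)


def annotate_colonies(
    colonies: Sequence[Colony],
    gene_model: GeneModel,
    promoter_bp: int = 1000,
) -> List[GenicContext]:
    """Assign every colony exactly one GenicContext.

    Intragenic assignment prefers the gene with the largest span overlap
    (ties break on gene ID) and classifies against its canonical transcript,
    falling back to other transcripts if the canonical one does not cover
    the colony. Intergenic distance is measured between closest span edges.
    """
    warned_chromosomes = set()
    contexts: List[GenicContext] = []
    for colony in colonies:
        colony_id = f"{colony.chromosome}:{colony.start}-{colony.end}"
        genes = gene_model.by_chromosome.get(colony.chromosome, [])
        if not genes:
            if colony.chromosome not in warned_chromosomes:
                warnings.warn(
                    f"chromosome {colony.chromosome} absent from gene model",
                    stacklevel=2,
                )
                warned_chromosomes.add(colony.chromosome)
            contexts.append(GenicContext(colony_id, "intergenic"))
            continue

        overlapping = []
        for g in genes:
            s, e = _gene_effective_span(g, promoter_bp)
            ov = _overlap(colony.start, colony.end, s, e)
            if ov > 0:
                overlapping.append((ov, g))
        if overlapping:
            _ov, gene = max(overlapping, key=lambda t: (t[0], t[1].gene_id))
            canonical = select_canonical_transcript(gene)
            hit = _classify_within_transcript(colony, canonical, promoter_bp)
            tx = canonical
            if hit is None:
                for other in sorted(
                    gene.transcripts, key=lambda t: t.transcript_id
                ):
                    hit = _classify_within_transcript(colony, other, promoter_bp)
                    if hit is not None:
                        tx = other
                        break
            if hit is None:
                # inside the gene span but in no transcript of it
                feature, ordinal = "intron", None
            else:
                feature, ordinal = hit
            contexts.append(
                GenicContext(
                    colony_id,
                    "intragenic",
                    feature=feature,
                    feature_ordinal=ordinal,
                    gene_id=gene.gene_id,
                    transcript_id=tx.transcript_id,
                    biotype=gene.biotype,
                    distance_bp=0,
                )
            )
            continue

        # intergenic: nearest gene by closest span edges
        def edge_distance(g: Gene) -> int:
            if colony.end <= g.start:
                return g.start - colony.end
            if g.end <= colony.start:
                return colony.start - g.end
            return 0

        nearest = min(genes, key=lambda g: (edge_distance(g), g.gene_id))
        dist = edge_distance(nearest)
        if colony.end <= nearest.start:
            direction = "upstream" if nearest.strand == "+" else "downstream"
        else:
            direction = "downstream" if nearest.strand == "+" else "upstream"
        contexts.append(
            GenicContext(
                colony_id,
                "intergenic",
                nearest_gene=nearest.gene_id,
                biotype=nearest.biotype,
                distance_bp=dist,
                direction=direction,
            )
        )
    return contexts


ANNOTATION_TSV_COLUMNS = [
    "colony_id",
    "name",
    "size",
    "formula",
    "category",
    "location",
    "feature",
    "feature_ordinal",
    "gene_id",
    "transcript_id",
    "biotype",
    "nearest_gene",
    "distance_bp",
    "direction",
]


def write_annotations_tsv(
    colonies: Sequence[Colony],
    contexts: Sequence[GenicContext],
    path: str | Path,
) -> None:
    """TSV join of colonies and their genic contexts (one row per colony)."""
    with open(path, "wt", encoding="ascii") as out:
        out.write("\t".join(ANNOTATION_TSV_COLUMNS) + "\n")
        for colony, ctx in zip(colonies, contexts):
            row = [
                ctx.colony_id,
                colony.name,
                str(colony.size),
                colony.formula,
                ctx.category,
                ctx.location_text(),
                ctx.feature or "",
                "" if ctx.feature_ordinal is None else str(ctx.feature_ordinal),
                ctx.gene_id or "",
                ctx.transcript_id or "",
                ctx.biotype or "",
                ctx.nearest_gene or "",
                str(ctx.distance_bp),
                ctx.direction or "",
            ]
            out.write("\t".join(row) + "\n")
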