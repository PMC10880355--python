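import pytest

from dyadscout import (
    Colony,
    GeneImplant,
    annotate_colonies,
    load_gene_model,
    select_canonical_transcript,
)
from dyadscout.annotate import Gene, Transcript
from dyadscout.fixtures import render_gff3


def colony(chrom, start, end, size=2, formula="[(GGC)2]2", comp=None):
    return Colony(chrom, start, end, size, formula, comp or {"GGC": size})


def gene_model(tmp_path, *implants):
    p = tmp_path / "genes.gff3"
    p.write_text(render_gff3(implants))
    return load_gene_model(p)


TWO_EXON_GENE = GeneImplant(
    "chr1", 10_000, 20_000, strand="+", gene_id="GENEA",
    biotype="protein_coding",
    exons=((10_000, 10_500), (19_500, 20_000)),
    utr5=((10_000, 10_100),),
    utr3=((19_900, 20_000),),
)


def test_colony_in_first_intron(tmp_path):
    model = gene_model(tmp_path, TWO_EXON_GENE)
    (ctx,) = annotate_colonies([colony("chr1", 12_000, 12_400)], model)
    assert ctx.category == "intragenic"
    assert (ctx.feature, ctx.feature_ordinal) == ("intron", 1)
    assert ctx.gene_id == "GENEA"
    assert ctx.biotype == "protein_coding"
    assert ctx.distance_bp == 0
    assert ctx.location_text() == "GENEA (intron 1)"


def test_intron_ordinal_counts_from_the_transcripts_5_prime_end(tmp_path):
    minus = GeneImplant(
        "chr1", 10_000, 20_000, strand="-", gene_id="GENEB",
        exons=((10_000, 10_500), (14_000, 14_500), (19_500, 20_000)),
    )
    model = gene_model(tmp_path, minus)
    # genomically-first intron is the transcript's last (2nd) on the minus strand
    (ctx,) = annotate_colonies([colony("chr1", 12_000, 12_400)], model)
    assert (ctx.feature, ctx.feature_ordinal) == ("intron", 2)


def test_exon_and_utr_take_priority_over_intron(tmp_path):
    model = gene_model(tmp_path, TWO_EXON_GENE)
    # straddles the exon-1 / intron-1 boundary: the 5'-most feature wins
    (ctx,) = annotate_colonies([colony("chr1", 10_400, 10_700)], model)
    assert (ctx.feature, ctx.feature_ordinal) == ("exon", 1)
    (ctx,) = annotate_colonies([colony("chr1", 10_050, 10_090)], model)
    assert ctx.feature == "5'UTR"
    (ctx,) = annotate_colonies([colony("chr1", 19_950, 19_990)], model)
    assert ctx.feature == "3'UTR"


def test_promoter_window_upstream_of_tss(tmp_path):
    model = gene_model(tmp_path, TWO_EXON_GENE)
    (ctx,) = annotate_colonies([colony("chr1", 9_400, 9_600)], model, promoter_bp=1000)
    assert ctx.category == "intragenic"
    assert ctx.feature == "promoter"
    # outside the promoter window the same colony is intergenic
    (ctx,) = annotate_colonies([colony("chr1", 9_400, 9_600)], model, promoter_bp=100)
    assert ctx.category == "intergenic"
    assert ctx.direction == "upstream"


def test_intergenic_downstream_distance(tmp_path):
    model = gene_model(tmp_path, TWO_EXON_GENE)
    (ctx,) = annotate_colonies([colony("chr1", 25_000, 25_300)], model)
    assert ctx.category == "intergenic"
    assert ctx.nearest_gene == "GENEA"
    assert ctx.distance_bp == 5_000
    assert ctx.direction == "downstream"
    assert ctx.location_text() == "Intergenic (5 kb downstream of GENEA)"


def test_strand_flip_swaps_direction_labels_keeps_distance(tmp_path):
    plus = gene_model(tmp_path, TWO_EXON_GENE)
    minus_implant = GeneImplant(
        "chr1", 10_000, 20_000, strand="-", gene_id="GENEA",
        exons=TWO_EXON_GENE.exons,
    )
    minus = gene_model(tmp_path, minus_implant)
    c = [colony("chr1", 25_000, 25_300)]
    ctx_plus = annotate_colonies(c, plus)[0]
    ctx_minus = annotate_colonies(c, minus)[0]
    assert ctx_plus.distance_bp == ctx_minus.distance_bp == 5_000
    assert {ctx_plus.direction, ctx_minus.direction} == {"upstream", "downstream"}


def test_gene_free_chromosome_warns_and_leaves_nearest_unset(tmp_path):
    model = gene_model(tmp_path, TWO_EXON_GENE)
    with pytest.warns(UserWarning, match="chrZ"):
        (ctx,) = annotate_colonies([colony("chrZ", 0, 100)], model)
    assert ctx.category == "intergenic"
    assert ctx.nearest_gene is None


def test_every_colony_gets_exactly_one_context(tmp_path):
    model = gene_model(tmp_path, TWO_EXON_GENE)
    colonies = [
        colony("chr1", s, s + 200) for s in (500, 9_800, 12_000, 19_600, 30_000)
    ]
    contexts = annotate_colonies(colonies, model)
    assert len(contexts) == len(colonies)
    for ctx in contexts:
        if ctx.category == "intragenic":
            assert ctx.distance_bp == 0 and ctx.feature is not None
        else:
            assert ctx.nearest_gene == "GENEA"


def _tx(tid, start, end, canonical=False):
    return Transcript(tid, start, end, "+", exons=((start, end),), canonical_tag=canonical)


def test_canonical_transcript_selection_rules():
    single = Gene("G", "chr1", 0, 500, "+", transcripts=(_tx("T1", 0, 500),))
    assert select_canonical_transcript(single).transcript_id == "T1"

    by_length = Gene(
        "G", "chr1", 0, 700, "+",
        transcripts=(_tx("T1", 0, 500), _tx("T2", 0, 700)),
    )
    assert select_canonical_transcript(by_length).transcript_id == "T2"

    tie = Gene(
        "G", "chr1", 0, 500, "+",
        transcripts=(_tx("T2", 0, 500), _tx("T1", 0, 500)),
    )
    assert select_canonical_transcript(tie).transcript_id == "T1"

    tagged = Gene(
        "G", "chr1", 0, 700, "+",
        transcripts=(_tx("T1", 0, 700), _tx("T2", 0, 500, canonical=True)),
    )
    assert select_canonical_transcript(tagged).transcript_id == "T2"


def test_bed_gene_model(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text("chr1\t1000\t2000\tMYGENE\t0\t+\tlncRNA\n")
    model = load_gene_model(p)
    (ctx,) = annotate_colonies([colony("chr1", 1_200, 1_300)], model)
    assert ctx.category == "intragenic"
    assert ctx.gene_id == "MYGENE"
    assert ctx.biotype == "lncRNA"
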