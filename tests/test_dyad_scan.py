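import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadscout import (
    ChromosomeRecord,
    DataError,
    Motif,
    RunPolicy,
    ScanConfig,
    StrandPolicy,
    reverse_strand_hits,
    scan_genome,
    scan_sequence,
)
from oracles import random_dna, regex_maximal_runs

GGC = Motif("GGC")
GCC = Motif("GCC")
GGC_ONLY = ScanConfig(motifs=(GGC,))
BOTH = ScanConfig(motifs=(GGC, GCC))


def rec(seq, name="chr1"):
    return ChromosomeRecord(name, seq)


@pytest.mark.parametrize(
    "sequence, config, expected",
    [
        # definitional dyad
        ("GGCGGC", GGC_ONLY, [(0, 6, 2)]),
        # maximal run reported once
        ("GGCGGCGGC", GGC_ONLY, [(0, 9, 3)]),
        # scan resumes after a mismatch
        ("GGCAGGCGGC", GGC_ONLY, [(4, 10, 2)]),
        # N never matches
        ("GGCGGN", GGC_ONLY, []),
        # no core is tandemly repeated
        ("GGCGCC", BOTH, []),
        # abutting runs of the two motifs; independent per-motif scans
        ("GGCGGCGCCGCC", BOTH, [(0, 6, 2), (6, 12, 2)]),
        # sequence shorter than the 6-bp window
        ("GGCGG", GGC_ONLY, []),
        ("", GGC_ONLY, []),
    ],
)
def test_scan_examples(sequence, config, expected):
    hits = scan_sequence(rec(sequence), config)
    assert [(h.start, h.end, h.run_length) for h in hits] == expected


def test_hit_invariants_on_random_sequence():
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 20_000, with_n=True)
    hits = scan_sequence(rec(seq), BOTH)
    for h in hits:
        core = h.motif.core
        assert h.end - h.start == h.run_length * len(core)
        assert seq[h.start : h.end] == core * h.run_length
    # non-overlap per motif
    for motif in (GGC, GCC):
        spans = [(h.start, h.end) for h in hits if h.motif == motif]
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
    assert hits == sorted(hits, key=lambda h: h.start)


@pytest.mark.parametrize("seed", range(12))
def test_scan_matches_regex_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 10_000, with_n=seed % 3 == 0)
    for core in ("GGC", "GCC", "AT"):
        hits = scan_sequence(rec(seq), ScanConfig(motifs=(Motif(core),)))
        assert [(h.start, h.end, h.run_length) for h in hits] == regex_maximal_runs(
            seq, core
        )


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", max_size=400))
def test_scan_equals_oracle_property(seq):
    hits = scan_sequence(rec(seq), GGC_ONLY)
    assert [(h.start, h.end, h.run_length) for h in hits] == regex_maximal_runs(
        seq, "GGC"
    )


@pytest.mark.parametrize("seed", range(6))
def test_strand_mirror_symmetry(seed):
    """(GGC)2 hits on S are the coordinate mirror of (GCC)2 hits on revcomp(S)."""
    rng = np.random.default_rng(100 + seed)
    seq = random_dna(rng, 5_000)
    fwd = scan_sequence(rec(seq), GGC_ONLY)
    rc = scan_sequence(rec(reverse_complement(seq)), ScanConfig(motifs=(GCC,)))
    n = len(seq)
    mirrored = sorted((n - h.end, n - h.start) for h in rc)
    assert mirrored == [(h.start, h.end) for h in fwd]


def test_reverse_strand_hits_equal_forward_revcomp_core():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 5_000)
    record = rec(seq)
    rev = reverse_strand_hits(record, GGC)
    fwd_gcc = scan_sequence(record, ScanConfig(motifs=(GCC,)))
    assert [(h.start, h.end, h.run_length) for h in rev] == [
        (h.start, h.end, h.run_length) for h in fwd_gcc
    ]
    assert all(h.strand == "-" for h in rev)


def test_both_dedup_reports_each_interval_once():
    config = ScanConfig(motifs=(GGC, GCC), strand_policy=StrandPolicy.BOTH_DEDUP)
    hits = scan_sequence(rec("GGCGGC"), config)
    assert len(hits) == 1
    # with a single motif, both_dedup picks up the reverse-strand image
    config = ScanConfig(motifs=(GGC,), strand_policy=StrandPolicy.BOTH_DEDUP)
    hits = scan_sequence(rec("GCCGCCTTTGGCGGC"), config)
    assert [(h.start, h.end, h.strand) for h in hits] == [
        (0, 6, "-"),
        (9, 15, "+"),
    ]


def test_n_block_insertion_only_offsets_downstream_hits():
    left, right = "GGCGGCA", "TGCCGCC"
    base = scan_sequence(rec(left + right), BOTH)
    shifted = scan_sequence(rec(left + "N" * 10 + right), BOTH)
    assert [(h.start, h.end) for h in base] == [(0, 6), (8, 14)]
    assert [(h.start, h.end) for h in shifted] == [(0, 6), (18, 24)]


@pytest.mark.parametrize(
    "policy, expected",
    [
        (RunPolicy.MAXIMAL_RUN_ONE_HIT, [(0, 15, 5)]),
        (RunPolicy.EXACT_TWO_ONLY, []),
        (RunPolicy.FLOOR_PAIRS, [(0, 6, 2), (6, 12, 2)]),
    ],
)
def test_run_policies_on_a_five_copy_run(policy, expected):
    config = ScanConfig(motifs=(GGC,), run_policy=policy)
    hits = scan_sequence(rec("GGC" * 5), config)
    assert [(h.start, h.end, h.run_length) for h in hits] == expected


def test_run_policies_agree_on_exact_double_runs():
    seq = "GGCGGCTTTTGGCGGC"
    results = {
        policy: scan_sequence(rec(seq), ScanConfig(motifs=(GGC,), run_policy=policy))
        for policy in RunPolicy
    }
    spans = {p: [(h.start, h.end) for h in hits] for p, hits in results.items()}
    assert all(s == [(0, 6), (10, 16)] for s in spans.values())


def test_softmasked_stretches_are_skipped_when_configured():
    record = rec("ggcggcTTGGCGGC")
    masked = scan_sequence(record, ScanConfig(motifs=(GGC,), skip_softmasked=True))
    assert [(h.start, h.end) for h in masked] == [(8, 14)]


def test_scan_genome_totals_and_streaming():
    records = [rec("GGCGGC", "chr1"), rec("GCCGCC", "chr2")]
    result = scan_genome(iter(records), BOTH)
    assert result.totals_by_motif == {"(GGC)2": 1, "(GCC)2": 1}
    assert result.total_hits == sum(
        len(h) for h in result.hits_by_chromosome.values()
    )


def test_scan_genome_empty_and_duplicates():
    assert scan_genome(iter([]), BOTH).total_hits == 0
    with pytest.raises(DataError, match="duplicate"):
        scan_genome(iter([rec("ACGT", "chr1"), rec("ACGT", "chr1")]), BOTH)


def test_scan_genome_random_sequence_matches_oracle():
    rng = np.random.default_rng(42)
    seq = random_dna(rng, 10_000)
    result = scan_genome(iter([rec(seq)]), BOTH)
    assert result.totals_by_motif["(GGC)2"] == len(regex_maximal_runs(seq, "GGC"))
    assert result.totals_by_motif["(GCC)2"] == len(regex_maximal_runs(seq, "GCC"))


@pytest.mark.parametrize(
    "core, reps, message",
    [("", 2, "non-empty"), ("GGX", 2, "ACGT"), ("GGC", 1, "repetitions")],
)
def test_motif_validation(core, reps, message):
    with pytest.raises(ValueError, match=message):
        Motif(core, reps)


def test_motif_window_and_label():
    assert GGC.window == 6
    assert GGC.label == "(GGC)2"
    assert GGC.reverse_complement() == GCC
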