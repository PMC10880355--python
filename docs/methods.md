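# Methods

## Dyad extraction

A motif is `repetitions` tandem copies of a `core` over {A,C,G,T}; the
default motifs are (GGC)2 and (GCC)2 (core length 3, two copies, 6-bp
match window). The scanner walks each chromosome left to right: at the
first position where the window equals the doubled core it extends the
match rightward by whole core copies for as long as they continue,
records the *maximal run*, and resumes scanning at the run's end, so hits
for one motif never overlap. The inner loop uses `str.find` for the seed
window, which is the same character-by-character comparison executed in C.
Any character outside the core — assembly-gap `N`, IUPAC ambiguity codes,
or lowercase bases when soft-masked stretches are being skipped — simply
never matches, so no special-casing is needed.

Two aspects of run handling are genuinely open and therefore configurable:

- **Run policy** (`maximal` default, `exact`, `floor_pairs`). A maximal
  run of n ≥ 2 copies is reported as one hit with `run_length = n`;
  alternatives report only exact double-copy runs, or tile the run with
  ⌊n/2⌋ double-copy hits. All three agree whenever runs are exact doubles.
- **Strand policy** (`forward` default, `both_dedup`). The reverse-strand
  image of a dyad motif occupies the same forward-strand interval as the
  dyad of the reverse-complemented core (revcomp((GGC)2) = (GCC)2), so
  scanning both strands for both default motifs double-counts every site.
  The default scans the forward strand per motif — the only convention
  consistent with *unequal* genome-wide GGC/GCC totals — and `both_dedup`
  adds reverse-strand images with interval-level deduplication for
  single-motif scans.

Sequences shorter than the window yield an empty result rather than an
error. Per-motif scans are independent: runs of different motifs may abut
(gap 0) but cannot overlap.

## Colony detection

Hits from all motifs are merged, sorted by (chromosome, start), and
chained single-linkage: a new chain starts whenever the inter-hit gap
(end of previous to start of next) reaches the threshold. The comparison
is strict — "within < 500 bp" — so a gap of exactly 500 bp breaks the
chain, and a gap of 0 chains. Chains with fewer than `min_size` members
(default 2) are discarded. Because hits are non-overlapping and sorted,
single-pass chaining is equivalent to connected components of the
all-pairs gap graph; the test suite asserts this equivalence against an
independent union-find implementation.

The composition formula is the run-length encoding of the ordered member
motifs (`[(GGC)2]11 [(GCC)2]5`; singleton blocks render bare, `(GCC)2`).
Reports name a colony `C<size>`; note that a mixed colony's size and its
leading block length differ (a 70-GGC + 1-GCC colony has size 71 but
formula `[(GGC)2]70 (GCC)2`), so both are always reported.

## Poisson scoring

Dyads are modelled as a homogeneous Poisson process: the count in a fixed
window of `window_bp` bases is Poisson with

λ = window_bp · dyad_count / genome_size_bp.

Defaults: `window_bp = 26,000` (a required, visible parameter — it is an
empirical window constant, not derivable from the data), `genome_size_bp
= 3e9` (the nominal genome size, deliberately not the exact assembly
length), and `dyad_count` = the number of **colony-member** dyads, not the
raw genome-wide hit total. With the reference human values (26,199 members)
this gives λ ≈ 0.227058, and the resulting densities match the published
colony-size probability table to the printed precision at every size from
2 to 99 — which is the calibration evidence for using the member count;
the raw-total alternative remains available through `--dyad-count`.

The pmf is computed as log p = −λ + k·ln λ − ln Γ(k+1) (via `lgamma`),
divided by ln 10 for the log10 report. Linear values below the smallest
positive double (≈ 5e−324, first crossed near k = 219 under the default
model) are reported as 0 with a finite log10 value. The tests verify the
normalization Σₖ p(k) = 1 (to 1e−12 for λ < 10), the recurrence
p(k+1)/p(k) = λ/(k+1) in log space, and agreement with
`scipy.stats.poisson.logpmf` into the deep tail.

Chromosome-distribution randomness is assessed with a Pearson chi-square
goodness-of-fit test against expected counts proportional to chromosome
length (df = #chromosomes − 1), with per-chromosome standardized residuals
(obs − exp)/√exp to localize deviations. P-values are reported raw; no
multiple-testing correction is applied. This is a deliberate
interpretation choice: the proportionality claim names no specific test,
and chi-square goodness-of-fit is the standard instrument for it.

## Annotation

Gene models load from GFF3 (via `gffutils`, in-memory database; `biotype`
attribute honoured) or from BED (one single-exon transcript per line,
optional 7th biotype column). The canonical transcript of a gene is the
one tagged canonical, else the longest, ties broken lexicographically on
transcript ID.

A colony overlapping a gene span or its promoter window (default 1,000 bp
upstream of the TSS) is *intragenic* with distance 0; it takes the feature
of the canonical transcript chosen by (1) class priority exon/UTR >
intron > promoter and (2) within a class, the feature whose overlapped
region is 5'-most in transcript orientation, with UTR labels beating the
exon that contains them on ties. Intron/exon ordinals count 5'→3' in the
transcript. If the canonical transcript does not cover the colony, other
transcripts are tried in ID order; a colony inside the gene span but
outside every transcript falls back to an unnumbered intron label.
All other colonies are *intergenic*, labelled with the nearest gene by
closest span edges, the distance in bp (rendered as rounded kb in text
output), and upstream/downstream relative to that gene's strand. Every
colony receives exactly one context; colonies on chromosomes absent from
the gene model get an empty nearest-gene field plus a warning.

## Synthetic genomes (fixtures)

The fixture generator is truth-first: expected hits, colony spans and
formulas are computed arithmetically from the implant specification — the
truth clustering uses an all-pairs connected-components pass, a different
algorithm from the production chainer — and only then is the sequence
materialized. The random background (default GC fraction 0.41, human-like)
is *sanitized*: any accidental tandem run of a watched core that does not
coincide exactly with an implant is broken by a single deterministic base
substitution (choosing a base absent from all watched cores), iterated to
a fixed point. Truth tables are therefore exact, and fixture generation is
byte-deterministic for a fixed seed.

`null_genome` places exact double-copy dyads uniformly at random (via the
order-statistics spacing transform, minimum separation one base so runs
never merge) — the Poisson model's own null. The model's colony-size score
P(k) is the probability of finding k dyads in one 26-kb window, so the
null check compares the empirical fraction of disjoint 26-kb windows
containing exactly two dyads with p(2), at a density of 262 dyads per
30 Mb (the reference human density, scaled 1:100 so 200 replicates run in
seconds). Note what the fixtures do *not* emulate: real GC isochores,
repeat families, soft-masking structure or mutation processes — passing
fixture tests demonstrates algorithmic correctness (exact recovery of
known truth), not biological realism of the background.

## Scale and verification

Desk-scale verification uses synthetic genomes of 10–360 kb and
positional simulations of 30 Mb; the pipeline streams one chromosome at a
time and the scanner's seed search runs in C, so whole-assembly scans
(about 3 Gb) are a matter of minutes, but reproducing published
whole-genome hit totals requires downloading the assembly and is left to
the user (the counts also depend on the run/strand policy conventions
above, which the calibration against the probability table pins down only
indirectly). All quantities asserted in tests and printed by
`scripts/acceptance.py` are recomputed at run time.

## Known limitations

- Perfect repeats only: no mismatch-tolerant runs, no ambiguity codes in
  cores, no STR genotyping.
- The homogeneous Poisson null ignores GC heterogeneity; colony scores are
  descriptive significance measures, not calibrated genome-wide p-values,
  and no multiple-testing correction is applied.
- Colony "periodicity" (regular member spacing) is visible in the member
  coordinates but no summary metric is implemented.
- Annotation reports one feature label per colony; a colony spanning many
  features keeps only the highest-priority, 5'-most one.
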