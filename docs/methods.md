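# Methods

This note documents the analysis conventions, the synthetic-data model,
and the numerical and design choices behind `clipsplice`.

## Coordinates and transcript structure

All internal coordinates are 0-based half-open genomic intervals. GTF
(1-based closed) is converted at the I/O boundary; BED passes through
unchanged. Exons are stored sorted ascending by genomic position
regardless of strand; "upstream/downstream" always means transcript
orientation. The CDS is represented as a single genomic span (min..max of
all CDS segments); per-exon CDS pieces are recovered by intersection,
which yields the same region decomposition with a simpler invariant.
Region derivation labels exonic sequence before the CDS (in transcript
orientation) 5'UTR, after it 3'UTR, CDS within the span, and inter-exon
gaps intron; the four label classes tile the transcript span exactly.
Non-coding transcripts are excluded from region derivation and peak
annotation — the binding-site composition is defined over protein-coding
genes only. IUPAC ambiguity codes other than ACGT are normalised to N so
that GC content (G+C over non-N bases) stays unambiguous.

Splice sites are boundary coordinates: for each intron, the 5'SS at its
transcript-orientation start and the 3'SS at its end. A transcript with E
exons yields E−1 sites of each kind.

## Filtering conventions

* DE genes: adjusted p **strictly below** 0.05 and |log2FC| ≥ 1
  (|FC| ≥ 2). Records with missing adjusted p are dropped (they were
  filtered upstream by independent-filtering, not "significant").
* AS events: FDR ≤ 0.05 and |ΔPSI| ≥ 0.05, **both inclusive**, plus
  detection in ≥ 10 junction reads (inclusion + skipping) in either
  condition. Whether the read rule pools replicates within a condition or
  requires a single replicate to reach 10 is not uniquely determined by
  the conventions this pipeline follows; pooling — the weaker reading —
  is the default and `per_replicate_reads=True` selects the other.
* The table's ΔPSI column is authoritative. ΔPSI recomputed from the
  per-replicate inclusion levels is used only to emit a validation
  warning when the two disagree by more than 0.01; substituting it would
  silently change the semantics of the upstream caller.
* Event identity across comparisons is the tuple (event type, contig,
  strand, target-exon, flanking-exon coordinates); numeric event IDs are
  not stable across runs of splicing callers.

ΔPSI sign convention: positive ΔPSI (condition1 − condition2) means the
exon is included more in condition 1. When condition 1 is the
factor-present state, the "included" class (included when the factor is
present) therefore carries positive ΔPSI and "skipped" negative.

## Peak annotation and metaprofiles

A peak receives one label: among same-strand overlapping transcripts, the
(transcript, label) pair with maximal per-base overlap wins; ties break
by CDS > 5'UTR > 3'UTR > intron, then by the transcript with the longest
CDS, then by transcript id for determinism. Max-overlap with
exon-favouring priority reproduces the exon/intron binding dichotomy such
analyses report; antisense peaks receive no label and are excluded from
composition.

Metaprofile coverage is binary per anchor — the fraction of sites whose
base at a given offset is covered by at least one same-strand peak. The
inputs are peak intervals, not read-level coverage, so depth weighting
would be artificial. Offsets are transcript-orientation: offset 0 is the
first base downstream of the boundary (first intronic base at a 5'SS,
first exonic base at a 3'SS) and offset −1 the last base upstream of it.
Offsets running past the neighbouring feature still count in the
denominator, so profiles from transcripts with short features are not
inflated. The window (default ±300 nt) and the per-region bin count of
the scaled transcript profile (default 100) are declared defaults, not
values inferred from any published figure.

## Motif enrichment

Peak sequences are extracted strand-aware (minus-strand peaks
reverse-complemented) so motifs read in transcript orientation. Per
sequence, k-mer frequencies are counts over valid windows (windows
containing N are skipped). k defaults to 6 — the analyses this package
supports report hexamer motifs — and is configurable.

The background is, by default, a dinucleotide-preserving
(Altschul–Erickson) shuffle of the foreground itself, one shuffle per
peak, seeded. Dinucleotide shuffling is the conservative standard for RBP
motif work because it preserves local composition (CpA content, GC) that
mononucleotide shuffles destroy. Mononucleotide shuffling and a
user-supplied background are also available.

Each k-mer observed in either group is tested with a Welch
(unequal-variance) two-sample t-test on per-sequence frequencies — group
variances are not asserted equal anywhere — and ranked by ascending p,
then descending foreground mean. Degenerate k-mers with zero variance in
both groups get p = 1 when the means agree (no evidence) and p = 0 with
infinite t when they differ. Raw p-values are reported by default; a
Benjamini–Hochberg flag exists but the default matches the convention of
reporting raw motif p-values.

## Cassette-exon features

For each skipped-exon event: exon GC%, upstream/downstream intron GC%
(full intron length, no window cap), downstream-intron:exon GC ratio, and
upstream/downstream intron:exon length ratios, with upstream/downstream
in transcript orientation (Matt-style semantics). Events lacking a
flanking intron, or with a 0%-GC exon (undefined ratio), are skipped with
a logged reason. All features are invariant under genome-wide
reverse-complement plus strand flip, which the tests verify. Non-SE event
types are excluded by default: the features are defined on cassette
exons.

Group comparisons use a two-sided Mann–Whitney U-test: the exact
enumeration null for combined n ≤ 20 without ties, otherwise the normal
approximation with tie and continuity correction. The two paths agree to
|Δp| ≤ 0.01 at the boundary. Identical constant groups return p = 1.

## Integration

A peak is unique to a condition when no same-strand peak of the other
condition overlaps it by ≥ 1 nt; uniqueness is decided per peak, not per
transcript. The high-confidence window around a cassette exon is
[exon_start − f_up, exon_end + f_down) with f = 250 nt truncated to the
actual flanking-intron length, so the window is intronic by construction
and never reaches the neighbouring exon. Under half-open coordinates a
peak must cover at least one base at intron offset ≤ 249 to hit the
flank. The three-way cross-reference collapses everything to gene level
(expression is gene-level; splicing and binding are transcript-level): a
transcript counts as DE-bound when its gene is DE.

PSI from isoform abundances is 100 × larger isoform / total; the isoform
ratio is larger/smaller after each is normalised by a supplied
loading-control value (a shared control cancels).

## Synthetic-data model

The generator emulates the statistical structure the analysis assumes,
with planted, recorded ground truth:

* **Genes** — multi-exon (5–8 exons) protein-coding transcripts laid
  end-to-end on one contig, random strand; the CDS runs from the middle
  of the first exon to the middle of the last so both UTRs exist. Exon
  length ~ N(150, 30) nt (min 60); sequence is drawn per-base at a target
  GC (uniform within GC/AT), the simplest null for motif statistics.
* **Splicing classes** — each gene carries one planted class. Cassette
  (middle) exon GC targets: included 53.4%, skipped 50.0%,
  non-differential 51.2%; other exons 51.2%; introns 45%. With ~150 nt
  exons the per-exon binomial sd is ≈ 4 GC points, matching the observed
  spread of real exon GC. Intron lengths scale to per-class intron:exon
  length-ratio targets (included 12.4, skipped 19.5, non-differential
  14.2).
* **Peaks** — two conditions, 2000 peaks each by default, 50 nt, placed
  wholly inside a region of the planted label; region mixtures are
  allocated by exact count (unstimulated: 56.9% CDS / 25.8% intron /
  11.7% 5'UTR / 5.6% 3'UTR; stimulated: 83.2 / 8.9 / 4.5 / 3.3). With
  probability 0.3 a condition-specific hexamer (CACACA unstimulated,
  GAAGAA stimulated) is written into the genome inside the peak in
  transcript orientation; overlapping plantings never overwrite each
  other (colliding offsets are re-drawn, or the planting is skipped and
  recorded as absent).
* **AS table** — one event per gene in the rMATS JC dialect. Planted
  significant events (included: +ΔPSI in [0.10, 0.40]; skipped: the
  negative mirror) carry FDR ≤ 0.04 and ample junction reads;
  non-differential events fail the FDR rule or the |ΔPSI| rule; a planted
  "low-read" class looks significant but has < 10 reads in both
  conditions, exercising the read filter. Replicate inclusion levels are
  base PSI ± ΔPSI/2 plus N(0, sd) noise (sd = 0.01 default; 0 for exact
  recovery tests). Default counts (62 included / 35 skipped SE among 200
  events, 70% SE overall) echo the event-type composition and sign split
  of the motivating datasets at desk scale.
* **DE table** — one row per gene; planted up/down genes have
  |log2FC| ∈ [1, 4] and padj < 0.05, nulls fail exactly one rule.
* **Seeding** — one integer seed drives a master `SeedSequence`; children
  are spawned in the order genome, peaks, AS, DE, so sub-generators are
  reproducible in isolation. All planted counts are exact; randomness
  enters only placement and noise, making truth-recovery tests exact.

What the generator does **not** emulate: read-level data, peak-caller
behaviour, realistic splice-site motifs (GT/AG dinucleotides are not
written), isoform structure beyond one transcript per gene, correlated
replicate noise, and genome-scale gene counts. Passing tests therefore
validate the analysis arithmetic and its statistical calibration — not
the upstream callers, and not effect sizes on real genomes.

## Problem sizes and calibration checks

The default test and acceptance conditions are desk-scale: 60–200 genes,
300–2000 peaks per condition, 46–200 splicing events. The planted-motif
benchmark uses 500 peaks at insertion probability 0.3 over 20 seeded
replicates (top-3 recovery expected in ≥ 19); the feature-shift benchmark
draws exon GC as N(53, 4) vs N(50, 4), n = 300 per group, 100 replicates
for power and 1000 null replicates for type-I calibration (expected
0.05 ± 0.02). Full-scale percentages (binding composition, overlap
percentages) are recomputed from the reported full-scale counts, which
are inputs to ratio arithmetic, not re-derived from sequencing data.

## Known limitations

* One isoform per gene in synthetic mode; the isoform-anchoring question
  for real annotations is resolved by the longest-CDS tie-break, not by
  expression-aware isoform selection.
* The high-confidence rule is geometric; it does not model crosslink
  position within peaks or binding strength.
* Welch-t motif ranking is slightly sensitive to group size through the
  degrees of freedom (exact t-ordering, not p-ordering, is
  duplication-invariant).
* The metaprofile treats every site equally; no weighting by expression
  or peak score.
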