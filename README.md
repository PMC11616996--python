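# clipsplice

Integrative analysis of RNA-binding-protein (RBP) CLIP peaks and
alternative-splicing events downstream of growth-factor signaling.

Studies of SR-protein–family splicing factors (such as Srsf3) routinely
combine two genome-scale readouts: eCLIP peak intervals marking where the
protein binds the transcriptome, and RNA-seq–derived tables of
differential gene expression (DESeq2-style) and differential splicing
(rMATS-style). The biological questions — *where* does the protein bind
(CDS, UTRs, introns, splice-site neighbourhoods), *what* sequence does it
prefer (hexamer motifs), *which* exons does it regulate (GC-rich cassette
exons with short flanking introns), and *which* binding events plausibly
explain splicing changes — are answered by a chain of interval
arithmetic, sequence statistics, and nonparametric tests. `clipsplice`
implements that chain as a tested, reusable library with a CLI, plus a
seeded synthetic-data generator with recorded ground truth so every stage
is verifiable without any sequencing data.

## What it computes

* **Differential filtering** — DE genes kept at adjusted p < 0.05 and
  |FC| ≥ 2; splicing events kept at FDR ≤ 0.05, |ΔPSI| ≥ 0.05, and ≥ 10
  junction reads in either condition. Venn-style overlap, sign
  concordance, and event-type composition summaries.
* **Peak annotation** — each peak is assigned the same-strand transcript
  region (5'UTR / CDS / intron / 3'UTR) with maximal nucleotide overlap
  (ties: CDS > 5'UTR > 3'UTR > intron, then longest CDS).
* **Metaprofiles** — mean binary peak coverage at each offset around 5'
  and 3' splice sites, and over length-scaled transcript regions.
* **Motif enrichment** — per-sequence k-mer (default hexamer) frequencies
  in peak sequences vs a dinucleotide-preserving shuffled background,
  compared with a Welch t-test and ranked by p.
* **Cassette-exon features** — exon GC%, flanking-intron GC%, and
  intron:exon GC/length ratios, compared between event groups with a
  Mann–Whitney U-test (exact null at small n, tie-corrected normal
  approximation otherwise).
* **Integration** — condition-unique peaks (no ≥1 nt same-strand overlap
  in the other condition), high-confidence peak/event hits (peak within
  the cassette exon or within 250 nt of its flanking introns, truncated
  at the intron's far end), the three-way DE/AS/bound Venn, and PSI /
  isoform-ratio arithmetic for validation experiments.

## Worked example

```python
from clipsplice import PipelineConfig, SyntheticConfig, run_pipeline

config = PipelineConfig(outdir="out", seed=7,
                        synthetic=SyntheticConfig(seed=7, n_genes=200))
report = run_pipeline(config)

comp = report["annotate"]["minus"]["percentages"]
print({k: round(v, 1) for k, v in comp.items()})
# {"5'UTR": 11.7, 'CDS': 56.9, 'intron': 25.8, "3'UTR": 5.6}

print([m["kmer"] for m in report["motifs"]["minus"]][:1],
      [m["kmer"] for m in report["motifs"]["plus"]][:1])
# ['CACACA'] ['GAAGAA']

gc = next(c for c in report["features"]["comparisons"]
          if c["feature"] == "exon_gc")
print(round(gc["median_a"], 1), round(gc["median_b"], 1), f"p={gc['p']:.1e}")
# 53.1 49.1 p=4.6e-05
```

The synthetic run plants the study conditions — an exonic-binding
mixture of ~57% CDS in the unstimulated peak set vs ~83% in the
stimulated one, a CA-rich hexamer in the first condition and a GA-rich
one in the second, and cassette exons whose GC targets differ by class —
and the pipeline recovers them: the region composition above matches the
planted mixture, the planted hexamers rank first in their conditions, and
included-class exons are measurably GC-richer than skipped-class exons
(medians 53.1% vs 49.1%). The report also carries a `truth_recovery`
block confirming the filters recovered exactly the planted significant
sets.

Command line equivalents:

```bash
clipsplice simulate --seed 7 --outdir data/
clipsplice filter --de data/de_genes.tsv --rmats-dir data/
clipsplice all --seed 7 --outdir out/
```

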