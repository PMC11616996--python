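"""Seeded synthetic genome / annotation / peak / table generator with a
recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale: multi-exon protein-coding genes whose cassette
exons carry planted GC targets per splicing class (included exons
GC-richer than skipped ones), two CLIP peak conditions with different
exonic-binding mixtures (~57% vs ~83% exonic), a condition-specific
hexamer planted into a configurable fraction of peaks (CA-rich in the
unstimulated condition, GA-rich in the stimulated one), an rMATS-dialect
splicing table whose significant events are planted by exact count, and a
DESeq2-style differential-expression table with planted up/down genes.

Planted quantities (region mixtures, significant-event counts) are
allocated by exact count; randomness enters only through placement and
noise, so truth-recovery tests are exact wherever possible.  A single
integer seed drives a master ``numpy.random.SeedSequence``; children are
spawned in a fixed order (genome, peaks, AS table, DE table), so each
sub-generator is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from clipsplice.genome import (
    GenomeSequence, TranscriptModel, derive_regions, reverse_complement,
    write_gtf,
)
from clipsplice.peaks import PeakRecord, write_bed
from clipsplice.differential import ASEventRecord, EVENT_TYPES

AS_CLASSES = ("included", "skipped", "non_differential")

_RMATS_HEADER = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
            "2ndExonEnd", "upstreamES", "upstreamEE",
            "downstreamES", "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions
    the package is exercised under (desk-scale sizes, published class
    medians and mixtures)."""

    seed: int
    n_genes: int = 200
    contig: str = "chrS"
    # transcript structure
    exon_count_min: int = 5
    exon_count_max: int = 8
    exon_length_mean: int = 150
    exon_length_sd: int = 30
    exon_length_min: int = 60
    intergenic_nt: int = 300
    # per-class cassette-exon GC targets (fractions) and intron:exon
    # length-ratio targets (dimensionless medians)
    exon_gc: dict = field(default_factory=lambda: {
        "included": 0.534, "skipped": 0.500, "non_differential": 0.512})
    background_exon_gc: float = 0.512
    intron_gc: float = 0.45
    intergenic_gc: float = 0.40
    intron_exon_length_ratio: dict = field(default_factory=lambda: {
        "included": 12.4, "skipped": 19.5, "non_differential": 14.2})
    intron_length_min: int = 80
    # peaks: per-condition counts, region mixtures, planted hexamers
    conditions: tuple = ("minus", "plus")
    n_peaks: dict = field(default_factory=lambda: {"minus": 2000, "plus": 2000})
    region_mixture: dict = field(default_factory=lambda: {
        "minus": {"CDS": 0.569, "intron": 0.258, "5'UTR": 0.117,
                  "3'UTR": 0.056},
        "plus": {"CDS": 0.832, "intron": 0.0891, "5'UTR": 0.0453,
                 "3'UTR": 0.0334},
    })
    peak_length: int = 50
    hexamer: dict = field(default_factory=lambda: {
        "minus": "CACACA", "plus": "GAAGAA"})
    hexamer_prob: float = 0.3
    # AS table: planted SE classes by exact count, other types sig/non-sig
    n_se_included: int = 62
    n_se_skipped: int = 35
    n_se_nondiff: int = 38
    n_se_lowread: int = 5
    n_other: dict = field(default_factory=lambda: {
        "RI": (12, 8), "MXE": (12, 8), "A5SS": (9, 1), "A3SS": (8, 2)})
    n_replicates: int = 3
    psi_noise_sd: float = 0.01
    reads_per_replicate: int = 60
    # DE table
    n_de_up: int = 60
    n_de_down: int = 50
    de_lfc_range: tuple = (1.0, 4.0)

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0.0 <= self.hexamer_prob <= 1.0):
            raise ValueError("hexamer_prob outside [0, 1]")
        if self.psi_noise_sd < 0:
            raise ValueError("psi_noise_sd must be >= 0")
        if self.exon_length_min < 10 or self.exon_length_mean <= 0:
            raise ValueError("exon lengths must be positive (min >= 10)")
        if self.intron_length_min < 2:
            raise ValueError("introns must be at least 2 nt")
        if self.exon_count_min < 3:
            raise ValueError("SE events need transcripts with >= 3 exons")
        for cond, mix in self.region_mixture.items():
            if any(not (0.0 <= f) for f in mix.values()):
                raise ValueError(f"negative mixture fraction for {cond}")
        total_events = self.n_se_total + sum(
            s + n for s, n in self.n_other.values())
        if self.n_genes and total_events > self.n_genes:
            raise ValueError(
                f"{total_events} AS events exceed {self.n_genes} genes")
        nondiff_needed = (total_events - self.n_se_included
                          - self.n_se_skipped)
        nondiff_avail = self.n_genes - self.n_se_included - self.n_se_skipped
        if self.n_genes and nondiff_needed > nondiff_avail:
            raise ValueError(
                f"{nondiff_needed} events need non-differential host genes "
                f"but only {nondiff_avail} exist")
        for cond in self.conditions:
            if cond not in self.n_peaks or cond not in self.region_mixture \
                    or cond not in self.hexamer:
                raise ValueError(f"missing per-condition settings for {cond!r}")
        if self.n_genes and self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("DE up+down exceed n_genes")

    @property
    def n_se_total(self) -> int:
        return (self.n_se_included + self.n_se_skipped + self.n_se_nondiff
                + self.n_se_lowread)


@dataclass
class TruthManifest:
    """Planted ground truth covering every generated record exactly once."""

    genes: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    as_events: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _draw_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with per-base GC probability ``gc`` (uniform within
    each class) — the simplest null for motif statistics."""
    is_gc = rng.random(length) < gc
    pick = rng.integers(0, 2, size=length)
    bases = np.where(is_gc, np.where(pick == 0, "G", "C"),
                     np.where(pick == 0, "A", "T"))
    return "".join(bases)


def _largest_remainder(fracs: dict[str, float], total: int) -> dict[str, int]:
    """Integer allocation of ``total`` by fractions, exact by construction."""
    s = sum(fracs.values())
    quotas = {k: total * v / s for k, v in fracs.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = total - sum(counts.values())
    for k in sorted(fracs, key=lambda k: quotas[k] - counts[k], reverse=True):
        if short <= 0:
            break
        counts[k] += 1
        short -= 1
    return counts


def generate_genome_and_annotation(
        config: SyntheticConfig,
        rng: Optional[np.random.Generator] = None,
) -> tuple[GenomeSequence, list[TranscriptModel], TruthManifest]:
    """Lay genes end-to-end on one contig with planted cassette-exon GC.

    Each gene is one multi-exon protein-coding transcript; the CDS runs
    from the middle of the first exon to the middle of the last, so every
    transcript has both UTRs.  The middle exon is the cassette exon and
    its GC target is set by the gene's planted splicing class; intron
    lengths are scaled to the class's intron:exon length-ratio target.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    manifest = TruthManifest()
    if config.n_genes == 0:
        return GenomeSequence({config.contig: "N"}), [], manifest

    # planted splicing class per gene, allocated by exact count
    classes = (["included"] * config.n_se_included
               + ["skipped"] * config.n_se_skipped
               + ["non_differential"]
               * (config.n_genes - config.n_se_included - config.n_se_skipped))
    rng.shuffle(classes)

    chunks: list[str] = []
    pos = 0
    models = []
    for gi in range(config.n_genes):
        cls = classes[gi]
        gene_id = f"G{gi:04d}"
        tid = f"T{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exon_count_min,
                                   config.exon_count_max + 1))
        cassette_idx = n_exons // 2
        exon_lens = np.maximum(
            rng.normal(config.exon_length_mean, config.exon_length_sd,
                       n_exons).astype(int),
            config.exon_length_min)
        ratio = config.intron_exon_length_ratio[cls]
        intron_target = max(config.intron_length_min,
                            int(ratio * config.exon_length_mean))
        intron_lens = np.maximum(
            rng.normal(intron_target, 0.15 * intron_target,
                       n_exons - 1).astype(int),
            config.intron_length_min)

        chunks.append(_draw_seq(rng, config.intergenic_nt, config.intergenic_gc))
        pos += config.intergenic_nt
        exons = []
        for ei in range(n_exons):
            gc = config.exon_gc[cls] if ei == cassette_idx \
                else config.background_exon_gc
            exons.append((pos, pos + int(exon_lens[ei])))
            chunks.append(_draw_seq(rng, int(exon_lens[ei]), gc))
            pos += int(exon_lens[ei])
            if ei < n_exons - 1:
                chunks.append(_draw_seq(rng, int(intron_lens[ei]),
                                        config.intron_gc))
                pos += int(intron_lens[ei])
        cds_lo = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        cds_hi = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=gene_id, contig=config.contig,
            strand=strand, exons=exons, cds_span=(cds_lo, cds_hi),
            protein_coding=True,
        ))
        manifest.genes[gene_id] = {
            "transcript_id": tid,
            "as_class": cls,
            "cassette_exon": list(exons[cassette_idx]),
            "cassette_index": cassette_idx,
            "exon_gc_target": config.exon_gc[cls],
            "strand": strand,
        }
    chunks.append(_draw_seq(rng, config.intergenic_nt, config.intergenic_gc))
    genome = GenomeSequence({config.contig: "".join(chunks)})
    return genome, models, manifest


def generate_peaks(
        config: SyntheticConfig,
        annotation: list[TranscriptModel],
        genome: GenomeSequence,
        manifest: Optional[TruthManifest] = None,
        rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[PeakRecord]], TruthManifest]:
    """Place peaks wholly inside planted region classes and plant hexamers.

    The region mixture per condition is allocated by exact count.  A
    planted hexamer is written into the genome inside the peak (transcript
    orientation; reverse-complemented on minus-strand hosts) at a uniform
    offset, with probability ``hexamer_prob`` per peak.  The genome
    sequence is edited in place and the edit recorded in the manifest.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    manifest = manifest or TruthManifest()

    region_pool: dict[str, list[tuple[str, str, int, int]]] = {}
    for m in annotation:
        rs = derive_regions(m)
        for label, a, b in rs.regions:
            if b - a >= config.peak_length:
                region_pool.setdefault(label, []).append(
                    (m.transcript_id, m.strand, a, b))
    contig_seq = {name: list(seq) for name, seq in genome.contigs.items()}
    edited: set[int] = set()  # genomic bases already carrying a planted motif

    peaks_by_condition: dict[str, list[PeakRecord]] = {}
    for cond in config.conditions:
        counts = _largest_remainder(config.region_mixture[cond],
                                    config.n_peaks[cond])
        peaks = []
        idx = 0
        for label, n_label in counts.items():
            pool = region_pool.get(label, [])
            if not pool:
                raise ValueError(
                    f"no region of class {label!r} can host a "
                    f"{config.peak_length} nt peak")
            for _ in range(n_label):
                tid, strand, a, b = pool[rng.integers(len(pool))]
                start = int(rng.integers(a, b - config.peak_length + 1))
                end = start + config.peak_length
                peak_id = f"{cond}_{idx:05d}"
                idx += 1
                motif = None
                motif_offset = None
                if rng.random() < config.hexamer_prob:
                    hexamer = config.hexamer[cond]
                    k = len(hexamer)
                    n_offsets = config.peak_length - k + 1
                    first = int(rng.integers(0, n_offsets))
                    # avoid overwriting a motif planted by an overlapping
                    # peak; scan offsets cyclically from the drawn one
                    for step in range(n_offsets):
                        off = (first + step) % n_offsets
                        g_off = (start + off if strand == "+"
                                 else end - off - k)
                        span = range(g_off, g_off + k)
                        if not edited.intersection(span):
                            insert = (hexamer if strand == "+"
                                      else reverse_complement(hexamer))
                            contig = annotation[0].contig
                            contig_seq[contig][g_off:g_off + k] = list(insert)
                            edited.update(span)
                            motif, motif_offset = hexamer, off
                            break
                peaks.append(PeakRecord(
                    peak_id=peak_id, contig=annotation[0].contig,
                    start=start, end=end, strand=strand, condition=cond,
                ))
                manifest.peaks[peak_id] = {
                    "condition": cond,
                    "region": label,
                    "transcript_id": tid,
                    "start": start, "end": end, "strand": strand,
                    "motif": motif,
                    "motif_offset": motif_offset,
                }
        peaks_by_condition[cond] = peaks
    for name in genome.contigs:
        genome.contigs[name] = "".join(contig_seq[name])
    return peaks_by_condition, manifest


def _class_dpsi(cls: str, rng: np.random.Generator) -> float:
    if cls == "included":
        return float(rng.uniform(0.10, 0.40))
    if cls == "skipped":
        return float(-rng.uniform(0.10, 0.40))
    return float(rng.uniform(-0.03, 0.03))


def generate_as_table(
        config: SyntheticConfig,
        annotation: list[TranscriptModel],
        manifest: Optional[TruthManifest] = None,
        rng: Optional[np.random.Generator] = None,
) -> tuple[list[ASEventRecord], TruthManifest]:
    """rMATS-dialect events with planted significance, one event per gene.

    SE events sit on each gene's cassette exon; planted ``included`` /
    ``skipped`` events carry FDR <= 0.05, |dPSI| >= 0.05 with the class
    sign, and ample junction reads; ``non_differential`` events fail the
    FDR or dPSI rule; ``low_read`` events look significant but are
    detected in < 10 reads in both conditions, so the read filter drops
    them.  Other event types receive an exact sig/non-sig split.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    manifest = manifest or TruthManifest()
    by_class: dict[str, list[TranscriptModel]] = {c: [] for c in AS_CLASSES}
    gene_class = {g: info["as_class"] for g, info in manifest.genes.items()}
    for m in annotation:
        cls = gene_class.get(m.gene_id, "non_differential")
        by_class[cls].append(m)

    records: list[ASEventRecord] = []
    eid = 0

    def host_exons(m: TranscriptModel) -> tuple:
        ci = manifest.genes[m.gene_id]["cassette_index"] \
            if m.gene_id in manifest.genes else len(m.exons) // 2
        target = m.exons[ci]
        left, right = m.exons[ci - 1], m.exons[ci + 1]
        if m.strand == "+":
            return target, left, right
        return target, right, left

    def emit(m: TranscriptModel, event_type: str, cls: str, sig: bool,
             low_read: bool) -> None:
        nonlocal eid
        target, up, down = host_exons(m)
        if sig or low_read:
            dpsi = _class_dpsi(cls if cls in ("included", "skipped")
                               else ("included" if rng.random() < 0.5
                                     else "skipped"), rng)
            fdr = float(rng.uniform(1e-5, 0.04))
        else:
            if rng.random() < 0.5:
                dpsi = _class_dpsi("non_differential", rng)
                fdr = float(rng.uniform(1e-5, 0.04))
            else:
                dpsi = _class_dpsi("included", rng)
                fdr = float(rng.uniform(0.10, 1.0))
        base = float(rng.uniform(0.35, 0.65))
        noise = rng.normal(0.0, config.psi_noise_sd,
                           size=2 * config.n_replicates)
        inc1 = np.clip(base + dpsi / 2 + noise[:config.n_replicates], 0, 1)
        inc2 = np.clip(base - dpsi / 2 + noise[config.n_replicates:], 0, 1)
        table_dpsi = float(np.mean(inc1) - np.mean(inc2))
        if low_read:
            totals1 = rng.integers(0, 3, config.n_replicates)
            totals2 = rng.integers(0, 3, config.n_replicates)
        else:
            totals1 = config.reads_per_replicate + rng.poisson(
                20, config.n_replicates)
            totals2 = config.reads_per_replicate + rng.poisson(
                20, config.n_replicates)
        ijc1 = np.round(totals1 * inc1).astype(int)
        ijc2 = np.round(totals2 * inc2).astype(int)
        event_id = f"AS{eid:04d}"
        eid += 1
        records.append(ASEventRecord(
            event_id=event_id, gene_id=m.gene_id, event_type=event_type,
            contig=m.contig, strand=m.strand, target_exon=target,
            upstream_exon=up, downstream_exon=down,
            inc1=[float(x) for x in inc1], inc2=[float(x) for x in inc2],
            delta_psi=table_dpsi, fdr=fdr,
            ijc1=[int(x) for x in ijc1],
            sjc1=[int(x) for x in totals1 - ijc1],
            ijc2=[int(x) for x in ijc2],
            sjc2=[int(x) for x in totals2 - ijc2],
        ))
        manifest.as_events[event_id] = {
            "gene_id": m.gene_id,
            "event_type": event_type,
            "class": ("low_read" if low_read
                      else cls if sig else "non_differential"),
            "significant": bool(sig and not low_read),
        }

    pools = {c: list(by_class[c]) for c in AS_CLASSES}
    for c in AS_CLASSES:
        rng.shuffle(pools[c])
    for _ in range(config.n_se_included):
        emit(pools["included"].pop(), "SE", "included", True, False)
    for _ in range(config.n_se_skipped):
        emit(pools["skipped"].pop(), "SE", "skipped", True, False)
    for _ in range(config.n_se_nondiff):
        emit(pools["non_differential"].pop(), "SE", "non_differential",
             False, False)
    for _ in range(config.n_se_lowread):
        emit(pools["non_differential"].pop(), "SE", "non_differential",
             True, True)
    for event_type, (n_sig, n_non) in config.n_other.items():
        for _ in range(n_sig):
            emit(pools["non_differential"].pop(), event_type, "other",
                 True, False)
        for _ in range(n_non):
            emit(pools["non_differential"].pop(), event_type, "other",
                 False, False)
    return records, manifest


def generate_de_table(
        config: SyntheticConfig,
        manifest: Optional[TruthManifest] = None,
        rng: Optional[np.random.Generator] = None,
) -> tuple[list, TruthManifest]:
    """DESeq2-style rows over all genes with planted up/down/null counts."""
    from clipsplice.differential import DEGeneRecord

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    manifest = manifest or TruthManifest()
    gene_ids = (sorted(manifest.genes)
                if manifest.genes else [f"G{i:04d}" for i in range(config.n_genes)])
    order = list(gene_ids)
    rng.shuffle(order)
    records = []
    for i, gid in enumerate(order):
        if i < config.n_de_up:
            direction = "up"
            lfc = float(rng.uniform(*config.de_lfc_range))
            padj = float(rng.uniform(1e-8, 0.049))
        elif i < config.n_de_up + config.n_de_down:
            direction = "down"
            lfc = -float(rng.uniform(*config.de_lfc_range))
            padj = float(rng.uniform(1e-8, 0.049))
        else:
            direction = "null"
            if rng.random() < 0.5:
                lfc = float(rng.uniform(-0.9, 0.9))
                padj = float(rng.uniform(1e-8, 0.049))
            else:
                lfc = float(rng.uniform(-4.0, 4.0))
                padj = float(rng.uniform(0.06, 1.0))
        records.append(DEGeneRecord(gene_id=gid, log2fc=lfc, padj=padj))
        manifest.de_genes[gid] = {"direction": direction,
                                  "significant": direction != "null"}
    records.sort(key=lambda r: r.gene_id)
    return records, manifest


@dataclass
class SyntheticDataset:
    """One fully generated study: genome, annotation, peaks, tables, truth."""

    config: SyntheticConfig
    genome: GenomeSequence
    annotation: list[TranscriptModel]
    peaks: dict[str, list[PeakRecord]]
    as_events: list[ASEventRecord]
    de_genes: list
    manifest: TruthManifest

    @classmethod
    def generate(cls, config: SyntheticConfig) -> "SyntheticDataset":
        """Run all sub-generators in the documented seeding order."""
        children = np.random.SeedSequence(config.seed).spawn(4)
        rngs = [np.random.default_rng(c) for c in children]
        genome, annotation, manifest = generate_genome_and_annotation(
            config, rng=rngs[0])
        if annotation:
            peaks, manifest = generate_peaks(config, annotation, genome,
                                             manifest, rng=rngs[1])
            as_events, manifest = generate_as_table(config, annotation,
                                                    manifest, rng=rngs[2])
        else:
            peaks, as_events = {c: [] for c in config.conditions}, []
        de_genes, manifest = generate_de_table(config, manifest, rng=rngs[3])
        return cls(config, genome, annotation, peaks, as_events, de_genes,
                   manifest)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GTF, per-condition BED, rMATS-dialect TSVs, DE TSV
        and the truth manifest; returns the path of each artefact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            for name, seq in self.genome.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        paths["fasta"] = fasta

        gtf = outdir / "annotation.gtf"
        write_gtf(self.annotation, gtf)
        paths["gtf"] = gtf

        for cond, peaks in self.peaks.items():
            bed = outdir / f"peaks_{cond}.bed"
            write_bed(peaks, bed)
            paths[f"peaks_{cond}"] = bed

        for event_type in EVENT_TYPES:
            rows = [e for e in self.as_events if e.event_type == event_type]
            path = outdir / f"{event_type}.MATS.JC.txt"
            write_rmats_table(rows, event_type, path)
            paths[f"as_{event_type}"] = path

        de = outdir / "de_genes.tsv"
        with open(de, "w") as fh:
            fh.write("gene_id\tlog2FoldChange\tpadj\n")
            for r in self.de_genes:
                fh.write(f"{r.gene_id}\t{r.log2fc:.6f}\t{r.padj:.6g}\n")
        paths["de"] = de

        man = outdir / "truth_manifest.json"
        self.manifest.to_json(man)
        paths["manifest"] = man
        return paths


def write_rmats_table(events: list[ASEventRecord], event_type: str,
                      path: str | Path) -> None:
    """Write one rMATS JC-dialect TSV (coordinate columns per event type)."""
    coord_cols = _RMATS_HEADER[event_type]
    cols = (["ID", "GeneID", "geneSymbol", "chr", "strand"] + coord_cols
            + ["IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
               "IncFormLen", "SkipFormLen", "PValue", "FDR",
               "IncLevel1", "IncLevel2", "IncLevelDifference"])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in events:
            ts, te = e.target_exon
            us, ue = e.upstream_exon
            ds, de_ = e.downstream_exon
            if event_type == "MXE":
                coords = [ts, te, ts, te, us, ue, ds, de_]
            elif event_type in ("A5SS", "A3SS"):
                coords = [ts, te, ts, te, us, ue]
            else:
                coords = [ts, te, us, ue, ds, de_]
            row = ([e.event_id, e.gene_id, e.gene_id, e.contig, e.strand]
                   + [str(c) for c in coords]
                   + [",".join(str(x) for x in e.ijc1),
                      ",".join(str(x) for x in e.sjc1),
                      ",".join(str(x) for x in e.ijc2),
                      ",".join(str(x) for x in e.sjc2),
                      "100", "50",
                      f"{e.fdr:.6g}", f"{e.fdr:.6g}",
                      ",".join(f"{x:.4f}" for x in e.inc1),
                      ",".join(f"{x:.4f}" for x in e.inc2),
                      f"{e.delta_psi:.6f}"])
            fh.write("\t".join(str(x) for x in row) + "\n")
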