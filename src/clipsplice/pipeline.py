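"""End-to-end orchestration: synthetic or file inputs, staged execution,
and a machine-readable report.

Stages run in a fixed order (filter -> annotate -> metaprofile -> motifs
-> features -> integrate); each stage's outputs are written before the
next begins, and the JSON report regenerates byte-identically for an
identical configuration and seed.  When no peak inputs are available the
peak stages are skipped with a logged notice and the DE/AS summaries are
still produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from clipsplice.genome import (GenomeSequence, TranscriptModel, derive_regions,
                               read_annotation, read_genome, splice_sites)
from clipsplice.differential import (EVENT_TYPES, filter_as, filter_de,
                                     event_type_composition, read_de_table,
                                     read_rmats_table)
from clipsplice.peaks import (annotate_peaks, read_bed, region_composition,
                              splice_site_metaprofile, transcript_metaprofile)
from clipsplice.motifs import (enrichment_test, extract_peak_sequences,
                               make_background)
from clipsplice.features import (bound_vs_unbound_features,
                                 compute_feature_table, group_compare)
from clipsplice.integrate import (condition_unique_peaks, highconf_overlap,
                                  three_way_crossref)
from clipsplice.synth import SyntheticConfig, SyntheticDataset, write_rmats_table

logger = logging.getLogger(__name__)

PACKAGE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic`` or the real-input paths must be set."""

    outdir: str
    seed: int = 0
    synthetic: Optional[SyntheticConfig] = None
    genome_fasta: Optional[str] = None
    annotation_gtf: Optional[str] = None
    peak_beds: dict = field(default_factory=dict)  # condition -> path
    rmats_dir: Optional[str] = None  # directory of <TYPE>.MATS.JC.txt
    de_table: Optional[str] = None
    # thresholds, defaulted to the study's printed values
    padj_max: float = 0.05
    min_abs_fc: float = 2.0
    fdr_max: float = 0.05
    min_abs_dpsi: float = 0.05
    min_reads: int = 10
    flank_nt: int = 250
    kmer_k: int = 6
    metaprofile_window: int = 300
    bins_per_region: int = 100

    def validate(self) -> None:
        real = any([self.genome_fasta, self.annotation_gtf, self.peak_beds,
                    self.rmats_dir, self.de_table])
        if (self.synthetic is None) == (not real):
            raise ValueError("exactly one of synthetic / real inputs required")
        for name in ("padj_max", "min_abs_fc", "fdr_max", "min_abs_dpsi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # the report must not depend on where it lands
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_profile_tsv(profiles: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("anchor\toffset\tvalue\n")
        for name, prof in profiles.items():
            for off, val in zip(prof.offsets, prof.values):
                fh.write(f"{name}\t{int(off)}\t{val:.6f}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the analysis report (also written to
    ``outdir/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "package_version": PACKAGE_VERSION,
        }
    }

    # ---- inputs -----------------------------------------------------
    manifest = None
    if config.synthetic is not None:
        ds = SyntheticDataset.generate(config.synthetic)
        ds.write(outdir / "synthetic_inputs")
        genome, annotation = ds.genome, ds.annotation
        peaks_by_condition = ds.peaks
        as_events, de_records = ds.as_events, ds.de_genes
        manifest = ds.manifest
    else:
        genome = read_genome(config.genome_fasta) if config.genome_fasta else None
        annotation = (read_annotation(config.annotation_gtf)
                      if config.annotation_gtf else [])
        peaks_by_condition = {
            cond: read_bed(path, condition=cond)
            for cond, path in sorted(config.peak_beds.items())
        }
        as_events = []
        if config.rmats_dir:
            for event_type in EVENT_TYPES:
                p = Path(config.rmats_dir) / f"{event_type}.MATS.JC.txt"
                if p.exists():
                    as_events.extend(read_rmats_table(p, event_type))
        de_records = read_de_table(config.de_table) if config.de_table else []

    # ---- stage: filter ----------------------------------------------
    sig_de = filter_de(de_records, config.padj_max, config.min_abs_fc)
    sig_as = filter_as(as_events, config.fdr_max, config.min_abs_dpsi,
                       config.min_reads)
    composition = event_type_composition(sig_as)
    report["filter"] = {
        "n_de_input": len(de_records), "n_de_significant": len(sig_de),
        "n_as_input": len(as_events), "n_as_significant": len(sig_as),
        "event_type_composition": composition,
    }
    if manifest is not None:
        truth_de = {g for g, v in manifest.de_genes.items() if v["significant"]}
        truth_as = {e for e, v in manifest.as_events.items() if v["significant"]}
        report["filter"]["truth_recovery"] = {
            "de_recovered": sorted({r.gene_id for r in sig_de}) == sorted(truth_de),
            "as_recovered": sorted({r.event_id for r in sig_as}) == sorted(truth_as),
        }
    stage_dir = outdir / "filter"
    stage_dir.mkdir(exist_ok=True)
    with open(stage_dir / "significant_de.tsv", "w") as fh:
        fh.write("gene_id\tlog2FoldChange\tpadj\n")
        for r in sig_de:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6f}\t{r.padj:.6g}\n")
    for event_type in EVENT_TYPES:
        rows = [e for e in sig_as if e.event_type == event_type]
        write_rmats_table(rows, event_type,
                          stage_dir / f"significant_{event_type}.tsv")

    have_peaks = any(peaks_by_condition.values())
    have_genome = genome is not None and annotation
    coding = [m for m in annotation if m.protein_coding and m.cds_span]
    region_sets = [derive_regions(m) for m in coding]

    # ---- stage: annotate + metaprofiles -----------------------------
    if have_peaks and region_sets:
        stage_dir = outdir / "annotate"
        stage_dir.mkdir(exist_ok=True)
        catalog = [s for m in coding for s in splice_sites(m)]
        report["annotate"] = {}
        for cond in sorted(peaks_by_condition):
            peaks = peaks_by_condition[cond]
            assignments = annotate_peaks(peaks, region_sets)
            comp = region_composition(assignments)
            report["annotate"][cond] = comp
            profiles = splice_site_metaprofile(peaks, catalog,
                                               config.metaprofile_window)
            _write_profile_tsv(profiles,
                               stage_dir / f"splice_site_profile_{cond}.tsv")
            tprof = transcript_metaprofile(peaks, region_sets,
                                           config.bins_per_region)
            _write_profile_tsv({"scaled": tprof},
                               stage_dir / f"transcript_profile_{cond}.tsv")
    else:
        logger.info("peak stages skipped: no peak inputs or no annotation")
        report["annotate"] = None

    # ---- stage: motifs ----------------------------------------------
    if have_peaks and have_genome:
        stage_dir = outdir / "motifs"
        stage_dir.mkdir(exist_ok=True)
        report["motifs"] = {}
        for cond in sorted(peaks_by_condition):
            seqs = extract_peak_sequences(peaks_by_condition[cond], genome)
            bg = make_background(seqs, "dinucleotide_shuffle",
                                 seed=config.seed)
            stats_ = enrichment_test(seqs, bg, k=config.kmer_k)
            with open(stage_dir / f"kmers_{cond}.tsv", "w") as fh:
                fh.write("rank\tkmer\tfg_mean\tbg_mean\tt\tp\n")
                for s in stats_:
                    fh.write(f"{s.rank}\t{s.kmer}\t{s.fg_mean:.6g}\t"
                             f"{s.bg_mean:.6g}\t{s.t:.4f}\t{s.p:.4g}\n")
            report["motifs"][cond] = [
                {"kmer": s.kmer, "p": s.p, "t": s.t} for s in stats_[:3]]
    else:
        report["motifs"] = None

    # ---- stage: features --------------------------------------------
    if have_genome and as_events:
        stage_dir = outdir / "features"
        stage_dir.mkdir(exist_ok=True)
        groups = {}
        for e in sig_as:
            if e.event_type == "SE":
                groups[e.event_id] = "included" if e.delta_psi > 0 else "skipped"
        for e in as_events:
            if e.event_type == "SE" and e.event_id not in groups:
                groups[e.event_id] = "non_differential"
        feats = compute_feature_table(
            [e for e in as_events if e.event_type == "SE"], genome, groups)
        with open(stage_dir / "exon_features.tsv", "w") as fh:
            fh.write("event_id\tgroup\texon_gc\tup_intron_gc\tdown_intron_gc\t"
                     "down_gc_ratio\tup_len_ratio\tdown_len_ratio\n")
            for r in feats:
                fh.write(f"{r.event_id}\t{r.group}\t{r.exon_gc:.3f}\t"
                         f"{r.up_intron_gc:.3f}\t{r.down_intron_gc:.3f}\t"
                         f"{r.down_intron_to_exon_gc_ratio:.4f}\t"
                         f"{r.up_intron_to_exon_length_ratio:.3f}\t"
                         f"{r.down_intron_to_exon_length_ratio:.3f}\n")
        comparisons = []
        present = {r.group for r in feats}
        for feature in ("exon_gc", "down_intron_to_exon_gc_ratio",
                        "up_intron_to_exon_length_ratio",
                        "down_intron_to_exon_length_ratio"):
            if {"included", "skipped"} <= present:
                comparisons.append(group_compare(feats, "included", "skipped",
                                                 feature))
        report["features"] = {"n_records": len(feats),
                              "comparisons": comparisons}
        if have_peaks:
            bound = bound_vs_unbound_features(peaks_by_condition, coding,
                                              genome)
            blabels = {r.group for r in bound}
            bound_cmp = []
            for lab in sorted(blabels - {"unbound"}):
                if "unbound" in blabels:
                    bound_cmp.append(group_compare(bound, lab, "unbound",
                                                   "exon_gc"))
            report["features"]["bound_vs_unbound"] = bound_cmp
    else:
        report["features"] = None

    # ---- stage: integrate -------------------------------------------
    conds = sorted(peaks_by_condition)
    if have_peaks and len(conds) == 2:
        stage_dir = outdir / "integrate"
        stage_dir.mkdir(exist_ok=True)
        ua, ub = condition_unique_peaks(peaks_by_condition[conds[0]],
                                        peaks_by_condition[conds[1]])
        unique = ua + ub
        hits = highconf_overlap(unique, sig_as, config.flank_nt)
        with open(stage_dir / "highconf_hits.tsv", "w") as fh:
            fh.write("event_id\tpeak_id\trelation\tdistance_nt\n")
            for h in hits:
                fh.write(f"{h.event_id}\t{h.peak_id}\t{h.relation}\t"
                         f"{h.distance_nt}\n")
        tx2gene = {m.transcript_id: m.gene_id for m in annotation}
        peak_genes = set()
        if region_sets:
            for a in annotate_peaks(unique, region_sets):
                peak_genes.add(tx2gene[a.transcript_id])
        venn = three_way_crossref({r.gene_id for r in sig_de},
                                  {e.gene_id for e in sig_as},
                                  peak_genes, tx2gene)
        report["integrate"] = {
            "n_unique_peaks": {conds[0]: len(ua), conds[1]: len(ub)},
            "n_highconf_hits": len(hits),
            "n_highconf_events": len({h.event_id for h in hits}),
            "crossref": {
                "n_de": venn.n_de, "n_as": venn.n_as, "n_peak": venn.n_peak,
                "cells": venn.cells,
                "pct_de_bound": venn.pct_de_bound,
                "pct_as_bound": venn.pct_as_bound,
            },
        }
        _write_json(report["integrate"]["crossref"], stage_dir / "venn.json")
    else:
        report["integrate"] = None

    _write_json(report, outdir / "report.json")
    return report
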