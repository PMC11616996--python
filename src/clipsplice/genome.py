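"""Genome sequence and transcript-structure primitives.

All internal coordinates are 0-based half-open genomic intervals; GTF
(1-based closed) is converted at the I/O boundary and BED passes through
unchanged.  Exons are stored sorted ascending by genomic start regardless
of strand; transcript orientation (5'→3') is applied where it matters
(region labels, splice-site kinds, metaprofile offsets).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

Interval = tuple[int, int]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes other than ACGT are normalised to N so that GC
# content stays unambiguous.
_AMBIG = re.compile(r"[RYSWKMBDHV]")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map IUPAC ambiguity codes to N."""
    s = _AMBIG.sub("N", seq.upper())
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """GC fraction of a sequence, N excluded from numerator and denominator.

    Raises ``ValueError`` on empty or all-N input.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    n_gc = s.count("G") + s.count("C")
    n_valid = len(s) - s.count("N")
    if n_valid == 0:
        raise ValueError("sequence is all N; GC content undefined")
    return n_gc / n_valid


@dataclass
class GenomeSequence:
    """In-memory genome: contig name → uppercase ACGTN string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of [start, end) on the plus strand; bounds are enforced."""
        if contig not in self.contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass
class TranscriptModel:
    """Exon structure of one transcript in genomic coordinates.

    ``exons`` are 0-based half-open intervals, sorted ascending and
    non-overlapping regardless of strand.  ``cds_span`` is the genomic
    min..max span of all CDS segments; per-exon CDS pieces are recovered
    by intersection with the exons.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[Interval]
    cds_span: Optional[Interval] = None
    protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"degenerate exon [{a}, {b})")
        for (_, b), (c, _) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError("exons overlap")
        if self.cds_span is not None:
            lo, hi = self.cds_span
            if not (self.exons[0][0] <= lo < hi <= self.exons[-1][1]):
                raise ValueError("cds_span outside exon span")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        ]

    @property
    def cds_length(self) -> int:
        if self.cds_span is None:
            return 0
        lo, hi = self.cds_span
        return sum(max(0, min(b, hi) - max(a, lo)) for a, b in self.exons)


@dataclass
class RegionSet:
    """Disjoint labelled intervals (5'UTR / CDS / intron / 3'UTR) covering
    one transcript's genomic span."""

    transcript_id: str
    contig: str
    strand: str
    regions: list[tuple[str, int, int]]  # (label, start, end)

    def intervals(self, label: str) -> list[Interval]:
        return [(a, b) for lab, a, b in self.regions if lab == label]


@dataclass(frozen=True)
class SpliceSite:
    """One exon/intron boundary.

    ``kind`` is 5SS at the transcript-orientation start of an intron and
    3SS at its end; ``position`` is the genomic boundary coordinate under
    half-open convention (first intronic base for a plus-strand 5'SS).
    """

    kind: str  # "5SS" or "3SS"
    contig: str
    position: int
    strand: str
    transcript_id: str


def read_genome(fasta_path: str | Path) -> GenomeSequence:
    """Read a multi-record FASTA into memory, uppercased and normalised."""
    contigs: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        n += 1
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r}")
        contigs[record.id] = normalize_sequence(str(record.seq))
    if n == 0:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return GenomeSequence(contigs)


_ATTR = re.compile(r'(\w+) "([^"]*)"')

_NONCODING = {"lncRNA", "snoRNA", "snRNA", "miRNA", "rRNA", "misc_RNA",
              "processed_pseudogene", "pseudogene"}


def read_annotation(gtf_path: str | Path) -> list[TranscriptModel]:
    """Parse exon and CDS features of a GTF into transcript models.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Protein-coding status is taken from the transcript_type / transcript_biotype
    attribute when present, else inferred from the presence of CDS features.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        if "transcript_id" not in feat.attributes:
            raise ValueError(f"{feat.featuretype} feature without transcript_id")
        tid = feat.attributes["transcript_id"][0]
        if feat.end < feat.start:
            raise ValueError(f"end < start in feature for {tid}")
        if feat.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {feat.strand!r} for {tid}")
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed → half-open
        if tid not in meta:
            biotype = None
            for key in ("transcript_type", "transcript_biotype"):
                if key in feat.attributes:
                    biotype = feat.attributes[key][0]
                    break
            meta[tid] = {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "contig": feat.seqid,
                "strand": feat.strand,
                "biotype": biotype,
            }
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)

    models = []
    for tid, ex in exons.items():
        m = meta[tid]
        merged = _merge_intervals(ex)
        cds_span = None
        if tid in cds:
            cds_span = (min(a for a, _ in cds[tid]), max(b for _, b in cds[tid]))
        biotype = m["biotype"]
        if biotype is not None:
            coding = biotype == "protein_coding"
        else:
            coding = cds_span is not None
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                contig=m["contig"],
                strand=m["strand"],
                exons=merged,
                cds_span=cds_span,
                protein_coding=coding,
            )
        )
    return models


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write exon and CDS features (1-based closed) for each transcript."""
    with open(path, "w") as fh:
        for m in models:
            biotype = "protein_coding" if m.protein_coding else "misc_RNA"
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'transcript_type "{biotype}";'
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.contig}\tclipsplice\texon\t{a + 1}\t{b}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_span is not None:
                lo, hi = m.cds_span
                for a, b in m.exons:
                    ca, cb = max(a, lo), min(b, hi)
                    if ca < cb:
                        fh.write(
                            f"{m.contig}\tclipsplice\tCDS\t{ca + 1}\t{cb}\t.\t"
                            f"{m.strand}\t0\t{attrs}\n"
                        )


def derive_regions(model: TranscriptModel) -> RegionSet:
    """Label the transcript span as 5'UTR / CDS / intron / 3'UTR.

    Exonic sequence upstream of the CDS in transcript orientation is 5'UTR,
    downstream is 3'UTR; inter-exon gaps are introns.  Non-coding models
    (no ``cds_span``) are rejected — callers restrict peak annotation to
    protein-coding transcripts.
    """
    if model.cds_span is None:
        raise ValueError(
            f"transcript {model.transcript_id} has no CDS; "
            "region derivation requires a protein-coding model"
        )
    lo, hi = model.cds_span
    left_utr = "5'UTR" if model.strand == "+" else "3'UTR"
    right_utr = "3'UTR" if model.strand == "+" else "5'UTR"
    regions: list[tuple[str, int, int]] = []
    for a, b in model.exons:
        if a < lo:
            regions.append((left_utr, a, min(b, lo)))
        ca, cb = max(a, lo), min(b, hi)
        if ca < cb:
            regions.append(("CDS", ca, cb))
        if b > hi:
            regions.append((right_utr, max(a, hi), b))
    for a, b in model.introns:
        regions.append(("intron", a, b))
    regions.sort(key=lambda r: (r[1], r[2]))
    return RegionSet(model.transcript_id, model.contig, model.strand, regions)


def splice_sites(model: TranscriptModel) -> list[SpliceSite]:
    """Splice sites of a transcript: one 5'SS and one 3'SS per intron.

    For a plus-strand intron (gap) [a, b): 5'SS at a, 3'SS at b.  On the
    minus strand the transcript traverses the gap downward, so the 5'SS is
    at b and the 3'SS at a.
    """
    sites = []
    for a, b in model.introns:
        if model.strand == "+":
            sites.append(SpliceSite("5SS", model.contig, a, "+", model.transcript_id))
            sites.append(SpliceSite("3SS", model.contig, b, "+", model.transcript_id))
        else:
            sites.append(SpliceSite("5SS", model.contig, b, "-", model.transcript_id))
            sites.append(SpliceSite("3SS", model.contig, a, "-", model.transcript_id))
    return sites
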