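"""CLIP peak handling: BED I/O, peak-to-region assignment, region
composition, and binary-coverage metaprofiles.

A peak gets one region label: the same-strand transcript region with the
largest nucleotide overlap, ties broken by CDS > 5'UTR > 3'UTR > intron
and then by the transcript with the longest CDS.  Antisense peaks (no
same-strand protein-coding transcript) receive no label and are excluded
from composition, matching counts restricted to protein-coding genes.

Metaprofile coverage is binary per anchor (is any base of any same-strand
peak present), not read-depth weighted: the inputs are peak intervals,
not coverage tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from clipsplice.genome import RegionSet, SpliceSite

_LABEL_PRIORITY = {"CDS": 3, "5'UTR": 2, "3'UTR": 1, "intron": 0}
REGION_ORDER = ("5'UTR", "CDS", "intron", "3'UTR")


@dataclass
class PeakRecord:
    peak_id: str
    contig: str
    start: int
    end: int
    strand: str
    condition: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak {self.peak_id}: end <= start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"peak {self.peak_id}: strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionAssignment:
    peak_id: str
    label: str
    transcript_id: str
    overlap_nt: int

    def __post_init__(self) -> None:
        if self.overlap_nt < 1:
            raise ValueError("overlap must be >= 1 nt")


@dataclass
class MetaProfile:
    """Positionally aligned mean binary coverage.

    For splice-site anchors ``offsets`` are nucleotide positions relative
    to the boundary in transcript orientation; for scaled transcript
    profiles they are bin indices over 5'UTR|CDS|intron|3'UTR.
    """

    anchor: str
    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.offsets) == len(self.values)
        assert np.all((self.values >= 0) & (self.values <= 1))


def read_bed(path: str | Path, condition: str = "") -> list[PeakRecord]:
    """Read a 6-column BED (0-based half-open, strand in column 6)."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{i + 1}: expected >= 6 BED columns")
            score = None if f[4] in (".", "") else float(f[4])
            peaks.append(PeakRecord(
                peak_id=f[3], contig=f[0], start=int(f[1]), end=int(f[2]),
                strand=f[5], condition=condition, score=score,
            ))
    return peaks


def write_bed(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.peak_id}\t"
                     f"{score}\t{p.strand}\n")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_region(peak: PeakRecord,
                  region_sets: Sequence[RegionSet]) -> Optional[RegionAssignment]:
    """Assign one peak to the best-overlapping same-strand region.

    Returns None when no same-strand transcript overlaps the peak.
    """
    contigs = {rs.contig for rs in region_sets}
    if peak.contig not in contigs:
        raise ValueError(f"contig {peak.contig!r} absent from annotation")
    candidates = []  # (-overlap, -label_priority, -cds_len, tid, label)
    for rs in region_sets:
        if rs.contig != peak.contig or rs.strand != peak.strand:
            continue
        per_label: dict[str, int] = {}
        for label, a, b in rs.regions:
            ov = _overlap((peak.start, peak.end), (a, b))
            if ov > 0:
                per_label[label] = per_label.get(label, 0) + ov
        if not per_label:
            continue
        cds_len = sum(b - a for lab, a, b in rs.regions if lab == "CDS")
        for label, ov in per_label.items():
            candidates.append((-ov, -_LABEL_PRIORITY[label], -cds_len,
                               rs.transcript_id, label))
    if not candidates:
        return None
    neg_ov, _, _, tid, label = min(candidates)
    return RegionAssignment(peak.peak_id, label, tid, -neg_ov)


def annotate_peaks(peaks: Iterable[PeakRecord],
                   region_sets: Sequence[RegionSet]) -> list[RegionAssignment]:
    """Batch :func:`assign_region`; unassignable (antisense) peaks are dropped."""
    by_contig: dict[str, list[RegionSet]] = {}
    for rs in region_sets:
        by_contig.setdefault(rs.contig, []).append(rs)
    out = []
    for p in peaks:
        if p.contig not in by_contig:
            raise ValueError(f"contig {p.contig!r} absent from annotation")
        a = assign_region(p, by_contig[p.contig])
        if a is not None:
            out.append(a)
    return out


def region_composition(assignments: Sequence[RegionAssignment]) -> dict:
    """Counts and percentages per region label over all assigned peaks."""
    counts = {label: 0 for label in REGION_ORDER}
    for a in assignments:
        counts[a.label] += 1
    total = len(assignments)
    pct = {label: (100.0 * counts[label] / total if total else 0.0)
           for label in REGION_ORDER}
    return {"counts": counts, "total": total, "percentages": pct}


class _CoverageIndex:
    """Merged same-strand peak intervals per (contig, strand) for O(log n)
    point-coverage queries."""

    def __init__(self, peaks: Iterable[PeakRecord]):
        raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for p in peaks:
            raw.setdefault((p.contig, p.strand), []).append((p.start, p.end))
        self.starts: dict[tuple[str, str], np.ndarray] = {}
        self.ends: dict[tuple[str, str], np.ndarray] = {}
        for key, ivs in raw.items():
            merged: list[list[int]] = []
            for a, b in sorted(ivs):
                if merged and a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            self.starts[key] = np.array([m[0] for m in merged])
            self.ends[key] = np.array([m[1] for m in merged])

    def covered(self, contig: str, strand: str, positions: np.ndarray) -> np.ndarray:
        key = (contig, strand)
        if key not in self.starts:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(self.starts[key], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < self.ends[key][idx[ok]]
        return out


def _site_positions(site: SpliceSite, offsets: np.ndarray) -> np.ndarray:
    """Genomic base for each transcript-orientation offset at a boundary.

    Offset 0 is the first base downstream of the boundary in transcript
    orientation (the first intronic base at a 5'SS, the first exonic base
    at a 3'SS); offset -1 is the last base upstream of it.
    """
    if site.strand == "+":
        return site.position + offsets
    return site.position - 1 - offsets


def splice_site_metaprofile(peaks: Iterable[PeakRecord],
                            catalog: Sequence[SpliceSite],
                            window_nt: int = 300) -> dict[str, MetaProfile]:
    """Mean binary peak coverage around 5' and 3' splice sites.

    For each offset o in [-window, +window] (transcript orientation:
    negative = exon side of a 5'SS / intron side of a 3'SS), the value is
    the fraction of sites of that kind whose base at offset o is covered
    by >= 1 same-strand peak.  Offsets beyond the transcript or the
    neighbouring feature still count in the denominator.
    """
    if window_nt < 1:
        raise ValueError("window_nt must be >= 1")
    catalog = list(catalog)
    if not catalog:
        raise ValueError("empty splice-site catalog")
    index = _CoverageIndex(peaks)
    offsets = np.arange(-window_nt, window_nt + 1)
    profiles = {}
    for kind in ("5SS", "3SS"):
        sites = [s for s in catalog if s.kind == kind]
        hits = np.zeros(len(offsets), dtype=float)
        for s in sites:
            pos = _site_positions(s, offsets)
            hits += index.covered(s.contig, s.strand, pos)
        values = hits / len(sites) if sites else hits
        profiles[kind] = MetaProfile(kind, offsets, values)
    return profiles


def transcript_metaprofile(peaks: Iterable[PeakRecord],
                           region_sets: Sequence[RegionSet],
                           bins_per_region: int = 100) -> MetaProfile:
    """Scaled metaprofile over 5'UTR | CDS | intron | 3'UTR.

    Each region of each transcript is rescaled to ``bins_per_region``
    bins in transcript orientation; a bin's value is the fraction of
    transcripts with >= 1 peak-covered base mapping into it.
    """
    if bins_per_region < 1:
        raise ValueError("bins_per_region must be >= 1")
    region_sets = list(region_sets)
    index = _CoverageIndex(peaks)
    nbins = bins_per_region * len(REGION_ORDER)
    hit = np.zeros(nbins, dtype=float)
    for rs in region_sets:
        for ri, label in enumerate(REGION_ORDER):
            ivs = rs.intervals(label)
            if not ivs:
                continue
            bases = np.concatenate([np.arange(a, b) for a, b in ivs])
            if rs.strand == "-":
                bases = bases[::-1]
            covered = index.covered(rs.contig, rs.strand, bases)
            if not covered.any():
                continue
            length = len(bases)
            bin_idx = (np.arange(length) * bins_per_region) // length
            covered_bins = np.unique(bin_idx[covered])
            hit[ri * bins_per_region + covered_bins] += 1.0
    values = hit / len(region_sets) if region_sets else hit
    return MetaProfile("scaled-region", np.arange(nbins), values)
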