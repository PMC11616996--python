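"""Cross-referencing CLIP binding with differential expression and
splicing: condition-unique peaks, the exon +/- 250 bp high-confidence
overlap rule, the three-way Venn, and PSI/isoform-ratio arithmetic for
gel- or electropherogram-based validation.

All windows are half-open.  A peak is unique to a condition when no
same-strand peak of the other condition overlaps it by >= 1 nt.  The
high-confidence window around a cassette exon extends ``flank_nt`` into
each neighbouring intron, truncated at the intron's far end so the window
never reaches the neighbouring exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from clipsplice.differential import ASEventRecord
from clipsplice.peaks import PeakRecord


@dataclass
class HighConfidenceHit:
    event_id: str
    peak_id: str
    relation: str  # within_exon | upstream_flank | downstream_flank
    distance_nt: int  # peak edge to nearer exon boundary; 0 within exon


@dataclass
class CrossRefSummary:
    """Seven-cell Venn of DE genes, AS genes, and peak-bearing genes."""

    n_de: int
    n_as: int
    n_peak: int
    cells: dict[str, int]  # exclusive cells keyed de/as/peak/de_as/...
    pct_de_bound: float
    pct_as_bound: float

    def __post_init__(self) -> None:
        c = self.cells
        assert self.n_de == c["de"] + c["de_as"] + c["de_peak"] + c["de_as_peak"]
        assert self.n_as == c["as"] + c["de_as"] + c["as_peak"] + c["de_as_peak"]
        assert self.n_peak == (c["peak"] + c["de_peak"] + c["as_peak"]
                               + c["de_as_peak"])


def _interval_index(peaks: Iterable[PeakRecord]):
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in peaks:
        by_key.setdefault((p.contig, p.strand), []).append((p.start, p.end))
    return {k: sorted(v) for k, v in by_key.items()}


class _OverlapIndex:
    """Max-end-prefix interval index for any-overlap queries."""

    def __init__(self, peaks: Iterable[PeakRecord]):
        self._idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for key, ivs in _interval_index(peaks).items():
            starts = np.array([a for a, _ in ivs])
            ends = np.maximum.accumulate(np.array([b for _, b in ivs]))
            self._idx[key] = (starts, ends)

    def any_overlap(self, contig: str, strand: str, start: int, end: int) -> bool:
        key = (contig, strand)
        if key not in self._idx:
            return False
        starts, max_ends = self._idx[key]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and max_ends[i - 1] > start


def condition_unique_peaks(
        peaks_a: Sequence[PeakRecord],
        peaks_b: Sequence[PeakRecord]) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Peaks of each condition with no >= 1 nt same-strand overlap in the other."""
    idx_a, idx_b = _OverlapIndex(peaks_a), _OverlapIndex(peaks_b)
    unique_a = [p for p in peaks_a
                if not idx_b.any_overlap(p.contig, p.strand, p.start, p.end)]
    unique_b = [p for p in peaks_b
                if not idx_a.any_overlap(p.contig, p.strand, p.start, p.end)]
    return unique_a, unique_b


def _event_window(event: ASEventRecord, flank_nt: int) -> tuple[int, int]:
    """Genomic window: exon extended flank_nt into each flanking intron,
    truncated at the intron's far end."""
    ts, te = event.target_exon
    if event.strand == "+":
        left_gap = ts - event.upstream_exon[1]
        right_gap = event.downstream_exon[0] - te
    else:
        left_gap = ts - event.downstream_exon[1]
        right_gap = event.upstream_exon[0] - te
    left = min(flank_nt, max(left_gap, 0))
    right = min(flank_nt, max(right_gap, 0))
    return ts - left, te + right


def highconf_overlap(unique_peaks: Sequence[PeakRecord],
                     events: Sequence[ASEventRecord],
                     flank_nt: int = 250) -> list[HighConfidenceHit]:
    """Peak/event pairs where the peak falls within the alternatively
    spliced exon or within ``flank_nt`` of the neighbouring introns."""
    by_key: dict[tuple[str, str], list[PeakRecord]] = {}
    for p in unique_peaks:
        by_key.setdefault((p.contig, p.strand), []).append(p)
    hits = []
    for e in events:
        ts, te = e.target_exon
        ws, we = _event_window(e, flank_nt)
        for p in by_key.get((e.contig, e.strand), []):
            if p.end <= ws or p.start >= we:
                continue
            if p.start < te and p.end > ts:
                relation, dist = "within_exon", 0
            elif p.start >= te:
                dist = p.start - te
                relation = ("downstream_flank" if e.strand == "+"
                            else "upstream_flank")
            else:
                dist = ts - p.end
                relation = ("upstream_flank" if e.strand == "+"
                            else "downstream_flank")
            hits.append(HighConfidenceHit(e.event_id, p.peak_id, relation, dist))
    return hits


def three_way_crossref(de_genes: Iterable[str], as_genes: Iterable[str],
                       peak_genes: Iterable[str],
                       transcript_to_gene: Optional[Mapping[str, str]] = None
                       ) -> CrossRefSummary:
    """Venn of DE genes, alternatively spliced genes, and peak-bearing genes.

    All sets are collapsed to gene level; ``transcript_to_gene`` maps any
    transcript-level identifiers onto genes before intersection.
    """
    def collapse(ids: Iterable[str]) -> set[str]:
        if transcript_to_gene is None:
            return set(ids)
        return {transcript_to_gene.get(i, i) for i in ids}

    de, as_, pk = collapse(de_genes), collapse(as_genes), collapse(peak_genes)
    cells = {
        "de": len(de - as_ - pk),
        "as": len(as_ - de - pk),
        "peak": len(pk - de - as_),
        "de_as": len((de & as_) - pk),
        "de_peak": len((de & pk) - as_),
        "as_peak": len((as_ & pk) - de),
        "de_as_peak": len(de & as_ & pk),
    }
    return CrossRefSummary(
        n_de=len(de), n_as=len(as_), n_peak=len(pk), cells=cells,
        pct_de_bound=100.0 * len(de & pk) / len(de) if de else 0.0,
        pct_as_bound=100.0 * len(as_ & pk) / len(as_) if as_ else 0.0,
    )


def psi_from_abundances(abundances: Sequence[float],
                        larger_first: bool = True) -> float:
    """Percent spliced in from isoform abundances: 100 x larger / total.

    With ``larger_first`` the first abundance is the larger isoform's;
    otherwise the maximum is used.
    """
    if len(abundances) < 2:
        raise ValueError("need >= 2 isoform abundances")
    if any(a < 0 for a in abundances):
        raise ValueError("negative abundance")
    total = sum(abundances)
    if total == 0:
        raise ValueError("all abundances zero")
    larger = abundances[0] if larger_first else max(abundances)
    return 100.0 * larger / total


def isoform_ratio(larger_fraction: float, smaller_fraction: float,
                  control_larger: float = 1.0,
                  control_smaller: float = 1.0) -> float:
    """Larger/smaller isoform ratio after loading-control normalisation."""
    if smaller_fraction <= 0:
        raise ValueError("smaller fraction must be > 0")
    if control_larger <= 0 or control_smaller <= 0:
        raise ValueError("control values must be > 0")
    return (larger_fraction / control_larger) / (smaller_fraction / control_smaller)
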