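"""Cassette-exon sequence features and nonparametric group comparison.

For each skipped-exon (SE) event the target exon's GC content, the GC of
its two flanking introns, and the intron:exon GC and length ratios are
computed, with upstream/downstream defined in transcript orientation.
Group distributions (e.g. exons included vs skipped when the RBP is
present) are compared with a two-sided Mann-Whitney U-test: exact
enumeration for small samples, normal approximation with tie correction
otherwise.  Intron GC uses the full intron length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from clipsplice.differential import ASEventRecord
from clipsplice.genome import GenomeSequence, TranscriptModel, gc_content
from clipsplice.peaks import PeakRecord, _CoverageIndex

logger = logging.getLogger(__name__)

EXACT_MW_MAX_N = 20  # combined sample size up to which the exact null is used


@dataclass
class ExonFeatureRecord:
    event_id: str
    exon_gc: float  # percent
    up_intron_gc: float
    down_intron_gc: float
    down_intron_to_exon_gc_ratio: float
    up_intron_to_exon_length_ratio: float
    down_intron_to_exon_length_ratio: float
    group: str = ""

    def __post_init__(self) -> None:
        for v in (self.exon_gc, self.up_intron_gc, self.down_intron_gc):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"GC percentage {v} outside [0, 100]")


def _flanking_introns(event: ASEventRecord) -> tuple[tuple[int, int], tuple[int, int]]:
    """(upstream, downstream) intron intervals in transcript orientation.

    On the minus strand the transcript-orientation upstream exon lies at
    higher genomic coordinates, so the genomic gaps swap roles.
    """
    ts, te = event.target_exon
    if event.strand == "+":
        up = (event.upstream_exon[1], ts)
        down = (te, event.downstream_exon[0])
    else:
        up = (te, event.upstream_exon[0])
        down = (event.downstream_exon[1], ts)
    for name, (a, b) in (("upstream", up), ("downstream", down)):
        if b <= a:
            raise ValueError(
                f"event {event.event_id}: zero-length {name} intron")
    return up, down


def compute_features(event: ASEventRecord, genome: GenomeSequence,
                     group: str = "") -> ExonFeatureRecord:
    """Sequence features of one cassette exon and its flanking introns."""
    if event.event_type != "SE":
        raise ValueError("feature analysis is defined for SE events")
    up, down = _flanking_introns(event)
    exon_seq = genome.fetch(event.contig, *event.target_exon)
    exon_gc = 100.0 * gc_content(exon_seq)
    if exon_gc == 0.0:
        raise ValueError(
            f"event {event.event_id}: exon GC is 0%; GC ratio undefined")
    up_gc = 100.0 * gc_content(genome.fetch(event.contig, *up))
    down_gc = 100.0 * gc_content(genome.fetch(event.contig, *down))
    exon_len = event.target_exon[1] - event.target_exon[0]
    return ExonFeatureRecord(
        event_id=event.event_id,
        exon_gc=exon_gc,
        up_intron_gc=up_gc,
        down_intron_gc=down_gc,
        down_intron_to_exon_gc_ratio=down_gc / exon_gc,
        up_intron_to_exon_length_ratio=(up[1] - up[0]) / exon_len,
        down_intron_to_exon_length_ratio=(down[1] - down[0]) / exon_len,
        group=group,
    )


def compute_feature_table(events: Iterable[ASEventRecord],
                          genome: GenomeSequence,
                          groups: Optional[dict[str, str]] = None,
                          include_non_se: bool = False) -> list[ExonFeatureRecord]:
    """Batch feature computation; unusable events are skipped with a log line.

    ``groups`` maps event_id to a group label.  Non-SE event types are
    excluded by default (the features are defined on cassette exons).
    """
    out = []
    for e in events:
        if e.event_type != "SE" and not include_non_se:
            continue
        try:
            rec = compute_features(e, genome,
                                   group=(groups or {}).get(e.event_id, ""))
        except (ValueError, KeyError) as exc:
            logger.info("skipping event %s: %s", e.event_id, exc)
            continue
        out.append(rec)
    return out


def mann_whitney(values_a: Sequence[float],
                 values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U for the first sample) and p.

    Exact-enumeration null for combined n <= EXACT_MW_MAX_N without ties;
    normal approximation with tie correction and continuity correction
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_MAX_N and not has_ties) \
        else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-tied degenerate input
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # identical constant groups: no evidence either way
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def group_compare(records: Sequence[ExonFeatureRecord], group_a: str,
                  group_b: str, feature: str = "exon_gc") -> dict:
    """Compare one feature between two groups: medians, U, two-sided p."""
    va = [getattr(r, feature) for r in records if r.group == group_a]
    vb = [getattr(r, feature) for r in records if r.group == group_b]
    if not va or not vb:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    u, p = mann_whitney(va, vb)
    return {
        "feature": feature,
        "group_a": group_a, "group_b": group_b,
        "n_a": len(va), "n_b": len(vb),
        "median_a": float(np.median(va)), "median_b": float(np.median(vb)),
        "U": u, "p": p,
    }


def bound_vs_unbound_features(
        peaks_by_condition: dict[str, Sequence[PeakRecord]],
        annotation: Sequence[TranscriptModel],
        genome: GenomeSequence) -> list[ExonFeatureRecord]:
    """Label every internal exon by CLIP-binding status and compute features.

    With two conditions (say "minus" and "plus"), an exon overlapped by
    same-strand peaks from only the first is ``bound_minus``, only the
    second ``bound_plus``, both ``bound``, neither ``unbound``.
    """
    conditions = list(peaks_by_condition)
    indexes = {c: _CoverageIndex(peaks_by_condition[c]) for c in conditions}
    out = []
    for m in annotation:
        if len(m.exons) < 3:
            continue
        internal = list(enumerate(m.exons))[1:-1]
        for i, (a, b) in internal:
            hit = [c for c in conditions
                   if indexes[c].covered(m.contig, m.strand,
                                         np.arange(a, b)).any()]
            if not hit:
                group = "unbound"
            elif len(hit) == len(conditions) and len(conditions) > 1:
                group = "bound"
            else:
                group = f"bound_{hit[0]}"
            prev_end = m.exons[i - 1][1]
            next_start = m.exons[i + 1][0]
            # transcript-orientation intron assignment
            if m.strand == "+":
                up, down = (prev_end, a), (b, next_start)
            else:
                up, down = (b, next_start), (prev_end, a)
            try:
                exon_gc = 100.0 * gc_content(genome.fetch(m.contig, a, b))
                if exon_gc == 0.0:
                    raise ValueError("exon GC is 0%")
                up_gc = 100.0 * gc_content(genome.fetch(m.contig, *up))
                down_gc = 100.0 * gc_content(genome.fetch(m.contig, *down))
            except ValueError as exc:
                logger.info("skipping exon %s:%d-%d: %s", m.contig, a, b, exc)
                continue
            out.append(ExonFeatureRecord(
                event_id=f"{m.transcript_id}:exon{i}",
                exon_gc=exon_gc,
                up_intron_gc=up_gc,
                down_intron_gc=down_gc,
                down_intron_to_exon_gc_ratio=down_gc / exon_gc,
                up_intron_to_exon_length_ratio=(up[1] - up[0]) / (b - a),
                down_intron_to_exon_length_ratio=(down[1] - down[0]) / (b - a),
                group=group,
            ))
    return out
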