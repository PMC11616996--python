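"""Differential-expression and alternative-splicing tables: parsing,
threshold filtering, and cross-comparison summaries.

Filtering conventions follow the source study's figure legends verbatim:
DE genes are significant at adjusted p < 0.05 (strict) and |FC| >= 2
(|log2FC| >= 1); AS events at FDR <= 0.05 and |dPSI| >= 0.05 (both
inclusive), plus detection in at least 10 junction reads in either
condition.  dPSI sign is taken from the table (condition1 PSI - condition2
PSI per the comparison's stated orientation); the recomputed value from
replicate inclusion levels is used only as a validation warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")

# rMATS-dialect coordinate columns per event type, mapped onto
# (target exon, upstream exon, downstream exon).  Upstream/downstream are
# transcript-orientation, as in rMATS output.
_RMATS_COORDS = {
    "SE": ("exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"),
    "RI": ("riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"),
    "MXE": ("1stExonStart_0base", "1stExonEnd", "upstreamES", "upstreamEE",
            "downstreamES", "downstreamEE"),
    "A5SS": ("longExonStart_0base", "longExonEnd", "flankingES", "flankingEE",
             "flankingES", "flankingEE"),
    "A3SS": ("longExonStart_0base", "longExonEnd", "flankingES", "flankingEE",
             "flankingES", "flankingEE"),
}


@dataclass
class DEGeneRecord:
    gene_id: str
    log2fc: float
    padj: Optional[float]

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj {self.padj} outside [0, 1]")


@dataclass
class ASEventRecord:
    """One rMATS-dialect splicing event.

    Coordinates are 0-based half-open genomic intervals; ``upstream_exon``
    and ``downstream_exon`` are the flanking exons in transcript
    orientation.  ``inc1``/``inc2`` are per-replicate PSI fractions;
    ``ijc1``/``sjc1``/``ijc2``/``sjc2`` are per-replicate inclusion and
    skipping junction read counts.
    """

    event_id: str
    gene_id: str
    event_type: str
    contig: str
    strand: str
    target_exon: tuple[int, int]
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    inc1: list[float]
    inc2: list[float]
    delta_psi: float
    fdr: float
    ijc1: list[int] = field(default_factory=list)
    sjc1: list[int] = field(default_factory=list)
    ijc2: list[int] = field(default_factory=list)
    sjc2: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR {self.fdr} outside [0, 1]")
        if abs(self.delta_psi) > 1.0 + 1e-9:
            raise ValueError(f"|dPSI| {self.delta_psi} exceeds 1")
        for counts in (self.ijc1, self.sjc1, self.ijc2, self.sjc2):
            if any(c < 0 for c in counts):
                raise ValueError("negative junction count")

    @property
    def coord_key(self) -> tuple:
        """Run-stable identity: type + strand-aware coordinate tuple."""
        return (self.event_type, self.contig, self.strand,
                self.target_exon, self.upstream_exon, self.downstream_exon)

    def reads_condition(self, condition: int) -> int:
        """Total junction reads (inclusion + skipping, all replicates)."""
        if condition == 1:
            return sum(self.ijc1) + sum(self.sjc1)
        return sum(self.ijc2) + sum(self.sjc2)

    def reads_per_replicate(self, condition: int) -> list[int]:
        ijc, sjc = (self.ijc1, self.sjc1) if condition == 1 else (self.ijc2, self.sjc2)
        return [i + s for i, s in zip(ijc, sjc)]


@dataclass
class ComparisonSummary:
    """Venn-style overlap of two significant sets plus sign concordance."""

    n_a: int
    n_b: int
    n_shared: int
    n_union: int
    shared_pct: float  # intersection as % of union
    n_concordant: Optional[int] = None
    concordant_pct: Optional[float] = None
    n_shared_up: Optional[int] = None
    n_shared_down: Optional[int] = None

    def __post_init__(self) -> None:
        assert self.n_shared <= min(self.n_a, self.n_b)
        assert self.n_union == self.n_a + self.n_b - self.n_shared

    @classmethod
    def from_counts(cls, n_a: int, n_b: int, n_shared: int) -> "ComparisonSummary":
        """Summary from set sizes alone (e.g. counts printed in a report)."""
        union = n_a + n_b - n_shared
        pct = 100.0 * n_shared / union if union else 0.0
        return cls(n_a, n_b, n_shared, union, pct)


def read_de_table(path: str | Path, gene_col: str = "gene_id",
                  lfc_col: str = "log2FoldChange",
                  padj_col: str = "padj") -> list[DEGeneRecord]:
    """Read a DESeq2-style TSV of gene, log2 fold change, adjusted p."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        padj = getattr(row, padj_col)
        lfc = getattr(row, lfc_col)
        records.append(DEGeneRecord(
            gene_id=str(getattr(row, gene_col)),
            log2fc=float(lfc),
            padj=None if pd.isna(padj) else float(padj),
        ))
    return records


def _parse_levels(cell: str) -> list[float]:
    return [float(x) for x in str(cell).split(",") if x not in ("", "NA")]


def _parse_counts(cell: str) -> list[int]:
    return [int(x) for x in str(cell).split(",") if x not in ("", "NA")]


def read_rmats_table(path: str | Path, event_type: str,
                     validate_dpsi: bool = True) -> list[ASEventRecord]:
    """Read one rMATS JC-dialect TSV (one event type per file).

    ``IncLevelDifference`` is authoritative for dPSI; when it disagrees
    with the replicate-mean difference by more than 0.01 a warning is
    emitted but the table value is kept.
    """
    if event_type not in _RMATS_COORDS:
        raise ValueError(f"unknown event type {event_type!r}")
    ts, te, us, ue, ds, de_ = _RMATS_COORDS[event_type]
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    records = []
    for _, row in df.iterrows():
        inc1 = _parse_levels(row["IncLevel1"])
        inc2 = _parse_levels(row["IncLevel2"])
        dpsi = float(row["IncLevelDifference"])
        if validate_dpsi and inc1 and inc2:
            recomputed = float(np.mean(inc1) - np.mean(inc2))
            if abs(recomputed - dpsi) > 0.01:
                warnings.warn(
                    f"event {row['ID']}: IncLevelDifference {dpsi:.3f} "
                    f"disagrees with replicate means ({recomputed:.3f})",
                    stacklevel=2,
                )
        records.append(ASEventRecord(
            event_id=str(row["ID"]),
            gene_id=str(row["GeneID"]),
            event_type=event_type,
            contig=str(row["chr"]),
            strand=str(row["strand"]),
            target_exon=(int(row[ts]), int(row[te])),
            upstream_exon=(int(row[us]), int(row[ue])),
            downstream_exon=(int(row[ds]), int(row[de_])),
            inc1=inc1,
            inc2=inc2,
            delta_psi=dpsi,
            fdr=float(row["FDR"]),
            ijc1=_parse_counts(row["IJC_SAMPLE_1"]),
            sjc1=_parse_counts(row["SJC_SAMPLE_1"]),
            ijc2=_parse_counts(row["IJC_SAMPLE_2"]),
            sjc2=_parse_counts(row["SJC_SAMPLE_2"]),
        ))
    return records


def filter_de(records: Iterable[DEGeneRecord], padj_max: float = 0.05,
              min_abs_fc: float = 2.0) -> list[DEGeneRecord]:
    """Significant DE genes: padj < padj_max (strict) and |FC| >= min_abs_fc.

    The fold-change threshold is applied on the linear scale, i.e.
    |log2fc| >= log2(min_abs_fc).  Records with missing padj are dropped.
    """
    min_abs_lfc = math.log2(min_abs_fc)
    out = []
    for r in records:
        if r.padj is None or not math.isfinite(r.log2fc):
            continue
        if r.padj < padj_max and abs(r.log2fc) >= min_abs_lfc:
            out.append(r)
    return out


def filter_as(records: Iterable[ASEventRecord], fdr_max: float = 0.05,
              min_abs_dpsi: float = 0.05, min_reads: int = 10,
              per_replicate_reads: bool = False) -> list[ASEventRecord]:
    """Significant AS events: FDR <= fdr_max, |dPSI| >= min_abs_dpsi (both
    inclusive), and >= min_reads junction reads in either condition.

    The read rule sums inclusion + skipping counts across replicates
    within a condition by default; ``per_replicate_reads=True`` instead
    requires one replicate alone to reach the threshold.
    """
    out = []
    for r in records:
        if r.fdr > fdr_max or abs(r.delta_psi) < min_abs_dpsi:
            continue
        if per_replicate_reads:
            detected = (any(c >= min_reads for c in r.reads_per_replicate(1))
                        or any(c >= min_reads for c in r.reads_per_replicate(2)))
        else:
            detected = (r.reads_condition(1) >= min_reads
                        or r.reads_condition(2) >= min_reads)
        if detected:
            out.append(r)
    return out


def _key_sign_map(items: Sequence, key, sign) -> dict:
    out = {}
    for it in items:
        k = key(it)
        if k in out:
            raise ValueError(f"duplicate key {k!r} within one set")
        out[k] = sign(it)
    return out


def overlap_summary(set_a: Sequence, set_b: Sequence,
                    key=None, direction=None) -> ComparisonSummary:
    """Intersection/union of two significant sets with sign concordance.

    ``set_a``/``set_b`` are DE or AS records; ``key`` defaults to gene_id
    for DE records and the coordinate tuple for AS records, ``direction``
    to the sign of log2fc / delta_psi.  Duplicate keys within one set are
    an error.
    """
    def default_key(it):
        return it.coord_key if isinstance(it, ASEventRecord) else it.gene_id

    def default_direction(it):
        v = it.delta_psi if isinstance(it, ASEventRecord) else it.log2fc
        return int(np.sign(v))

    key = key or default_key
    direction = direction or default_direction
    a = _key_sign_map(set_a, key, direction)
    b = _key_sign_map(set_b, key, direction)
    shared = set(a) & set(b)
    union = len(a) + len(b) - len(shared)
    pct = 100.0 * len(shared) / union if union else 0.0
    conc = sum(1 for k in shared if a[k] == b[k] and a[k] != 0)
    up = sum(1 for k in shared if a[k] == b[k] == 1)
    down = sum(1 for k in shared if a[k] == b[k] == -1)
    return ComparisonSummary(
        n_a=len(a), n_b=len(b), n_shared=len(shared), n_union=union,
        shared_pct=pct,
        n_concordant=conc,
        concordant_pct=(100.0 * conc / len(shared)) if shared else None,
        n_shared_up=up, n_shared_down=down,
    )


def event_type_composition(events: Sequence[ASEventRecord]) -> dict:
    """Counts and fractions per event type, plus dPSI-sign split within SE.

    Fractions are over all events; the SE sign split (``se_pos_frac`` /
    ``se_neg_frac``) is likewise reported as a fraction of all events, so
    the two sum to the SE fraction.
    """
    counts = {t: 0 for t in EVENT_TYPES}
    se_pos = se_neg = 0
    for e in events:
        counts[e.event_type] += 1
        if e.event_type == "SE":
            if e.delta_psi > 0:
                se_pos += 1
            elif e.delta_psi < 0:
                se_neg += 1
    total = len(events)
    fractions = {t: (counts[t] / total if total else 0.0) for t in EVENT_TYPES}
    return {
        "counts": counts,
        "total": total,
        "fractions": fractions,
        "se_pos_count": se_pos,
        "se_neg_count": se_neg,
        "se_pos_frac": se_pos / total if total else 0.0,
        "se_neg_frac": se_neg / total if total else 0.0,
    }
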