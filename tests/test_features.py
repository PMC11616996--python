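"""Cassette-exon features and the Mann-Whitney comparison machinery."""

import itertools

import numpy as np
import pytest

from clipsplice.differential import ASEventRecord
from clipsplice.features import (bound_vs_unbound_features, compute_features,
                                 compute_feature_table, group_compare,
                                 mann_whitney)
from clipsplice.genome import GenomeSequence, TranscriptModel, reverse_complement
from clipsplice.peaks import PeakRecord


def make_se_event(strand="+", exon_gc=0.6, intron_gc=0.5, exon_len=100,
                  up_intron=200, down_intron=300):
    """Deterministic toy SE event over a constructed genome.

    Layout (genomic, left to right): flank exon, intron, target exon,
    intron, flank exon.  For the minus strand the transcript-orientation
    upstream exon is the genomically-right one.
    """
    def block(length, gc):
        n_gc = round(length * gc)
        return "G" * n_gc + "A" * (length - n_gc)

    left_intron, right_intron = ((up_intron, down_intron) if strand == "+"
                                 else (down_intron, up_intron))
    seq = (block(50, 0.5) + block(left_intron, intron_gc)
           + block(exon_len, exon_gc) + block(right_intron, intron_gc)
           + block(50, 0.5))
    genome = GenomeSequence({"c": seq})
    ts = 50 + left_intron
    te = ts + exon_len
    left_exon = (0, 50)
    right_exon = (te + right_intron, te + right_intron + 50)
    up_exon, down_exon = ((left_exon, right_exon) if strand == "+"
                          else (right_exon, left_exon))
    event = ASEventRecord(
        event_id="e", gene_id="g", event_type="SE", contig="c", strand=strand,
        target_exon=(ts, te), upstream_exon=up_exon, downstream_exon=down_exon,
        inc1=[0.5], inc2=[0.4], delta_psi=0.1, fdr=0.01,
        ijc1=[20], sjc1=[20], ijc2=[20], sjc2=[20])
    return event, genome


def exact_mw_p(a, b):
    """Independent oracle: full enumeration of label arrangements."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(idx):
        r = sum(ranks[pooled[i]] for i in idx)
        return r - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    n_total = 0
    n_extreme = 0
    mean_u = n_a * len(b) / 2
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = u_of(idx)
        n_total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            n_extreme += 1
    return n_extreme / n_total


class TestComputeFeatures:
    def test_gc_ratio_arithmetic(self):
        event, genome = make_se_event(exon_gc=0.6, intron_gc=0.5)
        r = compute_features(event, genome)
        assert r.exon_gc == pytest.approx(60.0)
        assert r.down_intron_to_exon_gc_ratio == pytest.approx(0.8333, abs=1e-3)

    def test_length_ratio_arithmetic(self):
        event, genome = make_se_event(exon_len=100, up_intron=1240)
        r = compute_features(event, genome)
        assert r.up_intron_to_exon_length_ratio == pytest.approx(12.4)

    def test_minus_strand_mirrors_plus(self):
        plus_event, plus_genome = make_se_event(
            strand="+", up_intron=200, down_intron=300)
        minus_event, minus_genome = make_se_event(
            strand="-", up_intron=200, down_intron=300)
        rp = compute_features(plus_event, plus_genome)
        rm = compute_features(minus_event, minus_genome)
        assert rm.up_intron_to_exon_length_ratio == pytest.approx(
            rp.up_intron_to_exon_length_ratio)
        assert rm.down_intron_to_exon_length_ratio == pytest.approx(
            rp.down_intron_to_exon_length_ratio)

    def test_full_mirror_symmetry(self):
        """Reverse-complementing the genome and flipping strand and
        coordinates leaves every feature unchanged."""
        event, genome = make_se_event(strand="+", exon_gc=0.55,
                                      up_intron=150, down_intron=250)
        L = len(genome.contigs["c"])
        mirror_genome = GenomeSequence(
            {"c": reverse_complement(genome.contigs["c"])})

        def flip(iv):
            return (L - iv[1], L - iv[0])

        mirror_event = ASEventRecord(
            event_id="e", gene_id="g", event_type="SE", contig="c",
            strand="-", target_exon=flip(event.target_exon),
            upstream_exon=flip(event.upstream_exon),
            downstream_exon=flip(event.downstream_exon),
            inc1=[0.5], inc2=[0.4], delta_psi=0.1, fdr=0.01,
            ijc1=[20], sjc1=[20], ijc2=[20], sjc2=[20])
        a = compute_features(event, genome)
        b = compute_features(mirror_event, mirror_genome)
        for field in ("exon_gc", "up_intron_gc", "down_intron_gc",
                      "down_intron_to_exon_gc_ratio",
                      "up_intron_to_exon_length_ratio",
                      "down_intron_to_exon_length_ratio"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))

    def test_non_se_rejected(self):
        event, genome = make_se_event()
        event.event_type = "RI"
        with pytest.raises(ValueError, match="SE"):
            compute_features(event, genome)

    def test_zero_length_intron_rejected(self):
        event, genome = make_se_event()
        event.upstream_exon = (event.target_exon[0] - 100, event.target_exon[0])
        with pytest.raises(ValueError, match="intron"):
            compute_features(event, genome)

    def test_batch_skips_bad_events(self):
        good, genome = make_se_event()
        bad, _ = make_se_event()
        bad.event_id = "bad"
        bad.upstream_exon = (bad.target_exon[0] - 100, bad.target_exon[0])
        out = compute_feature_table([good, bad], genome, {"e": "included"})
        assert [r.event_id for r in out] == ["e"]
        assert out[0].group == "included"


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_groups(self):
        u, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n^2 / 2
        assert p > 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.choice(1000, size=4, replace=False))
        b = list(rng.choice(2000, size=5, replace=False) + 1000)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(exact_mw_p(a, b), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_and_asymptotic_agree_at_boundary(self, seed):
        """At combined n = 20 without heavy ties the exact null and the
        tie-corrected normal approximation give nearly identical p."""
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.4, 1, 10)
        _, p_pkg = mann_whitney(list(a), list(b))  # exact path at n=20
        p_norm = mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(p_pkg - p_norm) <= 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])


class TestGroupCompare:
    def test_medians_and_significance(self):
        recs = []
        rng = np.random.default_rng(0)
        for i in range(50):
            e, g = make_se_event(exon_gc=0.53 + rng.normal(0, 0.01))
            r = compute_features(e, g)
            r.group = "included"
            r.event_id = f"i{i}"
            recs.append(r)
        for i in range(50):
            e, g = make_se_event(exon_gc=0.50 + rng.normal(0, 0.01))
            r = compute_features(e, g)
            r.group = "skipped"
            r.event_id = f"s{i}"
            recs.append(r)
        out = group_compare(recs, "included", "skipped", "exon_gc")
        assert out["median_a"] > out["median_b"]
        assert out["p"] < 0.05
        assert out["n_a"] == out["n_b"] == 50

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_compare([], "included", "skipped")


class TestBoundVsUnbound:
    def _toy(self):
        exons = [(0, 100), (200, 300), (400, 500), (600, 700)]
        m = TranscriptModel("t", "g", "c", "+", exons, cds_span=(50, 650))
        seq = "".join("GCAT"[i % 4] for i in range(710))
        genome = GenomeSequence({"c": seq})
        return m, genome

    def test_no_peaks_all_unbound(self):
        m, genome = self._toy()
        out = bound_vs_unbound_features({"minus": [], "plus": []}, [m], genome)
        assert len(out) == 2  # two internal exons
        assert all(r.group == "unbound" for r in out)

    def test_single_condition_label(self):
        m, genome = self._toy()
        p = PeakRecord("p", "c", 250, 260, "+", condition="minus")
        out = bound_vs_unbound_features({"minus": [p], "plus": []}, [m], genome)
        by_id = {r.event_id: r.group for r in out}
        assert by_id["t:exon1"] == "bound_minus"
        assert by_id["t:exon2"] == "unbound"

    def test_both_conditions_label(self):
        m, genome = self._toy()
        pm = PeakRecord("p1", "c", 250, 260, "+", condition="minus")
        pp = PeakRecord("p2", "c", 280, 290, "+", condition="plus")
        out = bound_vs_unbound_features({"minus": [pm], "plus": [pp]},
                                        [m], genome)
        by_id = {r.event_id: r.group for r in out}
        assert by_id["t:exon1"] == "bound"

    def test_matches_bruteforce_overlap_labels(self):
        rng = np.random.default_rng(9)
        from conftest import random_transcript, random_genome_for
        models = [random_transcript(rng, start=i * 1500) for i in range(4)]
        models = [m for m in models if len(m.exons) >= 3]
        genome = random_genome_for(models, rng)
        starts = [int(rng.integers(0, 5000)) for _ in range(6)]
        peaks = {
            "minus": [PeakRecord(f"a{i}", "chr1", s, s + 40,
                                 "+" if rng.random() < 0.5 else "-")
                      for i, s in enumerate(starts[:3])],
            "plus": [PeakRecord(f"b{i}", "chr1", s, s + 40,
                                "+" if rng.random() < 0.5 else "-")
                     for i, s in enumerate(starts[3:])],
        }
        out = bound_vs_unbound_features(peaks, models, genome)
        by_id = {r.event_id: r.group for r in out}
        for m in models:
            for i, (a, b) in list(enumerate(m.exons))[1:-1]:
                hit = [c for c in ("minus", "plus")
                       if any(p.start < b and p.end > a
                              and p.strand == m.strand
                              for p in peaks[c])]
                expected = ("unbound" if not hit else
                            "bound" if len(hit) == 2 else f"bound_{hit[0]}")
                key = f"{m.transcript_id}:exon{i}"
                if key in by_id:
                    assert by_id[key] == expected
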