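"""Peak-to-region assignment, composition, and metaprofiles, checked
against independent per-base brute-force oracles."""

import numpy as np
import pytest

from clipsplice.genome import (SpliceSite, TranscriptModel, derive_regions,
                               splice_sites)
from clipsplice.peaks import (MetaProfile, PeakRecord, RegionAssignment,
                              annotate_peaks, assign_region, read_bed,
                              region_composition, splice_site_metaprofile,
                              transcript_metaprofile, write_bed)
from conftest import random_transcript

PRIORITY = {"CDS": 3, "5'UTR": 2, "3'UTR": 1, "intron": 0}


def brute_force_assignment(peak, region_sets):
    """Independent oracle: per-base label counting with the stated
    tie-break (max overlap, then CDS > 5'UTR > 3'UTR > intron, then
    longest CDS, then transcript id)."""
    candidates = []
    for rs in region_sets:
        if rs.contig != peak.contig or rs.strand != peak.strand:
            continue
        tally = {}
        for base in range(peak.start, peak.end):
            for label, a, b in rs.regions:
                if a <= base < b:
                    tally[label] = tally.get(label, 0) + 1
        cds_len = sum(b - a for lab, a, b in rs.regions if lab == "CDS")
        for label, n in tally.items():
            candidates.append((-n, -PRIORITY[label], -cds_len,
                               rs.transcript_id, label))
    if not candidates:
        return None
    best = min(candidates)
    return (best[4], best[3], -best[0])


def brute_force_site_coverage(peaks, site, offset):
    if site.strand == "+":
        base = site.position + offset
    else:
        base = site.position - 1 - offset
    return any(p.start <= base < p.end for p in peaks
               if p.contig == site.contig and p.strand == site.strand)


class TestAssignRegion:
    def setup_method(self):
        self.model = TranscriptModel("t1", "g1", "chr1", "+",
                                     [(0, 100), (200, 300)], cds_span=(50, 250))
        self.rs = [derive_regions(self.model)]

    def test_wholly_in_cds(self):
        p = PeakRecord("p", "chr1", 60, 90, "+")
        a = assign_region(p, self.rs)
        assert a.label == "CDS" and a.overlap_nt == 30

    def test_max_overlap_wins(self):
        # 30 nt CDS (70..100) + 70 nt intron (100..170)
        p = PeakRecord("p", "chr1", 70, 170, "+")
        assert assign_region(p, self.rs).label == "intron"

    def test_tie_goes_to_cds(self):
        # 50 nt CDS (50..100) + 50 nt intron (100..150)
        p = PeakRecord("p", "chr1", 50, 150, "+")
        assert assign_region(p, self.rs).label == "CDS"

    def test_antisense_peak_unassigned(self):
        p = PeakRecord("p", "chr1", 60, 90, "-")
        assert assign_region(p, self.rs) is None

    def test_unknown_contig_rejected(self):
        p = PeakRecord("p", "chr9", 60, 90, "+")
        with pytest.raises(ValueError, match="contig"):
            assign_region(p, self.rs)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        models = [random_transcript(rng, start=i * 1500) for i in range(4)]
        region_sets = [derive_regions(m) for m in models]
        for _ in range(20):
            start = int(rng.integers(0, 6000))
            p = PeakRecord("p", "chr1", start, start + int(rng.integers(10, 200)),
                           "+" if rng.random() < 0.5 else "-")
            got = assign_region(p, region_sets)
            expected = brute_force_assignment(p, region_sets)
            if expected is None:
                assert got is None
            else:
                assert (got.label, got.transcript_id, got.overlap_nt) == expected


class TestRegionComposition:
    def test_reported_counts_give_reported_percentages(self):
        assignments = (
            [RegionAssignment(f"c{i}", "CDS", "t", 10) for i in range(3727)]
            + [RegionAssignment(f"i{i}", "intron", "t", 10) for i in range(1690)]
            + [RegionAssignment(f"u{i}", "5'UTR", "t", 10) for i in range(768)]
            + [RegionAssignment(f"d{i}", "3'UTR", "t", 10) for i in range(367)])
        comp = region_composition(assignments)
        assert comp["total"] == 6552
        assert round(comp["percentages"]["CDS"], 1) == 56.9
        assert round(comp["percentages"]["intron"], 1) == 25.8
        assert round(comp["percentages"]["5'UTR"], 1) == 11.7
        assert round(comp["percentages"]["3'UTR"], 1) == 5.6

    def test_single_label(self):
        comp = region_composition(
            [RegionAssignment("p", "CDS", "t", 5) for _ in range(4)])
        assert comp["percentages"]["CDS"] == 100.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        labels = list(rng.choice(["CDS", "intron", "5'UTR", "3'UTR"], 200))
        comp = region_composition(
            [RegionAssignment(f"p{i}", lab, "t", 1)
             for i, lab in enumerate(labels)])
        assert sum(comp["percentages"].values()) == pytest.approx(100.0)
        for lab in set(labels):
            assert comp["counts"][lab] == labels.count(lab)

    def test_planted_exonic_fraction_recovered(self, small_dataset):
        """Estimated exonic (CDS+UTR) share tracks the planted mixture."""
        ds = small_dataset
        region_sets = [derive_regions(m) for m in ds.annotation]
        for cond in ("minus", "plus"):
            comp = region_composition(
                annotate_peaks(ds.peaks[cond], region_sets))
            exonic = (comp["percentages"]["CDS"] + comp["percentages"]["5'UTR"]
                      + comp["percentages"]["3'UTR"])
            mix = ds.config.region_mixture[cond]
            planted = 100 * (1 - mix["intron"] / sum(mix.values()))
            assert abs(exonic - planted) < 3.0


class TestSpliceSiteMetaprofile:
    def test_no_peaks_all_zero(self):
        sites = [SpliceSite("5SS", "chr1", 500, "+", "t")]
        profs = splice_site_metaprofile([], sites, window_nt=50)
        assert np.all(profs["5SS"].values == 0)

    def test_single_peak_exact_offsets(self):
        # exon side of the 5'SS boundary at 500: offsets -10..-1 = bases 490..499
        sites = [SpliceSite("5SS", "chr1", 500, "+", "t")]
        peaks = [PeakRecord("p", "chr1", 490, 500, "+")]
        prof = splice_site_metaprofile(peaks, sites, window_nt=20)["5SS"]
        expected = {o: (1.0 if -10 <= o <= -1 else 0.0)
                    for o in range(-20, 21)}
        for o, v in zip(prof.offsets, prof.values):
            assert v == expected[int(o)]

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="catalog"):
            splice_site_metaprofile([], [], window_nt=10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        models = [random_transcript(rng, start=i * 1200) for i in range(5)]
        catalog = [s for m in models for s in splice_sites(m)]
        peaks = []
        for i in range(30):
            start = int(rng.integers(0, 6000))
            peaks.append(PeakRecord(f"p{i}", "chr1", start,
                                    start + int(rng.integers(5, 80)),
                                    "+" if rng.random() < 0.5 else "-"))
        window = 40
        profs = splice_site_metaprofile(peaks, catalog, window)
        for kind in ("5SS", "3SS"):
            sites = [s for s in catalog if s.kind == kind]
            for j, o in enumerate(range(-window, window + 1)):
                expected = sum(brute_force_site_coverage(peaks, s, o)
                               for s in sites) / len(sites)
                assert profs[kind].values[j] == pytest.approx(expected)

    def test_duplicated_peaks_leave_profile_unchanged(self):
        rng = np.random.default_rng(7)
        models = [random_transcript(rng, start=i * 1200) for i in range(3)]
        catalog = [s for m in models for s in splice_sites(m)]
        starts = [int(rng.integers(0, 3000)) for _ in range(10)]
        peaks = [PeakRecord(f"p{i}", "chr1", s, s + 50, "+")
                 for i, s in enumerate(starts)]
        base = splice_site_metaprofile(peaks, catalog, 30)
        doubled = splice_site_metaprofile(peaks * 2, catalog, 30)
        for kind in base:
            assert np.array_equal(base[kind].values, doubled[kind].values)


class TestTranscriptMetaprofile:
    def test_fully_covered_transcript(self, two_exon_plus):
        rs = [derive_regions(two_exon_plus)]
        peaks = [PeakRecord("p", "chr1", 0, 300, "+")]
        prof = transcript_metaprofile(peaks, rs, bins_per_region=10)
        assert np.all(prof.values == 1.0)

    def test_no_peaks_all_zero(self, two_exon_plus):
        prof = transcript_metaprofile([], [derive_regions(two_exon_plus)], 10)
        assert np.all(prof.values == 0.0)

    def test_matches_bruteforce_binning_oracle(self):
        rng = np.random.default_rng(11)
        models = [random_transcript(rng, start=i * 1500) for i in range(3)]
        region_sets = [derive_regions(m) for m in models]
        starts = [int(rng.integers(0, 4000)) for _ in range(12)]
        peaks = [PeakRecord(f"p{i}", "chr1", s, s + 60,
                            "+" if rng.random() < 0.5 else "-")
                 for i, s in enumerate(starts)]
        bins = 7
        prof = transcript_metaprofile(peaks, region_sets, bins)
        order = ("5'UTR", "CDS", "intron", "3'UTR")
        hits = np.zeros(4 * bins)
        for rs in region_sets:
            for ri, label in enumerate(order):
                bases = []
                for lab, a, b in sorted(rs.regions, key=lambda r: r[1]):
                    if lab == label:
                        bases.extend(range(a, b))
                if rs.strand == "-":
                    bases = bases[::-1]
                bin_hit = set()
                for i, base in enumerate(bases):
                    covered = any(p.start <= base < p.end for p in peaks
                                  if p.strand == rs.strand)
                    if covered:
                        bin_hit.add((i * bins) // len(bases))
                for bi in bin_hit:
                    hits[ri * bins + bi] += 1
        assert np.allclose(prof.values, hits / len(region_sets))


class TestBedIO:
    def test_round_trip(self, tmp_path):
        peaks = [PeakRecord(f"p{i}", "chr1", i * 100, i * 100 + 50,
                            "+" if i % 2 else "-", score=float(i))
                 for i in range(5)]
        p = tmp_path / "peaks.bed"
        write_bed(peaks, p)
        back = read_bed(p, condition="c")
        for orig, rt in zip(peaks, back):
            assert (rt.contig, rt.start, rt.end, rt.peak_id, rt.strand) == \
                (orig.contig, orig.start, orig.end, orig.peak_id, orig.strand)
            assert rt.condition == "c"

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\n")
        with pytest.raises(ValueError, match="columns"):
            read_bed(p)
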