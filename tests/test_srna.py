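"""Small-RNA pipeline: trimming, structural filter, alignment, normalization,
binning and lost-region calling."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from epilocus import ReferenceLocus, revcomp
from epilocus.srna import (
    SmallRNALibrary,
    align_library,
    align_perfect,
    bin_table,
    call_lost_regions,
    filter_structural,
    mean_bin_abundance,
    normalize_libraries,
    position_coverage,
    size_distribution,
    trim_adapter,
    trim_library,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def naive_align(read: str, seq: str):
    """Brute-force O(n*m) scan oracle for perfect-match alignment."""
    hits = []
    rc = revcomp(read)
    for start in range(len(seq) - len(read) + 1):
        window = seq[start : start + len(read)]
        if window == read:
            hits.append((start + 1, "+"))
        if window == rc:
            hits.append((start + 1, "-"))
    return sorted(hits)


def make_aligned_library(lib_id, locus, inserts: dict[str, int]):
    """Library built straight from trimmed inserts, structural step empty."""
    lib = SmallRNALibrary(id=lib_id, raw_reads=Counter({s + ADAPTER: c for s, c in inserts.items()}))
    trim_library(lib, ADAPTER)
    filter_structural(lib, [])
    align_library(lib, locus)
    return lib


class TestTrimAdapter:
    def test_insert_recovered_before_adapter(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        assert trim_adapter(insert + ADAPTER, ADAPTER) == (insert, "ok")

    def test_no_adapter_rejected(self):
        assert trim_adapter("A" * 36, ADAPTER) == (None, "no_adapter")

    def test_short_insert_rejected_at_boundary(self):
        insert = "ACGTACGTACGTACGTA"  # 17 nt
        assert trim_adapter(insert + ADAPTER, ADAPTER) == (None, "too_short")
        assert trim_adapter(("ACGTACGTACGTACGTAC") + ADAPTER, ADAPTER)[1] == "ok"

    def test_long_insert_rejected(self):
        insert = "A" * 31
        assert trim_adapter(insert + ADAPTER, ADAPTER) == (None, "too_long")

    def test_empty_read_rejected(self):
        assert trim_adapter("", ADAPTER) == (None, "no_adapter")

    def test_leftmost_seed_match_wins(self):
        insert = "C" * 20
        read = insert + ADAPTER[:8] + "T" * 4 + ADAPTER
        assert trim_adapter(read, ADAPTER) == (insert, "ok")


class TestFilterStructural:
    RRNA = ("rRNA", "ACGTACGGTTCAAGGCCTTAGGATCCGGAATTCCGGTTAACCGGTTAA")

    def _lib(self, inserts):
        lib = SmallRNALibrary(id="x")
        lib.inserts = Counter(inserts)
        lib.tallies = {"raw": sum(inserts.values()), "no_adapter": 0, "length_rejected": 0}
        return lib

    def test_interior_kmer_is_structural(self):
        kmer = self.RRNA[1][5:26]  # interior 21-mer
        lib = filter_structural(self._lib({kmer: 3}), [self.RRNA])
        assert lib.tallies["structural"] == 3

    def test_reverse_complement_match_is_structural(self):
        kmer = revcomp(self.RRNA[1][10:31])
        lib = filter_structural(self._lib({kmer: 2}), [self.RRNA])
        assert lib.tallies["structural"] == 2

    def test_no_structural_records_keeps_everything(self):
        lib = filter_structural(self._lib({"ACGT" * 6: 5, "TTTTAAAACCCCGGGGTTTT": 4}), [])
        assert lib.tallies["structural"] == 0
        assert lib.tallies["nonstructural"] == 9
        lib.check_conservation()


class TestAlignPerfect:
    def test_palindromic_read_hits_both_strands_at_same_position(self):
        read = "AACGTACGTT"
        assert revcomp(read) == read
        seq = "TTT" + read + "GGGG"
        assert align_perfect(read, seq) == [(4, "+"), (4, "-")]

    def test_absent_read_has_no_hits(self):
        assert align_perfect("ACGTACGTACGTACGTAC", "T" * 100) == []

    def test_tandem_duplication_doubles_hits(self):
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), size=60))
        seq = "TT" + unit + unit + "AA"
        read = unit[10:34]
        assert len(align_perfect(read, seq)) == 2

    def test_agrees_with_naive_scan_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            start = int(rng.integers(0, 280))
            read = seq[start : start + 21]
            if rng.random() < 0.5:
                read = revcomp(read)
            assert align_perfect(read, seq) == naive_align(read, seq)


class TestNormalization:
    def _lib_with(self, lib_id, locus, n_22, n_24):
        reads = {}
        reads[locus.sequence[10:32]] = n_22   # 22-nt locus read
        reads[locus.sequence[40:64]] = n_24   # 24-nt locus read
        return make_aligned_library(lib_id, locus, reads)

    @pytest.fixture()
    def toy_locus(self):
        rng = np.random.default_rng(23)
        return ReferenceLocus(
            id="toy", sequence="".join(rng.choice(list("ACGT"), size=400)), tss_array_pos=200
        )

    def test_rpm_factor_arithmetic(self, toy_locus):
        lib = self._lib_with("a", toy_locus, n_22=1_000_000, n_24=1_000_000)
        factors = normalize_libraries([lib], mode="rpm")
        assert factors["a"] == pytest.approx(0.5)  # 2M denominator

    def test_anchor_multiplier_arithmetic(self, toy_locus):
        ref = self._lib_with("ref", toy_locus, n_22=100, n_24=900)
        other = self._lib_with("other", toy_locus, n_22=50, n_24=950)
        factors = normalize_libraries([ref, other], mode="rpm_22anchor", reference_library="ref")
        # both denominators are 1000, so the anchor multiplier is 100/50 = 2
        assert factors["other"] / factors["ref"] == pytest.approx(2.0)

    def test_anchored_22nt_totals_equal_across_libraries(self, toy_locus):
        libs = [
            self._lib_with("a", toy_locus, 120, 500),
            self._lib_with("b", toy_locus, 77, 900),
            self._lib_with("c", toy_locus, 300, 100),
        ]
        factors = normalize_libraries(libs, mode="rpm_22anchor")
        totals = []
        for lib in libs:
            n22 = sum(c for s, c in lib.retained.items() if len(s) == 22)
            totals.append(n22 * factors[lib.id])
        assert totals[0] == pytest.approx(totals[1], rel=1e-12)
        assert totals[0] == pytest.approx(totals[2], rel=1e-12)

    def test_zero_denominator_names_library(self, toy_locus):
        lib = SmallRNALibrary(id="empty")
        lib.tallies = {"locus_matched": 0}
        with pytest.raises(ValueError, match="empty"):
            normalize_libraries([lib], mode="rpm")

    def test_size_distribution_mass_and_rpm_identity(self, toy_locus):
        lib = self._lib_with("a", toy_locus, n_22=0, n_24=500)
        dist = size_distribution(lib)
        assert dist.loc[dist["length"] == 24, "raw"].iloc[0] == 500
        assert dist["raw"].sum() == 500
        assert dist["rpm"].sum() == pytest.approx(1e6)


class TestCoverageAndBins:
    @pytest.fixture()
    def toy_locus(self):
        rng = np.random.default_rng(31)
        return ReferenceLocus(
            id="toy", sequence="".join(rng.choice(list("ACGT"), size=600)), tss_array_pos=101
        )

    def test_single_read_span_rule(self, toy_locus):
        start_array = toy_locus.from_tss(100)  # tss +100 -> array 200
        read = toy_locus.sequence[start_array - 1 : start_array - 1 + 24]
        lib = make_aligned_library("a", toy_locus, {read: 1})
        track = position_coverage(lib, toy_locus, size_class=24, strand="+", factor=1.0)
        assert track[start_array - 1 : start_array + 23].tolist() == [1.0] * 24
        assert track.sum() == pytest.approx(24.0)
        minus = position_coverage(lib, toy_locus, size_class=24, strand="-", factor=1.0)
        assert minus.sum() == 0.0

    def test_overlapping_reads_add(self, toy_locus):
        r1 = toy_locus.sequence[100:124]
        r2 = toy_locus.sequence[110:134]
        lib = make_aligned_library("a", toy_locus, {r1: 2, r2: 3})
        track = position_coverage(lib, toy_locus, size_class=24, factor=1.0)
        assert track[115] == pytest.approx(5.0)

    def test_track_mass_conservation(self, toy_locus):
        rng = np.random.default_rng(7)
        inserts = {}
        for _ in range(30):
            start = int(rng.integers(0, 570))
            length = int(rng.integers(20, 27))
            inserts[toy_locus.sequence[start : start + length]] = int(rng.integers(1, 9))
        lib = make_aligned_library("a", toy_locus, inserts)
        track = position_coverage(lib, toy_locus, factor=2.5)
        expected = sum(
            lib.retained[s] * 2.5 * len(s) * len(hits) for s, hits in lib.hits.items()
        )
        assert track.sum() == pytest.approx(expected)

    def test_hit_on_edge_falls_in_right_hand_bin(self, toy_locus):
        # default anchor tiles from array position 1 (label -100), so label +50
        # (array 150) is a bin edge; a hit starting exactly there joins the
        # right-hand bin [50, 100)
        read = toy_locus.sequence[149:173]
        lib = make_aligned_library("a", toy_locus, {read: 1})
        bins = bin_table([lib], toy_locus, {"a": 1.0}, width=50)
        row = bins.loc[bins["a|24|both"] > 0].iloc[0]
        assert toy_locus.to_tss(150) == 50
        assert (row["tss_start"], row["tss_end"]) == (50, 100)

    def test_bin_sums_equal_total_hits(self, toy_locus):
        rng = np.random.default_rng(13)
        inserts = {}
        for _ in range(40):
            start = int(rng.integers(0, 575))
            inserts[toy_locus.sequence[start : start + 24]] = int(rng.integers(1, 5))
        lib = make_aligned_library("a", toy_locus, inserts)
        bins = bin_table([lib], toy_locus, {"a": 1.0}, width=50)
        total_hits = sum(
            lib.retained[s] * len(h) for s, h in lib.hits.items() if len(s) == 24
        )
        assert bins["a|24|both"].sum() == pytest.approx(total_hits)

    def test_printed_grid_with_nonzero_anchor(self):
        # with a 50-bp grid anchored at label 24, the upstream row boundaries
        # land on values like (-1726, -1676), the style locus tables print
        rng = np.random.default_rng(41)
        locus = ReferenceLocus(
            id="big", sequence="".join(rng.choice(list("ACGT"), size=4000)), tss_array_pos=2000
        )
        start_array = locus.from_tss(-1700)
        read = locus.sequence[start_array - 1 : start_array + 23]
        lib = make_aligned_library("a", locus, {read: 10})
        bins = bin_table([lib], locus, {"a": 1.0}, width=50, anchor=24)
        row = bins.loc[bins["a|24|both"] > 0].iloc[0]
        assert (row["tss_start"], row["tss_end"]) == (-1726, -1676)


class TestCallLostRegions:
    @staticmethod
    def _table(abundances):
        n = len(abundances)
        return pd.DataFrame(
            {
                "bin_index": range(n),
                "tss_start": [24 + 50 * i for i in range(n)],
                "tss_end": [24 + 50 * (i + 1) for i in range(n)],
                "abundance": abundances,
            }
        )

    def test_strong_loss_is_flagged_with_ratio(self):
        wt = self._table([0, 83, 0])
        mut = self._table([0, 7, 0])
        regions = call_lost_regions(wt, mut)
        assert len(regions) == 1
        assert regions["ratio"].iloc[0] == pytest.approx(7 / 83)

    def test_near_complete_loss_flagged(self):
        regions = call_lost_regions(self._table([233]), self._table([6]))
        assert len(regions) == 1

    def test_low_wildtype_bin_not_flagged(self):
        regions = call_lost_regions(self._table([4]), self._table([0]))
        assert len(regions) == 0

    def test_ratio_above_ceiling_not_flagged(self):
        regions = call_lost_regions(self._table([100]), self._table([30]))
        assert len(regions) == 0

    def test_adjacent_flagged_bins_merge(self):
        wt = self._table([50, 60, 0, 70])
        mut = self._table([0, 0, 0, 0])
        regions = call_lost_regions(wt, mut)
        assert len(regions) == 2
        assert regions["wt_abundance"].iloc[0] == pytest.approx(110.0)

    def test_mismatched_grids_rejected(self):
        wt = self._table([1, 2, 3])
        mut = self._table([1, 2, 3])
        mut["tss_start"] += 50
        with pytest.raises(ValueError, match="grid"):
            call_lost_regions(wt, mut)
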