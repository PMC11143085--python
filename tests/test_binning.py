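"""Bin construction, counting, quantile masking, GC correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarcall.binning import (
    BinnedCounts,
    count_reads,
    from_tsv,
    gc_correct,
    make_fixed_bins,
    make_variable_bins,
    quantile_mask,
    reference_normalize,
)
from polarcall.errors import AnalysisError, InputError
from polarcall.genome import GenomeLayout
from polarcall.reads import ReadSet

from conftest import make_reads


class TestFixedBins:
    def test_exact_division(self):
        layout = GenomeLayout(["c"], {"c": 1_000_000})
        bins = make_fixed_bins(layout, 100_000)
        assert len(bins) == 10
        assert bins.start[0] == 0 and bins.end[0] == 100_000
        assert bins.start[-1] == 900_000 and bins.end[-1] == 1_000_000

    def test_truncated_last_bin(self):
        layout = GenomeLayout(["c"], {"c": 1_050_000})
        bins = make_fixed_bins(layout, 100_000)
        assert len(bins) == 11
        assert (bins.start[-1], bins.end[-1]) == (1_000_000, 1_050_000)

    @pytest.mark.parametrize("width", [0, -5])
    def test_nonpositive_width_errors(self, width):
        layout = GenomeLayout(["c"], {"c": 1_000_000})
        with pytest.raises(InputError):
            make_fixed_bins(layout, width)

    def test_width_above_shortest_chromosome_errors(self, two_chrom_layout):
        with pytest.raises(InputError):
            make_fixed_bins(two_chrom_layout, 6_000_000)


class TestCountReads:
    def test_half_open_boundaries(self, two_chrom_layout):
        rs = make_reads(two_chrom_layout, ["toyA"] * 3, [0, 99_999, 100_000])
        counts = count_reads(rs, make_fixed_bins(two_chrom_layout, 100_000))
        assert counts.raw[0] == 2
        assert counts.raw[1] == 1
        assert counts.raw.sum() == 3

    def test_empty_readset_gives_zero_counts(self, two_chrom_layout):
        rs = ReadSet(
            two_chrom_layout,
            np.array([], dtype=np.int32),
            np.array([], dtype=np.int64),
            np.array([], dtype=np.int32),
        )
        counts = count_reads(rs, make_fixed_bins(two_chrom_layout, 100_000))
        assert counts.raw.sum() == 0

    def test_uniform_reads_pass_chi2(self, two_chrom_layout):
        from scipy.stats import chisquare

        rng = np.random.default_rng(11)
        rs = make_reads(
            two_chrom_layout, ["toyA"] * 10_000, rng.integers(0, 10_000_000, 10_000)
        )
        bins = make_fixed_bins(two_chrom_layout, 100_000)
        sl = bins.chromosome_slice("toyA")
        raw = count_reads(rs, bins).raw[sl]
        assert raw.mean() == pytest.approx(100, rel=0.05)
        assert chisquare(raw).pvalue > 0.001

    def test_count_conservation_under_masking(self, two_chrom_layout):
        rng = np.random.default_rng(5)
        rs = make_reads(
            two_chrom_layout, ["toyA"] * 2_000, rng.integers(0, 10_000_000, 2_000)
        )
        counts = count_reads(rs, make_fixed_bins(two_chrom_layout, 100_000))
        masked = quantile_mask(counts)
        assert masked.raw.sum() == counts.raw.sum() == 2_000


class TestQuantileMask:
    def test_degenerate_distribution_masks_nothing(self, two_chrom_layout):
        bins = make_fixed_bins(two_chrom_layout, 1_000_000)
        counts = BinnedCounts(
            bins,
            np.full(len(bins), 7),
            np.full(len(bins), 7.0),
            np.zeros(len(bins), bool),
            np.full(len(bins), np.nan),
        )
        assert not quantile_mask(counts).masked.any()

    @given(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=20, max_size=200)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_quantiles(self, raw_list):
        layout = GenomeLayout(["c"], {"c": len(raw_list) * 1000})
        bins = make_fixed_bins(layout, 1000)
        raw = np.array(raw_list)
        counts = BinnedCounts(
            bins, raw, raw.astype(float), np.zeros(len(raw), bool),
            np.full(len(raw), np.nan),
        )
        masked = quantile_mask(counts, hi=0.9985, lo=0.1).masked
        # independent oracle: sort-based type-7 quantiles
        srt = np.sort(raw)
        def q(p):
            h = (len(srt) - 1) * p
            lo_i, frac = int(np.floor(h)), h - int(np.floor(h))
            hi_i = min(lo_i + 1, len(srt) - 1)
            return srt[lo_i] + frac * (srt[hi_i] - srt[lo_i])
        expected = (raw > q(0.9985)) | (raw < q(0.1))
        np.testing.assert_array_equal(masked, expected)

    def test_inverted_quantiles_error(self, two_chrom_layout):
        bins = make_fixed_bins(two_chrom_layout, 1_000_000)
        counts = BinnedCounts(
            bins,
            np.arange(len(bins)),
            np.arange(len(bins), dtype=float),
            np.zeros(len(bins), bool),
            np.full(len(bins), np.nan),
        )
        with pytest.raises(InputError):
            quantile_mask(counts, hi=0.5, lo=0.6)


class TestVariableBins:
    def test_uniform_reference_approximates_nominal_width(self, two_chrom_layout):
        rng = np.random.default_rng(2)
        depth = 3000  # reads per Mb
        n = depth * 15
        chroms = ["toyA"] * (depth * 10) + ["toyB"] * (depth * 5)
        pos = np.concatenate(
            [rng.integers(0, 10_000_000, depth * 10), rng.integers(0, 5_000_000, depth * 5)]
        )
        ref = make_reads(two_chrom_layout, chroms, pos)
        bins = make_variable_bins(ref, two_chrom_layout, 1_000_000)
        widths = bins.widths
        assert np.all(np.abs(widths - 1_000_000) <= 100_000)

    def test_coverage_gap_widens_spanning_bin(self, two_chrom_layout):
        rng = np.random.default_rng(3)
        # uniform coverage except a 2-Mb hole on toyA at [4,6) Mb
        pos_a = rng.integers(0, 10_000_000, 30_000)
        pos_a = pos_a[(pos_a < 4_000_000) | (pos_a >= 6_000_000)]
        pos_b = rng.integers(0, 5_000_000, 15_000)
        ref = make_reads(
            two_chrom_layout,
            ["toyA"] * len(pos_a) + ["toyB"] * len(pos_b),
            np.concatenate([pos_a, pos_b]),
        )
        bins = make_variable_bins(ref, two_chrom_layout, 1_000_000)
        sl = bins.chromosome_slice("toyA")
        spanning = (bins.start[sl] < 4_000_000) & (bins.end[sl] > 6_000_000)
        assert spanning.any()
        assert bins.widths[sl][spanning].max() > 2_000_000
        counts = count_reads(ref, bins).raw[sl]
        target = np.median(counts)
        assert counts[spanning][0] == pytest.approx(target, rel=0.35)

    def test_tiling_invariant(self, layout, reference_reads):
        bins = make_variable_bins(reference_reads, layout, 1_000_000)
        for chrom in layout.chromosomes:
            sl = bins.chromosome_slice(chrom)
            assert bins.start[sl][0] == 0
            assert bins.end[sl][-1] == layout.length(chrom)
            assert np.all(bins.start[sl][1:] == bins.end[sl][:-1])

    def test_empty_chromosome_errors(self, two_chrom_layout):
        ref = make_reads(two_chrom_layout, ["toyA"] * 5000,
                         np.random.default_rng(0).integers(0, 10_000_000, 5000))
        with pytest.raises(AnalysisError, match="toyB"):
            make_variable_bins(ref, two_chrom_layout, 1_000_000)


def _counts_with_gc(layout, gc, raw):
    bins = make_fixed_bins(layout, 100_000)
    assert len(bins) == len(gc)
    return BinnedCounts(bins, raw, raw.astype(float), np.zeros(len(raw), bool), gc)


class TestGCCorrect:
    def test_flat_gc_leaves_counts_unchanged(self, two_chrom_layout):
        rng = np.random.default_rng(4)
        raw = rng.poisson(100, 150)
        counts = _counts_with_gc(two_chrom_layout, np.full(150, 0.42), raw)
        corrected = gc_correct(counts).corrected
        np.testing.assert_allclose(corrected, raw, rtol=1e-9)

    def test_removes_injected_linear_bias(self, two_chrom_layout):
        rng = np.random.default_rng(8)
        gc = rng.uniform(0.3, 0.6, 150)
        base = rng.poisson(500, 150).astype(float)
        raw = np.round(base * (1 + 0.8 * (gc - 0.4))).astype(int)
        counts = _counts_with_gc(two_chrom_layout, gc, raw)
        out = gc_correct(counts)
        slope_before = np.polyfit(gc, raw, 1)[0]
        slope_after = np.polyfit(gc, out.corrected, 1)[0]
        assert abs(slope_after) < 0.1 * abs(slope_before)

    def test_mean_preserved(self, two_chrom_layout):
        rng = np.random.default_rng(9)
        gc = rng.uniform(0.3, 0.6, 150)
        raw = rng.poisson(200 * (1 + 0.5 * (gc - 0.45)))
        counts = _counts_with_gc(two_chrom_layout, gc, raw)
        out = gc_correct(counts)
        assert out.corrected.mean() == pytest.approx(raw.mean(), rel=1e-6)

    def test_too_few_bins_errors(self, two_chrom_layout):
        bins = make_fixed_bins(two_chrom_layout, 1_000_000)
        n = len(bins)
        counts = BinnedCounts(
            bins, np.full(n, 10), np.full(n, 10.0), np.zeros(n, bool),
            np.full(n, 0.4),
        )
        with pytest.raises(AnalysisError, match=">= 50"):
            gc_correct(counts)


def test_combine_masks_excludes_either_masked_bin(two_chrom_layout):
    from polarcall.binning import combine_masks

    bins = make_fixed_bins(two_chrom_layout, 1_000_000)
    n = len(bins)
    mk = lambda mask: BinnedCounts(
        bins, np.full(n, 5), np.full(n, 5.0), mask, np.full(n, np.nan)
    )
    a = np.zeros(n, bool); a[0] = True
    b = np.zeros(n, bool); b[1] = True
    combined = combine_masks(mk(a), mk(b))
    assert combined[0] and combined[1] and not combined[2:].any()


class TestReferenceNormalize:
    def test_equalises_exposure(self, two_chrom_layout):
        bins = make_fixed_bins(two_chrom_layout, 1_000_000)
        n = len(bins)
        ref_raw = np.full(n, 1000)
        ref_raw[0] = 2000  # doubled reference content in bin 0
        sample_raw = np.full(n, 300)
        sample_raw[0] = 600  # sample scales the same way
        make = lambda r: BinnedCounts(
            bins, r, r.astype(float), np.zeros(n, bool), np.full(n, np.nan)
        )
        out = reference_normalize(make(sample_raw), make(ref_raw))
        np.testing.assert_allclose(out.corrected, 300.0)

    def test_zero_reference_bin_masked(self, two_chrom_layout):
        bins = make_fixed_bins(two_chrom_layout, 1_000_000)
        n = len(bins)
        ref_raw = np.full(n, 1000)
        ref_raw[3] = 0
        sample_raw = np.full(n, 300)
        make = lambda r: BinnedCounts(
            bins, r, r.astype(float), np.zeros(n, bool), np.full(n, np.nan)
        )
        out = reference_normalize(make(sample_raw), make(ref_raw))
        assert out.masked[3]
        assert np.isnan(out.corrected[3])


def test_bin_tsv_roundtrip(tmp_path, two_chrom_layout):
    rng = np.random.default_rng(12)
    rs = make_reads(
        two_chrom_layout, ["toyA"] * 1000, rng.integers(0, 10_000_000, 1000)
    )
    counts = quantile_mask(count_reads(rs, make_fixed_bins(two_chrom_layout, 100_000)))
    path = tmp_path / "bins.tsv"
    counts.to_tsv(path)
    again = from_tsv(str(path), two_chrom_layout)
    np.testing.assert_array_equal(again.raw, counts.raw)
    np.testing.assert_array_equal(again.masked, counts.masked)
    np.testing.assert_array_equal(again.binset.start, counts.binset.start)
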