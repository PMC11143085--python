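"""Bin construction, read counting, quantile masking, and GC correction.

Two binning schemes are used, mirroring the low-pass single-cell CNV
workflow: fixed 100-kb bins for genome-wide quantile blacklisting, and
variable-width ~1-Mb bins whose boundaries are placed so that each bin holds
the same number of reads from a merged euploid reference — low-mappability
regions thereby become genomically wider bins with comparable expected
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .genome import GenomeLayout
from .reads import ReadSet


@dataclass
class BinSet:
    """Non-overlapping, sorted genomic bins (0-based half-open)."""

    layout: GenomeLayout
    chrom_idx: np.ndarray
    start: np.ndarray
    end: np.ndarray
    scheme: str = "fixed"
    nominal_width: int = 0

    def __post_init__(self) -> None:
        self.chrom_idx = np.asarray(self.chrom_idx, dtype=np.int32)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.end <= self.start):
            raise InputError("bins must have end > start")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    def chromosome_slice(self, chromosome: str) -> slice:
        """Contiguous index range of one chromosome's bins."""
        idx = self.layout.index(chromosome)
        where = np.flatnonzero(self.chrom_idx == idx)
        if where.size == 0:
            return slice(0, 0)
        return slice(int(where[0]), int(where[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        chroms = np.asarray(self.layout.chromosomes, dtype=object)
        return pd.DataFrame(
            {"chrom": chroms[self.chrom_idx], "start": self.start, "end": self.end}
        )


@dataclass
class BinnedCounts:
    """Per-bin raw and GC-corrected read counts with a mask flag.

    ``corrected`` is NaN on masked bins; ``gc`` is the length-weighted GC
    fraction of each bin (NaN when no GC track is available).
    """

    binset: BinSet
    raw: np.ndarray
    corrected: np.ndarray
    masked: np.ndarray
    gc: np.ndarray
    n_dropped_reads: int = 0

    def __post_init__(self) -> None:
        n = len(self.binset)
        self.raw = np.asarray(self.raw, dtype=np.int64)
        self.corrected = np.asarray(self.corrected, dtype=float)
        self.masked = np.asarray(self.masked, dtype=bool)
        self.gc = np.asarray(self.gc, dtype=float)
        for arr in (self.raw, self.corrected, self.masked, self.gc):
            if len(arr) != n:
                raise InputError("binned-count arrays must match the bin set")
        if np.any(self.raw < 0):
            raise InputError("negative raw counts")

    def __len__(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        df = self.binset.to_frame()
        df["raw"] = self.raw
        df["corrected"] = self.corrected
        df["masked"] = self.masked.astype(int)
        df["gc"] = self.gc
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def from_tsv(path: str, layout: GenomeLayout) -> BinnedCounts:
    """Round-trip loader for the BED-like bin TSV written by ``to_tsv``."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "raw", "corrected", "masked", "gc"}
    if not need.issubset(df.columns):
        raise InputError(f"bin TSV {path} lacks columns {sorted(need - set(df.columns))}")
    chrom_idx = df["chrom"].map({c: layout.index(c) for c in layout.chromosomes})
    if chrom_idx.isna().any():
        raise InputError(f"bin TSV {path} has chromosomes outside the layout")
    binset = BinSet(
        layout,
        chrom_idx.to_numpy(dtype=np.int32),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        scheme="loaded",
    )
    return BinnedCounts(
        binset,
        df["raw"].to_numpy(),
        df["corrected"].to_numpy(),
        df["masked"].to_numpy(dtype=bool),
        df["gc"].to_numpy(),
    )


def make_fixed_bins(layout: GenomeLayout, width: int = 100_000) -> BinSet:
    """Tile each chromosome with fixed-width bins; the last bin is truncated."""
    if width <= 0:
        raise InputError("bin width must be positive")
    shortest = min(layout.lengths[c] for c in layout.chromosomes)
    if width > shortest:
        raise InputError(
            f"bin width {width} exceeds shortest chromosome length {shortest}"
        )
    chrom_idx, starts, ends = [], [], []
    for i, chrom in enumerate(layout.chromosomes):
        length = layout.lengths[chrom]
        s = np.arange(0, length, width, dtype=np.int64)
        e = np.minimum(s + width, length)
        chrom_idx.append(np.full(len(s), i, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    return BinSet(
        layout,
        np.concatenate(chrom_idx),
        np.concatenate(starts),
        np.concatenate(ends),
        scheme="fixed",
        nominal_width=width,
    )


def bin_gc(layout: GenomeLayout, binset: BinSet) -> np.ndarray:
    """Length-weighted mean GC fraction per bin from the layout's GC windows.

    All-NaN overlaps (or a missing GC track) yield NaN for the bin.
    """
    out = np.full(len(binset), np.nan)
    if layout.gc_windows is None or layout.gc_window is None:
        return out
    w = layout.gc_window
    for chrom in layout.chromosomes:
        sl = binset.chromosome_slice(chrom)
        if sl.start == sl.stop:
            continue
        gc = layout.gc_windows[chrom]
        starts = binset.start[sl]
        ends = binset.end[sl]
        for k in range(len(starts)):
            w0 = int(starts[k] // w)
            w1 = int((ends[k] - 1) // w) + 1
            seg = gc[w0:w1]
            # overlap length of each window with the bin
            win_starts = np.arange(w0, w1, dtype=np.int64) * w
            win_ends = np.minimum(win_starts + w, layout.lengths[chrom])
            ov = np.minimum(win_ends, ends[k]) - np.maximum(win_starts, starts[k])
            good = np.isfinite(seg) & (ov > 0)
            if good.any():
                out[sl.start + k] = float(np.average(seg[good], weights=ov[good]))
    return out


def count_reads(reads: ReadSet, binset: BinSet) -> BinnedCounts:
    """Assign each read start to the unique bin containing it.

    Reads falling past the last bin end of their chromosome (possible only
    if the bin set does not tile it) are dropped and tallied.
    """
    if reads.layout.chromosomes != binset.layout.chromosomes:
        raise InputError("reads and bins use different layouts")
    raw = np.zeros(len(binset), dtype=np.int64)
    dropped = 0
    for chrom in binset.layout.chromosomes:
        sl = binset.chromosome_slice(chrom)
        pos = reads.positions(chrom)
        if sl.start == sl.stop:
            dropped += len(pos)
            continue
        starts = binset.start[sl]
        ends = binset.end[sl]
        lo = np.searchsorted(pos, starts[0])
        hi = np.searchsorted(pos, ends[-1])
        dropped += len(pos) - (hi - lo)
        inside = pos[lo:hi]
        which = np.searchsorted(starts, inside, side="right") - 1
        # guard against gaps between bins
        in_bin = inside < ends[which]
        dropped += int((~in_bin).sum())
        np.add.at(raw, sl.start + which[in_bin], 1)
    gc = bin_gc(binset.layout, binset)
    return BinnedCounts(
        binset,
        raw,
        raw.astype(float),
        np.zeros(len(binset), dtype=bool),
        gc,
        n_dropped_reads=dropped,
    )


def quantile_mask(counts: BinnedCounts, hi: float = 0.9985, lo: float = 0.1) -> BinnedCounts:
    """Mask bins strictly above the ``hi`` or strictly below the ``lo``
    empirical quantile (linear interpolation, type 7) of the genome-wide
    raw-count distribution.
    """
    if hi <= lo:
        raise InputError(f"hi quantile ({hi}) must exceed lo quantile ({lo})")
    if not (0 <= lo <= 1 and 0 <= hi <= 1):
        raise InputError("quantiles must lie in [0, 1]")
    q_lo, q_hi = np.quantile(counts.raw, [lo, hi])
    masked = counts.masked | (counts.raw > q_hi) | (counts.raw < q_lo)
    corrected = counts.corrected.copy()
    corrected[masked] = np.nan
    return replace(counts, masked=masked, corrected=corrected)


def combine_masks(sample: BinnedCounts, reference: BinnedCounts) -> np.ndarray:
    """Blacklist over a shared fixed bin set: a bin is excluded when masked
    in either the sample or the euploid reference (kept territory is the
    intersection of the two unmasked territories)."""
    if len(sample) != len(reference):
        raise InputError("sample and reference bin sets differ")
    return sample.masked | reference.masked


def filter_reads_to_unmasked(reads: ReadSet, counts: BinnedCounts) -> ReadSet:
    """Drop reads whose start falls in a masked bin of ``counts``'s bin set."""
    binset = counts.binset
    keep_parts = []
    for chrom in binset.layout.chromosomes:
        sl = binset.chromosome_slice(chrom)
        idx = binset.layout.index(chrom)
        sel = np.flatnonzero(reads.chrom_idx == idx)
        if sl.start == sl.stop or sel.size == 0:
            continue
        pos = reads.start[sel]
        which = np.searchsorted(binset.start[sl], pos, side="right") - 1
        ok = (which >= 0) & (pos < binset.end[sl][np.clip(which, 0, None)])
        ok &= ~counts.masked[sl][np.clip(which, 0, None)]
        keep_parts.append(sel[ok])
    if not keep_parts:
        raise AnalysisError("no reads remain outside the blacklist")
    keep = np.sort(np.concatenate(keep_parts))
    prov = dict(reads.provenance)
    prov["n_blacklisted"] = len(reads) - len(keep)
    return ReadSet(
        reads.layout,
        reads.chrom_idx[keep],
        reads.start[keep],
        reads.mapq[keep],
        provenance=prov,
        seed=reads.seed,
    )


def make_variable_bins(
    reference: ReadSet, layout: GenomeLayout, nominal_width: int = 1_000_000
) -> BinSet:
    """Variable-width bins holding equal numbers of reference reads.

    The per-bin read target T is the median reference count in fixed
    ``nominal_width`` bins. Boundaries are placed at midpoints between the
    flanking reference read positions; a terminal bin holding fewer than T/2
    reference reads is merged into its neighbour. Bins tile each chromosome
    exactly.
    """
    if nominal_width <= 0:
        raise InputError("nominal width must be positive")
    fixed = make_fixed_bins(layout, nominal_width)
    ref_counts = count_reads(reference, fixed)
    target = int(np.median(ref_counts.raw))
    if target < 1:
        raise AnalysisError("reference coverage too sparse for variable binning")
    chrom_idx, starts, ends = [], [], []
    for i, chrom in enumerate(layout.chromosomes):
        pos = reference.positions(chrom)
        if pos.size == 0:
            raise AnalysisError(f"reference has zero reads on chromosome {chrom}")
        length = layout.lengths[chrom]
        cuts = [0]
        k = target
        while k < pos.size:
            mid = int((pos[k - 1] + pos[k]) // 2) + 1
            if cuts[-1] < mid < length:
                cuts.append(mid)
            k += target
        # merge an under-filled terminal bin into its neighbour
        if len(cuts) > 1 and pos.size - (len(cuts) - 1) * target < target / 2:
            cuts.pop()
        cuts.append(length)
        s = np.asarray(cuts[:-1], dtype=np.int64)
        e = np.asarray(cuts[1:], dtype=np.int64)
        chrom_idx.append(np.full(len(s), i, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    return BinSet(
        layout,
        np.concatenate(chrom_idx),
        np.concatenate(starts),
        np.concatenate(ends),
        scheme="variable",
        nominal_width=nominal_width,
    )


def reference_normalize(
    sample: BinnedCounts, reference: BinnedCounts
) -> BinnedCounts:
    """Mappability normalisation: scale each bin's corrected count by the
    median reference bin count over that bin's reference count.

    Variable bins hold approximately — not exactly — equal reference read
    numbers (terminal bins are truncated or merged), so the per-bin
    reference content is the correct per-bin exposure; after this step the
    expected corrected count is uniform across bins for a flat karyotype.
    Bins with zero reference reads are masked.
    """
    if len(sample) != len(reference):
        raise InputError("sample and reference counts use different bin sets")
    ref = reference.raw.astype(float)
    target = np.median(ref[~sample.masked]) if (~sample.masked).any() else np.median(ref)
    if target <= 0:
        raise AnalysisError("reference has no coverage in unmasked bins")
    masked = sample.masked | (ref <= 0)
    corrected = np.where(ref > 0, sample.corrected * target / np.maximum(ref, 1e-12), np.nan)
    corrected[masked] = np.nan
    return replace(sample, corrected=corrected, masked=masked)


def gc_correct(counts: BinnedCounts, min_bins: int = 50) -> BinnedCounts:
    """Remove GC bias with a 2nd-degree polynomial fit of count on GC.

    ``corrected[b] = count[b] * mean(fitted) / fitted(gc[b])`` over unmasked
    bins with a finite GC fraction, rescaled so the unmasked mean is
    preserved. The input signal is the current ``corrected`` vector (equal
    to the raw counts unless a prior normalisation step modified it).
    Non-positive fitted values are clamped to the 1st percentile of the
    fitted curve (with a warning).
    """
    usable = ~counts.masked & np.isfinite(counts.gc) & np.isfinite(counts.corrected)
    if int(usable.sum()) < min_bins:
        raise AnalysisError(
            f"GC correction needs >= {min_bins} unmasked bins with GC, "
            f"got {int(usable.sum())}"
        )
    gc = counts.gc[usable]
    raw = counts.corrected[usable].astype(float)
    with warnings.catch_warnings():
        # a flat GC covariate makes the quadratic fit rank-deficient, which
        # is fine: the fitted curve is constant and correction is a no-op
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coef = np.polyfit(gc, raw, deg=2)
    fitted = np.polyval(coef, gc)
    floor = np.percentile(fitted, 1)
    if np.any(fitted <= 0):
        warnings.warn(
            "GC fit non-positive for some bins; clamping divisor", stacklevel=2
        )
        fitted = np.maximum(fitted, max(floor, 1e-9))
    corrected_vals = raw * fitted.mean() / fitted
    # enforce exact mean preservation
    corrected_vals *= raw.mean() / corrected_vals.mean()
    corrected = np.full(len(counts), np.nan)
    corrected[usable] = corrected_vals
    # unmasked bins without GC keep their incoming value
    no_gc = ~counts.masked & ~np.isfinite(counts.gc) & np.isfinite(counts.corrected)
    corrected[no_gc] = counts.corrected[no_gc]
    return replace(counts, corrected=corrected)
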