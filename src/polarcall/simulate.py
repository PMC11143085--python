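"""Seeded generators for karyotypes, WGA-like read sets, and aCGH profiles.

The generators emulate the data regime of rapid nanopore PGT-A on pooled
polar bodies: roughly one million reads of low-pass single-cell coverage
per sample, with the coverage noise characteristic of whole-genome
amplification (a per-window lognormal amplification factor plus
over-dispersion and occasional dropout), a smooth GC bias, and matched
aCGH probe profiles whose noise is calibrated to a target DLR spread.
Every simulated event is recorded in an exact ground-truth table.

Two layouts are provided: ``toy_layout`` scales the 23 GRCh38 chromosomes
1:30 (~103 Mb total) so million-read regimes run in seconds, and
``grch38_layout`` uses full chromosome lengths for physically sized events
(e.g. a 50-Mb segmental gain). Both carry a deterministic synthetic GC
landscape, since no reference FASTA ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import BASELINE_SOMY
from .errors import InputError
from .genome import GRCH38_LENGTHS, GenomeLayout
from .reads import ReadSet

MAX_SOMY = 4


def _synthetic_gc(n_windows: int, chrom_rank: int) -> np.ndarray:
    """Smooth, deterministic GC landscape in the human 0.33–0.55 range.

    Two incommensurate sinusoids plus a seeded wiggle give isochore-like
    structure that differs between chromosomes but is identical across runs.
    """
    t = np.arange(n_windows, dtype=float)
    base = (
        0.44
        + 0.06 * np.sin(2 * np.pi * (t / 47.0 + 0.37 * chrom_rank))
        + 0.04 * np.sin(2 * np.pi * (t / 11.0 + 0.11 * chrom_rank))
    )
    rng = np.random.default_rng(10_000 + chrom_rank)
    wiggle = rng.normal(0.0, 0.015, size=n_windows)
    # light smoothing keeps the wiggle spatially coherent
    kernel = np.ones(5) / 5.0
    wiggle = np.convolve(wiggle, kernel, mode="same")
    return np.clip(base + wiggle, 0.30, 0.60)


def _layout_with_gc(lengths: dict[str, int], gc_window: int) -> GenomeLayout:
    names = list(lengths)
    gc = {
        name: _synthetic_gc(-(-lengths[name] // gc_window), rank)
        for rank, name in enumerate(names)
    }
    return GenomeLayout(names, dict(lengths), gc_window=gc_window, gc_windows=gc)


def toy_layout(scale: int = 30, gc_window: int = 20_000) -> GenomeLayout:
    """23-chromosome layout with GRCh38 lengths scaled ``1:scale``."""
    lengths = {
        name: max(int(round(length / scale / 10_000)) * 10_000, 20 * gc_window)
        for name, length in GRCH38_LENGTHS.items()
    }
    return _layout_with_gc(lengths, gc_window)


def grch38_layout(gc_window: int = 100_000) -> GenomeLayout:
    """Full GRCh38 chromosome lengths with the synthetic GC landscape."""
    return _layout_with_gc(dict(GRCH38_LENGTHS), gc_window)


@dataclass
class SegmentalEvent:
    chromosome: str
    start: int
    end: int
    delta: int  # chromatid delta relative to the whole-chromosome count

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("event end must exceed start")


@dataclass
class KaryotypeSpec:
    """Chromatid counts per chromosome (baseline 3 for pooled polar bodies)
    plus optional segmental events."""

    baseline: int = BASELINE_SOMY
    chromatids: dict = field(default_factory=dict)  # chromosome -> count 0..4
    events: list = field(default_factory=list)

    def count(self, chromosome: str) -> int:
        return int(self.chromatids.get(chromosome, self.baseline))

    def validate(self, layout: GenomeLayout) -> None:
        for chrom, n in self.chromatids.items():
            if chrom not in layout:
                raise InputError(f"karyotype names unknown chromosome {chrom}")
            if not 0 <= int(n) <= MAX_SOMY:
                raise InputError(f"chromatid count {n} on {chrom} outside 0..{MAX_SOMY}")
        for ev in self.events:
            if ev.chromosome not in layout:
                raise InputError(f"event on unknown chromosome {ev.chromosome}")
            if ev.end > layout.length(ev.chromosome):
                raise InputError(f"event on {ev.chromosome} exceeds chromosome end")
            local = self.count(ev.chromosome) + ev.delta
            if not 0 <= local <= MAX_SOMY:
                raise InputError(
                    f"event on {ev.chromosome} drives copy number to {local}"
                )

    def window_copies(self, layout: GenomeLayout, chromosome: str, window: int) -> np.ndarray:
        """Per-window chromatid copy number including segmental events."""
        n_windows = -(-layout.length(chromosome) // window)
        copies = np.full(n_windows, self.count(chromosome), dtype=float)
        for ev in self.events:
            if ev.chromosome != chromosome:
                continue
            w0, w1 = ev.start // window, -(-ev.end // window)
            copies[w0:w1] += ev.delta
        return np.clip(copies, 0, MAX_SOMY)

    def truth_classes(self, layout: GenomeLayout) -> dict:
        """Whole-chromosome ground-truth classification by modal-bp copy
        number, using the same tie rules as the caller."""
        out = {}
        for chrom in layout.chromosomes:
            window = layout.gc_window or 100_000
            copies = self.window_copies(layout, chrom, window)
            vals, counts = np.unique(copies, return_counts=True)
            modal = vals[
                np.lexsort((vals, np.abs(vals - self.baseline), -counts))[0]
            ]
            if modal == self.baseline:
                out[chrom] = "euploid"
            else:
                out[chrom] = "gain" if modal > self.baseline else "loss"
        return out

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "chromatids": {k: int(v) for k, v in self.chromatids.items()},
            "events": [
                {
                    "chromosome": e.chromosome,
                    "start": e.start,
                    "end": e.end,
                    "delta": e.delta,
                }
                for e in self.events
            ],
        }


@dataclass
class NoiseModel:
    """WGA-like coverage noise.

    ``gc_slope`` is the multiplicative bias per unit GC deviation from the
    genome mean; ``wga_sigma`` the SD of the per-window lognormal
    amplification factor (the bin-scale unevenness WGA is notorious for);
    ``zero_inflation_p`` the probability a window drops out entirely; and
    ``nb_dispersion`` the target variance/mean ratio of window counts.
    """

    gc_slope: float = 0.8
    wga_sigma: float = 0.25
    zero_inflation_p: float = 0.01
    nb_dispersion: float = 2.0

    def __post_init__(self) -> None:
        if min(self.gc_slope, self.wga_sigma, self.nb_dispersion) < 0:
            raise InputError("noise parameters must be non-negative")
        if not 0 <= self.zero_inflation_p < 1:
            raise InputError("zero_inflation_p must lie in [0, 1)")


NOISELESS = NoiseModel(gc_slope=0.0, wga_sigma=0.0, zero_inflation_p=0.0, nb_dispersion=1.0)


def simulate_reads(
    spec: KaryotypeSpec,
    layout: GenomeLayout,
    n_reads: int,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[ReadSet, dict]:
    """Draw read start positions proportional to local copy number, GC bias,
    and a per-window lognormal WGA factor; zero-inflated windows emit
    nothing. Returns the read set plus an exact ground-truth record.
    """
    if n_reads <= 0:
        raise InputError("n_reads must be positive")
    noise = noise if noise is not None else NoiseModel()
    spec.validate(layout)
    window = layout.gc_window or 100_000
    rng = np.random.default_rng(seed)
    weights, chrom_of_window, window_start, window_len = [], [], [], []
    mean_gc_parts = []
    for chrom in layout.chromosomes:
        gc = (
            layout.gc_windows[chrom]
            if layout.gc_windows is not None
            else np.full(-(-layout.length(chrom) // window), 0.44)
        )
        mean_gc_parts.append(np.nan_to_num(gc, nan=0.44))
    mean_gc = float(np.mean(np.concatenate(mean_gc_parts)))
    for ci, chrom in enumerate(layout.chromosomes):
        copies = spec.window_copies(layout, chrom, window)
        gc = mean_gc_parts[ci]
        w = copies * np.maximum(1.0 + noise.gc_slope * (gc - mean_gc), 0.0)
        if noise.wga_sigma > 0:
            w = w * rng.lognormal(0.0, noise.wga_sigma, size=len(w))
        if noise.nb_dispersion > 1.0:
            # gamma factor tuned so window counts hit the target var/mean
            m_bar = max(n_reads / max(sum(len(p) for p in mean_gc_parts), 1), 1e-9)
            shape = m_bar / (noise.nb_dispersion - 1.0)
            w = w * rng.gamma(shape, 1.0 / shape, size=len(w))
        if noise.zero_inflation_p > 0:
            w = w * (rng.random(len(w)) >= noise.zero_inflation_p)
        n_w = len(w)
        starts = np.arange(n_w, dtype=np.int64) * window
        lens = np.minimum(starts + window, layout.length(chrom)) - starts
        weights.append(w * lens / window)  # short terminal windows weigh less
        chrom_of_window.append(np.full(n_w, ci, dtype=np.int32))
        window_start.append(starts)
        window_len.append(lens)
    w_all = np.concatenate(weights)
    if w_all.sum() <= 0:
        raise InputError("all-zero copy genome; nothing to simulate")
    p = w_all / w_all.sum()
    counts = rng.multinomial(n_reads, p)
    chrom_all = np.concatenate(chrom_of_window)
    start_all = np.concatenate(window_start)
    len_all = np.concatenate(window_len)
    nz = np.flatnonzero(counts)
    chrom_idx = np.repeat(chrom_all[nz], counts[nz])
    offsets = rng.random(n_reads) * np.repeat(len_all[nz], counts[nz])
    positions = np.repeat(start_all[nz], counts[nz]) + offsets.astype(np.int64)
    mapq = np.full(n_reads, 60, dtype=np.int32)
    reads = ReadSet(
        layout,
        chrom_idx,
        positions,
        mapq,
        provenance={"source": "simulate_reads", "seed": seed, "n_reads": n_reads},
        seed=seed,
    )
    reads.sort()
    truth = {
        "karyotype": spec.to_dict(),
        "chromosome_classes": spec.truth_classes(layout),
        "events": spec.to_dict()["events"],
        "seed": seed,
    }
    return reads, truth


def simulate_acgh(
    spec: KaryotypeSpec,
    n_probes: int,
    target_dlrs: float,
    seed: int = 0,
    layout: GenomeLayout | None = None,
    sample_id: str = "",
) -> "ACGHProfile":
    """aCGH probe profile: log2(copies/baseline) per probe plus Normal noise
    with SD ``target_dlrs`` (the DLRS of iid probe noise equals its SD).

    The male-control X channel sits one log2 unit above the female channel,
    reflecting the single X of an XY control hybridisation.
    """
    import pandas as pd

    from .acgh import ACGHProfile

    layout = layout if layout is not None else toy_layout()
    if n_probes < len(layout.chromosomes):
        raise InputError("need at least one probe per chromosome")
    if target_dlrs < 0:
        raise InputError("target DLRS must be non-negative")
    spec.validate(layout)
    rng = np.random.default_rng(seed)
    total = layout.total_length
    rows = []
    for chrom in layout.chromosomes:
        length = layout.length(chrom)
        k = max(int(round(n_probes * length / total)), 2)
        positions = np.linspace(0, length - 1, k).astype(np.int64)
        window = layout.gc_window or 100_000
        copies = spec.window_copies(layout, chrom, window)[positions // window]
        copies = np.maximum(copies, 0.25)  # a nullisomy still hybridises faintly
        expected = np.log2(copies / spec.baseline)
        noise_f = rng.normal(0.0, target_dlrs, size=k) if target_dlrs > 0 else 0.0
        noise_m = rng.normal(0.0, target_dlrs, size=k) if target_dlrs > 0 else 0.0
        is_x = chrom.removeprefix("chr") == "X"
        male_offset = 1.0 if is_x else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": positions,
                    "log2_vs_male": expected + male_offset + noise_m,
                    "log2_vs_female": expected + noise_f,
                }
            )
        )
    return ACGHProfile(pd.concat(rows, ignore_index=True), sample_id=sample_id)


#: chromosomes with the highest aneuploidy rates in polar-body cohorts
ENRICHED_CHROMOSOMES = ("chr15", "chr16", "chr19", "chr21", "chr22")


def default_aneuploidy_probs(
    layout: GenomeLayout,
    base_gain: float = 0.01,
    base_loss: float = 0.02,
    enriched_gain: float = 0.05,
    enriched_loss: float = 0.08,
) -> dict:
    """Per-chromosome gain/loss probabilities, enriched for the chromosomes
    most often aneuploid in oocytes (15, 16, 19, 21, 22), with losses more
    frequent than gains."""
    probs = {}
    for chrom in layout.chromosomes:
        if chrom in ENRICHED_CHROMOSOMES:
            probs[chrom] = (enriched_gain, enriched_loss)
        else:
            probs[chrom] = (base_gain, base_loss)
    return probs


def draw_karyotype(
    rng: np.random.Generator, aneuploidy_probs: dict, layout: GenomeLayout
) -> KaryotypeSpec:
    """One random karyotype: per chromosome a gain (4 chromatids) with
    probability p_gain, else a loss (2) with probability p_loss, else 3."""
    chromatids = {}
    for chrom in layout.chromosomes:
        pg, pl = aneuploidy_probs.get(chrom, (0.0, 0.0))
        u = rng.random()
        if u < pg:
            chromatids[chrom] = MAX_SOMY
        elif u < pg + pl:
            chromatids[chrom] = BASELINE_SOMY - 1
    return KaryotypeSpec(chromatids=chromatids)


def simulate_cohort(
    n_samples: int,
    aneuploidy_probs: dict | None = None,
    seed: int = 0,
    layout: GenomeLayout | None = None,
    n_reads: int = 1_000_000,
    noise: NoiseModel | None = None,
    n_probes: int = 20_000,
    target_dlrs: float = 0.57,
) -> list[dict]:
    """Paired read sets and aCGH profiles with an exact truth table.

    Each sample draws an independent karyotype: per chromosome, a gain
    (4 chromatids) with probability p_gain, else a loss (2 chromatids) with
    probability p_loss, else the euploid 3.
    """
    layout = layout if layout is not None else toy_layout()
    if aneuploidy_probs is None:
        aneuploidy_probs = default_aneuploidy_probs(layout)
    for chrom, (pg, pl) in aneuploidy_probs.items():
        if not (0 <= pg <= 1 and 0 <= pl <= 1 and pg + pl <= 1):
            raise InputError(f"invalid gain/loss probabilities for {chrom}")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_samples):
        spec = draw_karyotype(rng, aneuploidy_probs, layout)
        read_seed = int(rng.integers(0, 2**31 - 1))
        acgh_seed = int(rng.integers(0, 2**31 - 1))
        reads, truth = simulate_reads(spec, layout, n_reads, noise, seed=read_seed)
        profile = simulate_acgh(
            spec, n_probes, target_dlrs, seed=acgh_seed, layout=layout,
            sample_id=f"SIM{i:03d}",
        )
        cohort.append(
            {
                "sample_id": f"SIM{i:03d}",
                "reads": reads,
                "acgh": profile,
                "truth": truth,
            }
        )
    return cohort
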