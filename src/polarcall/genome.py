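"""Genome layout: chromosome set, lengths, and per-window GC fractions.

The analysis set for pooled polar bodies is the 22 autosomes plus X
(23 chromosomes); Y is excluded because polar bodies are maternal material.
Layouts can be loaded from a FASTA (GC computed per window) or from a
two-column length table, and toy layouts for simulation are built in
:mod:`polarcall.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: GRCh38 primary-assembly chromosome lengths for the analysis set.
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
}

CANONICAL_CHROMOSOMES: tuple[str, ...] = tuple(GRCH38_LENGTHS)

_Y_NAMES = {"chrY", "Y"}


@dataclass
class GenomeLayout:
    """Ordered chromosome names, lengths, and optional per-window GC track.

    Parameters
    ----------
    chromosomes
        Ordered chromosome names; must be unique.
    lengths
        Chromosome length in bp; strictly positive.
    gc_window
        Window size in bp of the GC track, if present.
    gc_windows
        Per-chromosome arrays of GC fraction per window (NaN where the
        window is all N).
    """

    chromosomes: list[str]
    lengths: dict[str, int]
    gc_window: int | None = None
    gc_windows: dict[str, np.ndarray] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise InputError("duplicate chromosome names in layout")
        if not self.chromosomes:
            raise InputError("layout has no chromosomes")
        for name in self.chromosomes:
            if name not in self.lengths:
                raise InputError(f"no length for chromosome {name}")
            if self.lengths[name] <= 0:
                raise InputError(f"non-positive length for chromosome {name}")
        if self.gc_windows is not None:
            for name, gc in self.gc_windows.items():
                finite = gc[np.isfinite(gc)]
                if finite.size and (finite.min() < 0 or finite.max() > 1):
                    raise InputError(f"GC fractions outside [0,1] on {name}")
        self._index = {name: i for i, name in enumerate(self.chromosomes)}

    def index(self, chromosome: str) -> int:
        try:
            return self._index[chromosome]
        except KeyError:
            raise InputError(f"chromosome {chromosome} not in layout") from None

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self._index

    @property
    def total_length(self) -> int:
        return sum(self.lengths[c] for c in self.chromosomes)

    def length(self, chromosome: str) -> int:
        return self.lengths[chromosome]


def gc_fraction(sequence: str) -> float:
    """GC fraction of a sequence, N bases excluded from the denominator.

    Returns NaN for an all-N (or empty) sequence.
    """
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    return gc / denom if denom else float("nan")


def _restrict_names(names: list[str]) -> list[str]:
    """Apply the analysis-set rule to a list of source chromosome names.

    If any canonical human name is present the full 23-chromosome set is
    required; otherwise (toy genomes) names are kept as given. Y is always
    dropped.
    """
    kept = [n for n in names if n not in _Y_NAMES]
    if not kept:
        raise InputError("source contains no usable chromosomes")
    if any(n in GRCH38_LENGTHS for n in kept):
        missing = [c for c in CANONICAL_CHROMOSOMES if c not in kept]
        if missing:
            label = ", ".join(m.removeprefix("chr") for m in missing)
            raise InputError(f"chromosome {label} absent from source")
        return [c for c in CANONICAL_CHROMOSOMES]
    return kept


def load_genome_layout(source: str, gc_window: int | None = None) -> GenomeLayout:
    """Load a :class:`GenomeLayout` from a FASTA or a length-table TSV.

    FASTA sources (``.fa``/``.fasta``/``.fa.gz`` etc.) yield a GC track with
    ``gc_window``-bp windows; a two-column TSV (``chrom<TAB>length``, header
    optional) yields lengths only.
    """
    lower = str(source).lower()
    if any(lower.endswith(ext) for ext in (".fa", ".fasta", ".fna", ".fa.gz", ".fasta.gz")):
        return _layout_from_fasta(source, gc_window)
    return _layout_from_table(source)


def _layout_from_fasta(path: str, gc_window: int | None) -> GenomeLayout:
    from pyfaidx import Fasta

    if gc_window is not None and gc_window <= 0:
        raise InputError("gc_window must be positive")
    try:
        fasta = Fasta(str(path))
    except Exception as exc:  # pyfaidx raises several types
        raise InputError(f"cannot read FASTA {path}: {exc}") from exc
    names = list(fasta.keys())
    if not names:
        raise InputError(f"empty FASTA {path}")
    kept = _restrict_names(names)
    lengths = {n: len(fasta[n]) for n in kept}
    gc_windows = None
    if gc_window is not None:
        gc_windows = {}
        for n in kept:
            seq = str(fasta[n][:])
            vals = [
                gc_fraction(seq[s : s + gc_window])
                for s in range(0, len(seq), gc_window)
            ]
            gc_windows[n] = np.asarray(vals, dtype=float)
    return GenomeLayout(kept, lengths, gc_window=gc_window, gc_windows=gc_windows)


def _layout_from_table(path: str) -> GenomeLayout:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:
        raise InputError(f"cannot read length table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError(f"length table {path} needs two columns (chrom, length)")
    # tolerate an optional header row
    if not str(df.iloc[0, 1]).strip().isdigit():
        df = df.iloc[1:]
    if df.empty:
        raise InputError(f"length table {path} is empty")
    names = df.iloc[:, 0].str.strip().tolist()
    lengths_in = {n: int(v) for n, v in zip(names, df.iloc[:, 1])}
    kept = _restrict_names(names)
    return GenomeLayout(kept, {n: lengths_in[n] for n in kept})
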