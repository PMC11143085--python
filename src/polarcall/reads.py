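"""Aligned-read ingestion, MAPQ filtering, and seeded downsampling.

A read is represented by its leftmost mapped position only; at 1-Mb bin
resolution the read length (520–590 bp typical for rapid nanopore WGA
libraries) is irrelevant. Duplicates are kept — the pipeline applies no
deduplication. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .genome import GenomeLayout

TSV_COLUMNS = ("chrom", "start", "mapq")


@dataclass
class ReadSet:
    """Filtered aligned-read start positions, sorted by (chromosome, start).

    ``chrom_idx`` indexes into ``layout.chromosomes``; ``provenance`` records
    the source and the counts removed by each filter; ``seed`` is set when
    the set is a downsample.
    """

    layout: GenomeLayout
    chrom_idx: np.ndarray
    start: np.ndarray
    mapq: np.ndarray
    provenance: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.chrom_idx = np.asarray(self.chrom_idx, dtype=np.int32)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.mapq = np.asarray(self.mapq, dtype=np.int32)
        if not (len(self.chrom_idx) == len(self.start) == len(self.mapq)):
            raise InputError("read arrays have mismatched lengths")

    def __len__(self) -> int:
        return len(self.start)

    def sort(self) -> None:
        order = np.lexsort((self.start, self.chrom_idx))
        self.chrom_idx = self.chrom_idx[order]
        self.start = self.start[order]
        self.mapq = self.mapq[order]

    def positions(self, chromosome: str) -> np.ndarray:
        """Sorted start positions on one chromosome."""
        idx = self.layout.index(chromosome)
        return np.sort(self.start[self.chrom_idx == idx])

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.chrom_idx.tobytes())
        h.update(self.start.tobytes())
        h.update(self.mapq.tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        chroms = np.asarray(self.layout.chromosomes, dtype=object)
        return pd.DataFrame(
            {"chrom": chroms[self.chrom_idx], "start": self.start, "mapq": self.mapq}
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _filter_records(
    chrom_names: "list[str] | pd.Series",
    starts: np.ndarray,
    mapqs: np.ndarray,
    layout: GenomeLayout,
    min_mapq: int,
    provenance: dict,
) -> ReadSet:
    name_to_idx = {c: layout.index(c) for c in layout.chromosomes}
    idx = pd.Series(chrom_names).map(name_to_idx).to_numpy()
    on_layout = ~pd.isna(idx)
    starts = np.asarray(starts, dtype=np.int64)
    mapqs = np.asarray(mapqs, dtype=np.int64)
    idx_f = np.where(on_layout, idx, -1).astype(np.int32)
    lengths = np.array([layout.length(c) for c in layout.chromosomes], dtype=np.int64)
    in_bounds = on_layout & (starts >= 0) & (starts < lengths[idx_f])
    good_mapq = mapqs >= min_mapq
    keep = on_layout & good_mapq & in_bounds
    provenance.update(
        {
            "min_mapq": min_mapq,
            "n_off_layout": int((~on_layout).sum()),
            "n_low_mapq": int((on_layout & ~good_mapq).sum()),
            "n_out_of_bounds": int((on_layout & good_mapq & ~in_bounds).sum()),
            "n_kept": int(keep.sum()),
        }
    )
    if not keep.any():
        raise AnalysisError("zero surviving reads after filtering")
    rs = ReadSet(
        layout,
        idx_f[keep],
        starts[keep],
        mapqs[keep].astype(np.int32),
        provenance=provenance,
    )
    rs.sort()
    return rs


def ingest_alignments(path: str, layout: GenomeLayout, min_mapq: int = 5) -> ReadSet:
    """Load reads from BAM/SAM (via pysam) or the plain read-TSV format.

    Unmapped, secondary, and supplementary records are excluded; records
    below ``min_mapq`` (default 5) or on chromosomes outside the layout
    (Y, decoys) are dropped and tallied in the provenance.
    """
    lower = str(path).lower()
    if lower.endswith((".bam", ".sam", ".cram")):
        return _ingest_pysam(path, layout, min_mapq)
    return _ingest_tsv(path, layout, min_mapq)


def _ingest_pysam(path: str, layout: GenomeLayout, min_mapq: int) -> ReadSet:
    import pysam

    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot parse alignment file {path}: {exc}") from exc
    names, starts, mapqs = [], [], []
    n_unmapped = n_secondary = 0
    with af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                n_secondary += 1
                continue
            names.append(rec.reference_name)
            starts.append(rec.reference_start)
            mapqs.append(rec.mapping_quality)
    prov = {
        "source": str(path),
        "n_unmapped": n_unmapped,
        "n_secondary_or_supplementary": n_secondary,
    }
    if not names:
        raise AnalysisError("zero surviving reads: file has no mapped primary records")
    return _filter_records(names, starts, mapqs, layout, min_mapq, prov)


def _ingest_tsv(path: str, layout: GenomeLayout, min_mapq: int) -> ReadSet:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise InputError(f"cannot parse read TSV {path}: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"read TSV {path} lacks columns: {', '.join(missing)}")
    prov = {"source": str(path)}
    return _filter_records(
        df["chrom"].astype(str),
        df["start"].to_numpy(dtype=np.int64),
        df["mapq"].to_numpy(dtype=np.int64),
        layout,
        min_mapq,
        prov,
    )


def downsample_reads(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Uniform sample of ``n`` reads without replacement, deterministic in ``seed``."""
    if n <= 0:
        raise InputError("downsample size must be positive")
    if n > len(reads):
        raise InputError(f"cannot downsample {len(reads)} reads to {n}")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(reads), size=n, replace=False)
    keep.sort()
    prov = dict(reads.provenance)
    prov["downsampled_from"] = len(reads)
    prov["downsampled_to"] = n
    prov["downsample_seed"] = seed
    out = ReadSet(
        reads.layout,
        reads.chrom_idx[keep],
        reads.start[keep],
        reads.mapq[keep],
        provenance=prov,
        seed=seed,
    )
    out.sort()
    return out
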