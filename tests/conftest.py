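"""Shared fixtures: toy genome layouts, simulated reference pools, and
small on-disk alignment fixtures, all generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from polarcall.genome import GenomeLayout
from polarcall.reads import ReadSet
from polarcall.simulate import KaryotypeSpec, NoiseModel, simulate_reads, toy_layout


@pytest.fixture(scope="session")
def layout() -> GenomeLayout:
    """23-chromosome toy layout (GRCh38 scaled 1:30, ~101 Mb)."""
    return toy_layout()


@pytest.fixture(scope="session")
def reference_reads(layout) -> ReadSet:
    """Merged euploid reference pool at 2 M reads with mild WGA noise,
    mimicking the pooled reference samples used for blacklisting and
    variable binning."""
    reads, _ = simulate_reads(
        KaryotypeSpec(), layout, 2_000_000, NoiseModel(wga_sigma=0.1), seed=424242
    )
    return reads


@pytest.fixture()
def two_chrom_layout() -> GenomeLayout:
    """Minimal two-chromosome layout for unit-level bin arithmetic."""
    return GenomeLayout(["toyA", "toyB"], {"toyA": 10_000_000, "toyB": 5_000_000})


def make_reads(layout: GenomeLayout, chroms, positions, mapq=60) -> ReadSet:
    """Hand-build a ReadSet from parallel chromosome/position lists."""
    idx = np.array([layout.index(c) for c in chroms], dtype=np.int32)
    pos = np.asarray(positions, dtype=np.int64)
    q = np.full(len(pos), mapq, dtype=np.int32) if np.isscalar(mapq) else np.asarray(mapq)
    rs = ReadSet(layout, idx, pos, q)
    rs.sort()
    return rs


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n"


def write_sam(path, references, records) -> str:
    """Write a minimal SAM file.

    ``references`` is {name: length}; ``records`` is a list of
    (qname, flag, rname, pos0, mapq) with 0-based positions.
    """
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos0, mapq in records:
            if flag & 0x4:
                fh.write(f"{qname}\t{flag}\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
            else:
                fh.write(
                    f"{qname}\t{flag}\t{rname}\t{pos0 + 1}\t{mapq}\t4M\t*\t0\t0\tACGT\t*\n"
                )
    return str(path)
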