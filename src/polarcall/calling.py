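"""Segment construction, 10-Mb filtering, and per-chromosome ploidy calls.

Decoded state paths become maximal same-somy segments (zero-inflation bins
are merged into the larger flanking segment); segments shorter than the
minimum size are reassigned to their dominant neighbour so every chromosome
stays fully tiled; each chromosome is then called by the somy occupying the
most bp, and a sample is aneuploid if at least one chromosome deviates from
the 3-chromatid baseline. More than half of the 23 chromosomes aneuploid
marks the sample highly complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import BinSet
from .errors import InputError
from .genome import GenomeLayout
from .hmm import SOMY_OF_STATE, ZI, StatePath

N_CHROMOSOMES = 23
BASELINE_SOMY = 3
#: more than half of the 23 analysed chromosomes
HIGHLY_COMPLEX_THRESHOLD = N_CHROMOSOMES // 2 + 1


@dataclass
class CopyNumberSegment:
    chromosome: str
    start: int
    end: int
    somy: int
    n_bins: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChromosomePloidyCall:
    chromosome: str
    modal_somy: int | None
    classification: str  # euploid | gain | loss | no-call
    fraction_modal: float = 0.0


@dataclass
class SampleClassification:
    verdict: str  # euploid | aneuploid
    highly_complex: bool
    n_aneuploid_chromosomes: int
    baseline_flag: bool = False
    n_no_call: int = 0

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "highly_complex": self.highly_complex,
            "n_aneuploid_chromosomes": self.n_aneuploid_chromosomes,
            "baseline_flag": self.baseline_flag,
            "n_no_call": self.n_no_call,
        }


def segments_from_path(path: StatePath, binset: BinSet) -> list[CopyNumberSegment]:
    """Merge maximal runs of identical decoded somy into segments.

    Zero-inflation bins are absorbed into the flanking segment with the
    greater bp extent (ties go left); a chromosome decoded entirely as
    zero-inflation yields no segments (a downstream no-call).
    """
    segments: list[CopyNumberSegment] = []
    layout = binset.layout
    for chrom in layout.chromosomes:
        cidx = layout.index(chrom)
        sel = np.flatnonzero(binset.chrom_idx[path.bin_index] == cidx)
        if sel.size == 0:
            continue
        idx = path.bin_index[sel]
        states = path.states[sel]
        starts = binset.start[idx]
        ends = binset.end[idx]
        # run-length encode over states
        runs: list[tuple[int, int, int]] = []  # (state, first, last) index into sel
        first = 0
        for k in range(1, len(states) + 1):
            if k == len(states) or states[k] != states[first]:
                runs.append((int(states[first]), first, k - 1))
                first = k
        # absorb zero-inflation runs into the larger neighbour
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, (st, a, b) in enumerate(runs):
                if st != ZI:
                    continue
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i + 1 < len(runs) else None
                if left is None and right is None:
                    continue
                def _bp(run):
                    return int(ends[run[2]] - starts[run[1]])
                if right is None or (left is not None and _bp(left) >= _bp(right)):
                    heir = left
                else:
                    heir = right
                runs[i] = (heir[0], a, b)
                # re-merge identical neighbours
                merged: list[tuple[int, int, int]] = []
                for run in runs:
                    if merged and merged[-1][0] == run[0]:
                        merged[-1] = (run[0], merged[-1][1], run[2])
                    else:
                        merged.append(run)
                runs = merged
                changed = True
                break
        for st, a, b in runs:
            if st == ZI:
                continue  # whole chromosome zero-inflated
            segments.append(
                CopyNumberSegment(
                    chrom,
                    int(starts[a]),
                    int(ends[b]),
                    int(SOMY_OF_STATE[st]),
                    n_bins=b - a + 1,
                )
            )
    return segments


def filter_segments(
    segments: list[CopyNumberSegment], min_length: int = 10_000_000
) -> list[CopyNumberSegment]:
    """Reassign segments shorter than ``min_length`` to the flanking somy.

    A short segment takes the somy of the flanking segment with the greater
    bp (terminal segments take their only neighbour), adjacent same-somy
    segments are re-merged, and the process iterates until stable, so the
    chromosome tiling is preserved. A chromosome shorter than ``min_length``
    keeps its segments with a warning.
    """
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    out: list[CopyNumberSegment] = []
    too_short: list[str] = []
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        chrom_span = segs[-1].end - segs[0].start
        if chrom_span < min_length:
            too_short.append(chrom)
            out.extend(segs)
            continue
        while True:
            short = [
                i for i, s in enumerate(segs) if s.length < min_length and len(segs) > 1
            ]
            if not short:
                break
            # handle the shortest first for a stable, order-independent result
            i = min(short, key=lambda k: (segs[k].length, k))
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i + 1 < len(segs) else None
            if right is None or (left is not None and left.length >= right.length):
                heir = left
            else:
                heir = right
            segs[i] = CopyNumberSegment(
                chrom, segs[i].start, segs[i].end, heir.somy, segs[i].n_bins
            )
            merged: list[CopyNumberSegment] = []
            for s in segs:
                if merged and merged[-1].somy == s.somy and merged[-1].end == s.start:
                    prev = merged[-1]
                    merged[-1] = CopyNumberSegment(
                        chrom, prev.start, s.end, s.somy, prev.n_bins + s.n_bins
                    )
                else:
                    merged.append(s)
            segs = merged
        out.extend(segs)
    if too_short:
        warnings.warn(
            f"decoded span shorter than the minimum segment size on "
            f"{len(too_short)} chromosome(s) ({', '.join(too_short[:4])}"
            f"{', ...' if len(too_short) > 4 else ''}); their segments kept as-is",
            stacklevel=2,
        )
    order = {c: i for i, c in enumerate(dict.fromkeys(s.chromosome for s in segments))}
    out.sort(key=lambda s: (order[s.chromosome], s.start))
    return out


def call_chromosomes(
    segments: list[CopyNumberSegment], layout: GenomeLayout
) -> list[ChromosomePloidyCall]:
    """Per-chromosome modal-somy call over all layout chromosomes.

    Modal somy is the somy with the greatest total bp; ties prefer the state
    nearer 3-somy, then the lower somy. A chromosome with no decoded
    segments becomes a ``no-call`` (never silently euploid).
    """
    bp: dict[str, dict[int, int]] = {}
    for seg in segments:
        bp.setdefault(seg.chromosome, {}).setdefault(seg.somy, 0)
        bp[seg.chromosome][seg.somy] += seg.length
    calls = []
    for chrom in layout.chromosomes:
        somy_bp = bp.get(chrom)
        if not somy_bp:
            calls.append(ChromosomePloidyCall(chrom, None, "no-call", 0.0))
            continue
        total = sum(somy_bp.values())
        modal = min(
            somy_bp, key=lambda s: (-somy_bp[s], abs(s - BASELINE_SOMY), s)
        )
        if modal == BASELINE_SOMY:
            cls = "euploid"
        elif modal > BASELINE_SOMY:
            cls = "gain"
        else:
            cls = "loss"
        calls.append(
            ChromosomePloidyCall(chrom, modal, cls, somy_bp[modal] / total)
        )
    return calls


def classify_sample(
    calls: list[ChromosomePloidyCall], baseline_flag: bool = False
) -> SampleClassification:
    """Sample verdict from 23 chromosome calls.

    Aneuploid iff at least one chromosome is a gain or a loss; highly
    complex iff more than half (>= 12 of 23) are aneuploid. No-calls count
    toward neither verdict and are reported separately.
    """
    if len(calls) != N_CHROMOSOMES:
        raise InputError(f"expected {N_CHROMOSOMES} chromosome calls, got {len(calls)}")
    n_aneuploid = sum(1 for c in calls if c.classification in ("gain", "loss"))
    n_no_call = sum(1 for c in calls if c.classification == "no-call")
    return SampleClassification(
        verdict="aneuploid" if n_aneuploid >= 1 else "euploid",
        highly_complex=n_aneuploid >= HIGHLY_COMPLEX_THRESHOLD,
        n_aneuploid_chromosomes=n_aneuploid,
        baseline_flag=baseline_flag,
        n_no_call=n_no_call,
    )


def segments_to_bed(
    segments: list[CopyNumberSegment],
    path: str,
    calls: list[ChromosomePloidyCall] | None = None,
) -> None:
    """Write segments as BED (name = somy, score = fraction_modal * 1000)."""
    frac = {c.chromosome: c.fraction_modal for c in calls} if calls else {}
    with open(path, "w") as fh:
        for seg in segments:
            score = int(round(1000 * frac.get(seg.chromosome, 0.0)))
            fh.write(
                f"{seg.chromosome}\t{seg.start}\t{seg.end}\t{seg.somy}-somy\t{score}\n"
            )


def calls_to_dict(calls: list[ChromosomePloidyCall]) -> list[dict]:
    return [
        {
            "chromosome": c.chromosome,
            "modal_somy": c.modal_somy,
            "classification": c.classification,
            "fraction_modal": round(c.fraction_modal, 6),
        }
        for c in calls
    ]
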