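"""Trisomic-baseline aCGH classification and the DLR-spread QC metric.

Commercial aCGH software assumes a diploid genome; pooled first+second
polar bodies of a euploid oocyte instead carry three chromatids per
chromosome, so the expected log2 ratios shift: a gain is log2(4/3) = 0.42
and a loss log2(2/3) = -0.58 rather than the diploid 0.58 / -1. The
classification thresholds are placed halfway between states in copy-number
space: gain above log2(3.5/3) = 0.22, loss below log2(2.5/3) = -0.26.
An autosome is called aneuploid only when the means against BOTH the male
and the female control exceed a threshold in the same direction; for X only
the female control is used (the male control carries a single X).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log2

import numpy as np
import pandas as pd

from .calling import ChromosomePloidyCall, SampleClassification, classify_sample
from .errors import AnalysisError, InputError

#: 1.349 is the IQR of the standard normal; differences of adjacent iid
#: probes have variance 2*sigma^2, hence the sqrt(2).
_DLRS_NORMALISER = 1.349 * np.sqrt(2.0)

PROBE_COLUMNS = ("chrom", "position", "log2_vs_male", "log2_vs_female")


@dataclass
class ACGHProfile:
    """Ordered probe table: chromosome, position, log2 vs male/female control."""

    data: pd.DataFrame
    sample_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"probe table lacks columns: {', '.join(missing)}")
        vals = self.data[["log2_vs_male", "log2_vs_female"]].to_numpy()
        if not np.all(np.isfinite(vals)):
            raise InputError("probe log2 ratios must be finite")
        self.data = self.data.sort_values(
            ["chrom", "position"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path: str, sample_id: str = "") -> "ACGHProfile":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise InputError(f"cannot read probe TSV {path}: {exc}") from exc
        return cls(df, sample_id=sample_id or str(path))

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class ThresholdSet:
    baseline: int
    gain_threshold: float
    loss_threshold: float

    def __post_init__(self) -> None:
        if not self.gain_threshold > 0 > self.loss_threshold:
            raise InputError("gain threshold must be positive, loss negative")


def state_log2(copies: float, baseline: int) -> float:
    """Expected mean log2 ratio of ``copies`` against a ``baseline``-chromatid
    euploid state, e.g. log2(4/3) = 0.42 for a gain on three chromatids."""
    if copies <= 0 or baseline <= 0:
        raise InputError("copies and baseline must be positive")
    return log2(copies / baseline)


def thresholds(baseline: int) -> ThresholdSet:
    """Gain/loss log2 thresholds: the expected boundary between euploid and
    the adjacent states, i.e. log2((baseline±0.5)/baseline)."""
    if baseline < 1:
        raise InputError("baseline must be >= 1")
    return ThresholdSet(
        baseline,
        log2((baseline + 0.5) / baseline),
        log2((baseline - 0.5) / baseline),
    )


def chromosome_means(profile: ACGHProfile) -> pd.DataFrame:
    """Arithmetic mean log2 ratio per chromosome per control channel."""
    if len(profile) == 0:
        raise InputError("empty probe table")
    return (
        profile.data.groupby("chrom", sort=False)[
            ["log2_vs_male", "log2_vs_female"]
        ]
        .mean()
    )


def classify_acgh(
    means: pd.DataFrame,
    thresh: ThresholdSet,
    chromosomes: list[str] | None = None,
) -> tuple[list[ChromosomePloidyCall], SampleClassification]:
    """Threshold classification of per-chromosome means.

    Autosomes are gains when BOTH channel means strictly exceed the gain
    threshold, losses when both fall strictly below the loss threshold, and
    euploid otherwise (a single-channel excursion is treated as a
    control-specific artifact). X uses the female channel only. Comparisons
    are strict so borderline values never silently classify.
    """
    if chromosomes is None:
        chromosomes = list(means.index)
    calls: list[ChromosomePloidyCall] = []
    for chrom in chromosomes:
        is_x = chrom.removeprefix("chr") == "X"
        if chrom not in means.index:
            if is_x:
                raise InputError("missing X-chromosome mean (female channel required)")
            warnings.warn(f"{chrom} has no probes; emitting no-call", stacklevel=2)
            calls.append(ChromosomePloidyCall(chrom, None, "no-call", 0.0))
            continue
        m = float(means.loc[chrom, "log2_vs_male"])
        f = float(means.loc[chrom, "log2_vs_female"])
        if is_x:
            gain = f > thresh.gain_threshold
            loss = f < thresh.loss_threshold
        else:
            gain = m > thresh.gain_threshold and f > thresh.gain_threshold
            loss = m < thresh.loss_threshold and f < thresh.loss_threshold
        if gain:
            calls.append(ChromosomePloidyCall(chrom, thresh.baseline + 1, "gain"))
        elif loss:
            calls.append(ChromosomePloidyCall(chrom, thresh.baseline - 1, "loss"))
        else:
            calls.append(ChromosomePloidyCall(chrom, thresh.baseline, "euploid"))
    return calls, classify_sample(calls)


def dlr_spread(profile: ACGHProfile, channel: str = "female") -> float:
    """Derivative log-ratio spread: robust SD of adjacent-probe log2
    differences, IQR(d) / (1.349 * sqrt(2)), never spanning a chromosome
    boundary. For iid Normal probe noise of SD sigma this estimates sigma.
    """
    if channel not in ("male", "female"):
        raise InputError("channel must be 'male' or 'female'")
    col = f"log2_vs_{channel}"
    diffs = []
    for _, grp in profile.data.groupby("chrom", sort=False):
        vals = grp[col].to_numpy()
        if len(vals) >= 2:
            diffs.append(np.diff(vals))
    if not diffs:
        raise AnalysisError("DLR spread needs >= 2 probes on some chromosome")
    d = np.concatenate(diffs)
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / _DLRS_NORMALISER)
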