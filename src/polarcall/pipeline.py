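"""End-to-end orchestration: ingestion -> binning -> HMM -> calls -> report.

The sequencing pipeline follows the low-pass single-cell CNV recipe for
pooled polar bodies: MAPQ>=5 filtering, fixed 100-kb bin counting with
0.9985/0.1 quantile blacklisting (on both the sample and a merged euploid
reference), variable-width ~1-Mb bins derived from the reference, GC
correction, a zero-inflated NB HMM anchored so the modal state is 3-somy,
and segment filtering at 10 Mb. Reports are plain JSON-serialisable dicts
embedding the configuration, input checksums, and package version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .acgh import ACGHProfile, chromosome_means, classify_acgh, dlr_spread, thresholds
from .binning import (
    count_reads,
    filter_reads_to_unmasked,
    gc_correct,
    make_fixed_bins,
    make_variable_bins,
    quantile_mask,
    reference_normalize,
)
from .calling import (
    calls_to_dict,
    call_chromosomes,
    classify_sample,
    filter_segments,
    segments_from_path,
)
from .concordance import calls_to_units, concordance_stats, cross_table
from .errors import InputError
from .genome import GenomeLayout
from .hmm import anchor_baseline, fit_with_restarts, viterbi
from .reads import ReadSet, downsample_reads, ingest_alignments


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their standard defaults."""

    min_mapq: int = 5
    fixed_bin: int = 100_000
    variable_bin: int = 1_000_000
    quantile_hi: float = 0.9985
    quantile_lo: float = 0.1
    expected_baseline: int = 3
    min_segment: int = 10_000_000
    em_tol: float = 1e-4
    em_max_iter: int = 500
    em_restarts: int = 3
    downsample_n: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.fixed_bin <= 0 or self.variable_bin <= 0:
            raise InputError("mapq threshold and bin sizes must be positive")
        if not 0 <= self.quantile_lo < self.quantile_hi <= 1:
            raise InputError("quantiles must satisfy 0 <= lo < hi <= 1")
        if self.expected_baseline < 1 or self.min_segment <= 0:
            raise InputError("baseline and minimum segment size must be positive")
        if self.em_max_iter < 1 or self.em_restarts < 1:
            raise InputError("EM iteration/restart counts must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _as_reads(source, layout: GenomeLayout, min_mapq: int) -> ReadSet:
    if isinstance(source, ReadSet):
        return source
    return ingest_alignments(str(source), layout, min_mapq=min_mapq)


def run_ont_pipeline(
    sample,
    reference,
    layout: GenomeLayout,
    config: PipelineConfig | None = None,
    sample_id: str = "",
) -> dict:
    """Full sequencing-side analysis of one sample against a euploid
    reference pool. ``sample``/``reference`` may be ReadSets or paths.
    Deterministic given the config seed."""
    config = config or PipelineConfig()
    sample_reads = _as_reads(sample, layout, config.min_mapq)
    reference_reads = _as_reads(reference, layout, config.min_mapq)
    if config.downsample_n is not None and config.downsample_n < len(sample_reads):
        sample_reads = downsample_reads(sample_reads, config.downsample_n, config.seed)

    # The blacklist comes from the euploid reference only: a lo-quantile cut
    # on the sample's own counts would erase genuine whole-chromosome losses
    # (one chromosome is ~4% of bins, well inside the lowest 10%).
    fixed = make_fixed_bins(layout, config.fixed_bin)
    ref_fixed = quantile_mask(
        count_reads(reference_reads, fixed), config.quantile_hi, config.quantile_lo
    )
    sample_kept = filter_reads_to_unmasked(sample_reads, ref_fixed)
    reference_kept = filter_reads_to_unmasked(reference_reads, ref_fixed)
    blacklist = ref_fixed.masked

    variable = make_variable_bins(reference_kept, layout, config.variable_bin)
    counts = count_reads(sample_kept, variable)
    ref_var = count_reads(reference_kept, variable)
    counts = reference_normalize(counts, ref_var)
    counts = gc_correct(counts)

    model = fit_with_restarts(
        counts,
        expected_baseline=config.expected_baseline,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
        n_restarts=config.em_restarts,
        seed=config.seed,
    )
    model = anchor_baseline(
        model, counts, tol=config.em_tol, max_iter=config.em_max_iter
    )
    path = viterbi(model, counts)
    segments = segments_from_path(path, variable)
    segments = filter_segments(segments, config.min_segment)
    calls = call_chromosomes(segments, layout)
    classification = classify_sample(calls, baseline_flag=model.baseline_flag)

    return {
        "tool": "polarcall",
        "version": __version__,
        "sample_id": sample_id,
        "config": config.to_dict(),
        "inputs": {
            "sample_checksum": sample_reads.checksum(),
            "reference_checksum": reference_reads.checksum(),
            "sample_provenance": sample_reads.provenance,
            "reference_provenance": reference_reads.provenance,
        },
        "qc": {
            "n_sample_reads": len(sample_reads),
            "n_reference_reads": len(reference_reads),
            "n_blacklisted_fixed_bins": int(blacklist.sum()),
            "n_variable_bins": len(variable),
            "median_variable_bin_width": float(np.median(variable.widths)),
            "em_loglik": model.loglik_trace[-1] if model.loglik_trace else None,
            "baseline_flag": model.baseline_flag,
        },
        "model": model.to_dict(),
        "segments": [
            {
                "chromosome": s.chromosome,
                "start": s.start,
                "end": s.end,
                "somy": s.somy,
                "n_bins": s.n_bins,
            }
            for s in segments
        ],
        "chromosome_calls": calls_to_dict(calls),
        "classification": classification.to_dict(),
    }


def run_acgh_classifier(profile, baseline: int = 3, sample_id: str = "") -> dict:
    """aCGH-side analysis: chromosome means against both controls,
    trisomic-baseline thresholds, and the DLRS QC metric."""
    if not isinstance(profile, ACGHProfile):
        profile = ACGHProfile.from_tsv(str(profile), sample_id=sample_id)
    thresh = thresholds(baseline)
    means = chromosome_means(profile)
    calls, classification = classify_acgh(means, thresh)
    return {
        "tool": "polarcall",
        "version": __version__,
        "sample_id": profile.sample_id or sample_id,
        "baseline": baseline,
        "thresholds": {
            "gain": thresh.gain_threshold,
            "loss": thresh.loss_threshold,
        },
        "qc": {
            "dlr_spread_female": dlr_spread(profile, "female"),
            "dlr_spread_male": dlr_spread(profile, "male"),
            "n_probes": len(profile),
        },
        "chromosome_means": {
            str(c): [float(means.loc[c, "log2_vs_male"]),
                     float(means.loc[c, "log2_vs_female"])]
            for c in means.index
        },
        "chromosome_calls": calls_to_dict(calls),
        "classification": classification.to_dict(),
    }


def run_concordance(
    reports_a: dict,
    reports_b: dict,
    level: str = "sample",
    exclude: list | None = None,
) -> dict:
    """Cross-tabulate two per-sample report collections.

    ``reports_a``/``reports_b`` map sample id -> report dict (from either
    pipeline); method A forms the table rows.
    """
    if level == "sample":
        calls_a = {s: r["classification"]["verdict"] for s, r in reports_a.items()}
        calls_b = {s: r["classification"]["verdict"] for s, r in reports_b.items()}
    else:
        calls_a, calls_b = {}, {}
        for s, r in reports_a.items():
            calls_a.update(calls_to_units(r["chromosome_calls"], s))
        for s, r in reports_b.items():
            calls_b.update(calls_to_units(r["chromosome_calls"], s))
    table = cross_table(calls_a, calls_b, level=level, exclude=exclude)
    return {
        "level": level,
        "table": table.to_dict(),
        "stats": concordance_stats(table),
    }


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
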