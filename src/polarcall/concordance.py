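"""Cross-tabulation of two methods' ploidy calls and concordance statistics.

Sample-level tables use the classes {euploid, aneuploid}; chromosome-level
tables use {euploid, gain, loss}, with any somy below the baseline mapping
to "loss" (at least one chromatid lost). Per-class concordance is
conditioned on method A's rows (in the study design, A is the aCGH
classification and B the sequencing-based one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

SAMPLE_CLASSES = ("euploid", "aneuploid")
CHROMOSOME_CLASSES = ("euploid", "gain", "loss")


@dataclass
class ConcordanceTable:
    level: str  # "sample" | "chromosome"
    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray
    excluded_units: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise InputError("count matrix shape does not match labels")
        if np.any(self.counts < 0):
            raise InputError("negative cell counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
            "excluded_units": [list(u) if isinstance(u, tuple) else u
                               for u in self.excluded_units],
        }


def _normalise_class(value, level: str) -> str:
    """Map a call to its table class; sub-baseline somies all map to loss."""
    v = str(value)
    if level == "sample":
        if v not in SAMPLE_CLASSES:
            raise InputError(f"sample-level class must be euploid/aneuploid, got {v}")
        return v
    if v in CHROMOSOME_CLASSES:
        return v
    raise InputError(f"chromosome-level class must be euploid/gain/loss, got {v}")


def cross_table(
    calls_a: dict,
    calls_b: dict,
    level: str = "sample",
    exclude: list | None = None,
) -> ConcordanceTable:
    """Cross-tabulate two call sets keyed by unit.

    Units are sample ids (sample level) or (sample, chromosome) pairs
    (chromosome level); only units present in both sets are tabulated,
    the rest are listed as excluded, as are explicitly excluded samples.
    """
    if level not in ("sample", "chromosome"):
        raise InputError("level must be 'sample' or 'chromosome'")
    labels = SAMPLE_CLASSES if level == "sample" else CHROMOSOME_CLASSES
    exclude = set(exclude or [])

    def _excluded(unit) -> bool:
        sample = unit[0] if isinstance(unit, tuple) else unit
        return sample in exclude

    shared = [
        u for u in calls_a if u in calls_b and not _excluded(u)
    ]
    if not shared:
        raise InputError("no shared units between the two call sets")
    dropped = sorted(
        set(calls_a).symmetric_difference(calls_b)
        | {u for u in calls_a if _excluded(u)},
        key=str,
    )
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    pos = {c: i for i, c in enumerate(labels)}
    for u in shared:
        if str(calls_a[u]) == "no-call" or str(calls_b[u]) == "no-call":
            dropped.append(u)
            continue
        a = _normalise_class(calls_a[u], level)
        b = _normalise_class(calls_b[u], level)
        counts[pos[a], pos[b]] += 1
    return ConcordanceTable(level, labels, labels, counts, excluded_units=dropped)


def concordance_stats(table: ConcordanceTable) -> dict:
    """Overall concordance (trace/total) and per-class concordance
    (diagonal over method-A row total; None for an empty row)."""
    if table.total == 0:
        raise InputError("empty concordance table")
    diag = np.diag(table.counts)
    overall = float(diag.sum()) / table.total
    per_class = {}
    for i, label in enumerate(table.row_labels):
        row = int(table.counts[i].sum())
        per_class[label] = float(diag[i]) / row if row > 0 else None
    return {"overall": overall, "per_class": per_class}


def gain_loss_tally(calls: dict) -> dict:
    """Count gain/loss classifications overall and per chromosome.

    ``calls`` maps (sample, chromosome) -> classification.
    """
    gains = losses = 0
    per_chromosome: dict[str, dict[str, int]] = {}
    for (_, chrom), cls in calls.items():
        entry = per_chromosome.setdefault(str(chrom), {"gains": 0, "losses": 0})
        if cls == "gain":
            gains += 1
            entry["gains"] += 1
        elif cls == "loss":
            losses += 1
            entry["losses"] += 1
    return {"gains": gains, "losses": losses, "per_chromosome": per_chromosome}


def calls_to_units(report_calls: list[dict], sample_id: str) -> dict:
    """Flatten a report's chromosome calls into {(sample, chrom): class}."""
    return {
        (sample_id, c["chromosome"]): c["classification"] for c in report_calls
    }
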