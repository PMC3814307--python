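"""Fold-change target calling and the direct/indirect partition.

A gene is *derepressed* when its mutant/wild-type ratio is threshold-fold or
more (inclusive, default 3-fold) at at least one post-diauxic-shift
timepoint, and *under-represented* when the ratio is threshold-fold or more
below 1.  Derepressed genes whose promoter window carries at least one
binding-site match are *direct* targets; derepressed genes without a site
are *indirect*; everything else is *none*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "POST_DS_TIMEPOINTS",
    "TargetCall",
    "ClassificationSummary",
    "call_regulated",
    "partition_targets",
    "timepoint_tables",
]

# The 14 h sample is the diauxic shift itself; "post-DS" begins at 18 h and
# includes purified quiescent cells.  Configurable wherever used.
POST_DS_TIMEPOINTS: tuple[str, ...] = ("18", "24", "48", "Q")

# Relative slop on the log2-ratio comparison so that an exactly
# threshold-fold ratio is called (the threshold is inclusive) even when the
# ratio was computed through a different floating-point path.
_REL_TOL = 1e-9


@dataclass
class TargetCall:
    gene_id: str
    log2_ratio: dict[str, float]
    derepressed_at: frozenset[str]
    underrepresented_at: frozenset[str]
    has_motif: bool
    cls: str  # direct | indirect | none
    gene_name: str = ""


@dataclass
class ClassificationSummary:
    n_genes: int
    n_derepressed: int
    n_direct: int
    n_indirect: int
    n_underrepresented: int

    @property
    def fraction_direct(self) -> float:
        return self.n_direct / self.n_derepressed if self.n_derepressed else 0.0


def call_regulated(
    ratios: pd.DataFrame,
    threshold_fold: float = 3.0,
    post_ds_timepoints: Sequence[str] = POST_DS_TIMEPOINTS,
    direction: str = "up",
) -> dict[str, frozenset[str]]:
    """Per-gene set of post-DS timepoints where the gene passes the fold cut.

    ``ratios`` is a genes x timepoints table of log2(mutant / wild-type).
    ``direction="up"`` calls derepression (ratio >= threshold);
    ``direction="down"`` calls under-representation (ratio <= 1/threshold).
    The comparison is inclusive: an exactly threshold-fold change is called.
    """
    if threshold_fold <= 1:
        raise ValueError(f"threshold_fold must be > 1, got {threshold_fold}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    unknown = [tp for tp in post_ds_timepoints if tp not in ratios.columns]
    if unknown:
        raise ValueError(f"unknown timepoint label(s): {unknown}")
    cut = np.log2(threshold_fold)
    tol = _REL_TOL * max(1.0, abs(cut))
    calls: dict[str, frozenset[str]] = {}
    sub = ratios[list(post_ds_timepoints)]
    for gene, row in zip(sub.index, sub.to_numpy(dtype=float)):
        if direction == "up":
            passed = row >= cut - tol
        else:
            passed = row <= -cut + tol
        calls[gene] = frozenset(
            tp for tp, ok in zip(post_ds_timepoints, passed) if ok
        )
    return calls


def partition_targets(
    ratios: pd.DataFrame,
    up_calls: Mapping[str, frozenset[str]],
    down_calls: Mapping[str, frozenset[str]],
    motif_genes: Iterable[str],
    scanned_genes: Iterable[str],
    gene_names: Mapping[str, str] | None = None,
) -> tuple[list[TargetCall], ClassificationSummary]:
    """Assign direct/indirect/none classes and summarize the partition.

    ``motif_genes`` are genes with at least one promoter motif hit;
    ``scanned_genes`` is the full set of promoters that were scanned — a
    called gene whose promoter was never scanned is an error, because its
    motif status would be unknowable rather than FALSE.
    """
    scanned = set(scanned_genes)
    with_motif = set(motif_genes)
    names = gene_names or {}
    unscanned = sorted(
        g for g in ratios.index
        if (up_calls.get(g) or down_calls.get(g)) and g not in scanned
    )
    if unscanned:
        raise ValueError(
            f"called genes missing from the scanned promoter set: {unscanned[:10]}"
        )
    calls: list[TargetCall] = []
    n_derepressed = n_direct = n_indirect = n_down = 0
    for gene in ratios.index:
        up = up_calls.get(gene, frozenset())
        down = down_calls.get(gene, frozenset())
        has_motif = gene in with_motif
        if up:
            n_derepressed += 1
            if has_motif:
                cls = "direct"
                n_direct += 1
            else:
                cls = "indirect"
                n_indirect += 1
        else:
            cls = "none"
        if down:
            n_down += 1
        calls.append(
            TargetCall(
                gene_id=gene,
                gene_name=names.get(gene, ""),
                log2_ratio={tp: float(v) for tp, v in ratios.loc[gene].items()},
                derepressed_at=up,
                underrepresented_at=down,
                has_motif=has_motif,
                cls=cls,
            )
        )
    summary = ClassificationSummary(
        n_genes=len(calls),
        n_derepressed=n_derepressed,
        n_direct=n_direct,
        n_indirect=n_indirect,
        n_underrepresented=n_down,
    )
    return calls, summary


def timepoint_tables(
    calls: Sequence[TargetCall],
    timepoints: Sequence[str] = POST_DS_TIMEPOINTS,
    first_called_only: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-timepoint tables of called genes with their motif flag.

    By default a gene appears in the table of every timepoint at which it is
    called (the per-timepoint-snapshot convention); with
    ``first_called_only`` it appears only at its earliest called timepoint.
    """
    tables: dict[str, pd.DataFrame] = {}
    for tp in timepoints:
        rows = []
        for call in calls:
            for direction, called_at in (
                ("up", call.derepressed_at),
                ("down", call.underrepresented_at),
            ):
                if tp not in called_at:
                    continue
                if first_called_only:
                    first = min(called_at, key=lambda t: timepoints.index(t))
                    if first != tp:
                        continue
                rows.append(
                    {
                        "gene_id": call.gene_id,
                        "direction": direction,
                        "has_motif": call.has_motif,
                        "class": call.cls if direction == "up" else "none",
                    }
                )
        frame = pd.DataFrame(rows, columns=["gene_id", "direction", "has_motif", "class"])
        tables[tp] = frame.sort_values(["direction", "gene_id"]).reset_index(drop=True)
    return tables
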