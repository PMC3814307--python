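"""Count normalization and per-timepoint mutant/wild-type expression ratios.

Two normalizations are provided: MRPKBME (mapped reads per kilobase of
modeled exon per million mapped reads, an RPKM-style unit whose denominator
is the summed exon length of the gene model) and median-of-ratios size
factors.  Fold-change calling downstream uses size-factor-normalized counts
by default; both paths produce the same log2-ratio surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneModel, SampleTag

__all__ = [
    "ExpressionTable",
    "compute_mrpkbme",
    "estimate_size_factors",
    "normalized_counts",
    "compute_log2_ratios",
    "log2_ratios_from_expression",
]


@dataclass
class ExpressionTable:
    """Genes x samples non-negative expression values with a unit flag."""

    values: pd.DataFrame
    unit: str
    samples: list[SampleTag]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


def compute_mrpkbme(counts: CountMatrix, models: Mapping[str, GeneModel]) -> ExpressionTable:
    """Reads per kilobase of modeled exon per million mapped reads.

    value = reads / ((modeled_exon_length / 1000) * (library total / 1e6)).
    """
    missing = [g for g in counts.gene_ids if g not in models]
    if missing:
        raise ValueError(f"genes lacking a gene model: {missing[:5]}")
    totals = counts.counts.sum(axis=0).astype(float)
    zero = [str(s) for s, t in zip(counts.samples, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total mapped reads: {zero}")
    lengths_kb = np.array(
        [models[g].modeled_exon_length / 1000.0 for g in counts.gene_ids]
    )
    values = counts.counts / (lengths_kb[:, None] * (totals[None, :] / 1e6))
    frame = pd.DataFrame(
        values,
        index=pd.Index(counts.gene_ids, name="gene_id"),
        columns=[str(s) for s in counts.samples],
    )
    return ExpressionTable(values=frame, unit="MRPKBME", samples=list(counts.samples))


def estimate_size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-gene reference is the geometric mean across samples, computed on
    genes with nonzero counts in every sample (the geometric mean is
    undefined at zero); each sample's factor is the median over those genes
    of count / reference.
    """
    arr = counts.counts.astype(float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_arr = np.log(arr[all_nonzero])
    log_ref = log_arr.mean(axis=1)
    log_factors = np.median(log_arr - log_ref[:, None], axis=0)
    log_factors -= log_factors.mean()  # geometric mean -> 1
    return np.exp(log_factors)


def normalized_counts(counts: CountMatrix, factors: np.ndarray) -> ExpressionTable:
    """Counts divided by their per-sample size factors."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValueError("one size factor per sample required")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    frame = pd.DataFrame(
        counts.counts / factors[None, :],
        index=pd.Index(counts.gene_ids, name="gene_id"),
        columns=[str(s) for s in counts.samples],
    )
    return ExpressionTable(frame, unit="size-factor-normalized", samples=list(counts.samples))


def _ratio_table(
    expr: ExpressionTable,
    pseudocount: float,
    mutant: str,
    wildtype: str,
    timepoints: Sequence[str] | None,
    ratio_mode: str,
) -> pd.DataFrame:
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if ratio_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown ratio mode {ratio_mode!r}")
    tags = expr.samples
    if timepoints is None:
        seen: list[str] = []
        for tag in tags:
            if tag.timepoint not in seen:
                seen.append(tag.timepoint)
        timepoints = seen
    values = expr.values.to_numpy(dtype=float)
    out = np.empty((values.shape[0], len(timepoints)))
    for j, tp in enumerate(timepoints):
        mut_cols = [i for i, t in enumerate(tags) if t.strain == mutant and t.timepoint == tp]
        wt_cols = [i for i, t in enumerate(tags) if t.strain == wildtype and t.timepoint == tp]
        if not mut_cols or not wt_cols:
            missing = mutant if not mut_cols else wildtype
            raise ValueError(f"strain {missing!r} has no samples at timepoint {tp!r}")
        if ratio_mode == "ratio_of_means":
            m = values[:, mut_cols].mean(axis=1)
            w = values[:, wt_cols].mean(axis=1)
            # pseudocount 0 with zero counts legitimately yields +/-inf
            with np.errstate(divide="ignore", invalid="ignore"):
                out[:, j] = np.log2((m + pseudocount) / (w + pseudocount))
        else:
            # mean of per-replicate log2 ratios, paired by replicate label
            mut_by_rep = {tags[i].replicate: i for i in mut_cols}
            wt_by_rep = {tags[i].replicate: i for i in wt_cols}
            shared = sorted(set(mut_by_rep) & set(wt_by_rep))
            if not shared:
                raise ValueError(
                    f"no paired replicates between strains at timepoint {tp!r}"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = [
                    np.log2(
                        (values[:, mut_by_rep[r]] + pseudocount)
                        / (values[:, wt_by_rep[r]] + pseudocount)
                    )
                    for r in shared
                ]
            out[:, j] = np.mean(ratios, axis=0)
    return pd.DataFrame(out, index=expr.values.index, columns=list(timepoints))


def compute_log2_ratios(
    counts: CountMatrix,
    factors: np.ndarray,
    pseudocount: float = 0.5,
    mutant: str = "xbp1",
    wildtype: str = "wt",
    timepoints: Sequence[str] | None = None,
    ratio_mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Per-gene, per-timepoint log2(mutant / wild-type) on normalized counts.

    Replicates are averaged after normalization; the symmetric pseudocount
    (default 0.5 normalized units, added to both strains) keeps ratios
    defined at zero counts without directional bias.
    """
    expr = normalized_counts(counts, factors)
    return _ratio_table(expr, pseudocount, mutant, wildtype, timepoints, ratio_mode)


def log2_ratios_from_expression(
    expr: ExpressionTable,
    pseudocount: float = 0.5,
    mutant: str = "xbp1",
    wildtype: str = "wt",
    timepoints: Sequence[str] | None = None,
    ratio_mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Same ratio surface computed from an arbitrary expression unit
    (e.g. MRPKBME)."""
    return _ratio_table(expr, pseudocount, mutant, wildtype, timepoints, ratio_mode)
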