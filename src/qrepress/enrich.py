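"""Hypergeometric category enrichment with multiple-testing correction.

The statistic is the one-sided hypergeometric upper tail (Fisher's exact
test, enrichment direction): the probability of drawing at least k
category members when n genes are sampled without replacement from a
universe of N containing K members.  Correction is Bonferroni across the
categories tested (those with at least one target gene) by default, with
Benjamini-Hochberg offered as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = ["EnrichmentResult", "hypergeometric_pvalue", "enrich_gene_sets"]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int          # target genes in the category
    K: int          # universe genes in the category
    n: int          # target-set size
    N: int          # universe size
    p_raw: float
    p_corrected: float


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for a hypergeometric draw of n from N with K
    successes.  Evaluated through the survival function, which works in log
    space internally and is stable for the tiny tails typical of genome-scale
    enrichment."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _bonferroni(p_values: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, p_values * len(p_values))


def _benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    m = len(p_values)
    order = np.argsort(p_values, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p_values[idx] * m / rank)
        adjusted[idx] = running_min
    return np.minimum(1.0, adjusted)


def enrich_gene_sets(
    targets: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Enrichment of a target gene set in each annotation category.

    ``annotation`` maps category id -> genes in the category.  One result is
    produced per category containing at least one target gene; the corrected
    p-value multiplies by the number of such tested categories (Bonferroni)
    or applies the Benjamini-Hochberg step-up (``correction="bh"``).
    Results are sorted by corrected p ascending, ties by category id, and
    are independent of category iteration order.
    """
    if correction not in ("bonferroni", "bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    target_set = set(targets)
    outside = target_set - universe_set
    if outside:
        raise ValueError(f"target genes outside the universe: {sorted(outside)[:5]}")
    for category, genes in annotation.items():
        stray = set(genes) - universe_set
        if stray:
            raise ValueError(
                f"annotated genes outside the universe in category "
                f"{category!r}: {sorted(stray)[:5]}"
            )

    N = len(universe_set)
    n = len(target_set)
    rows = []
    for category in sorted(annotation):
        members = set(annotation[category]) & universe_set
        k = len(members & target_set)
        if k == 0:
            continue
        rows.append((category, k, len(members)))
    if not rows:
        return []
    p_raw = np.array([hypergeometric_pvalue(k, K, n, N) for _, k, K in rows])
    if correction == "bonferroni":
        p_corr = _bonferroni(p_raw)
    elif correction == "bh":
        p_corr = _benjamini_hochberg(p_raw)
    else:
        p_corr = p_raw.copy()
    results = [
        EnrichmentResult(category=c, k=k, K=K, n=n, N=N,
                         p_raw=float(p), p_corrected=float(pc))
        for (c, k, K), p, pc in zip(rows, p_raw, p_corr)
    ]
    results.sort(key=lambda r: (r.p_corrected, r.category))
    return results
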