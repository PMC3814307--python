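"""Phase-anticorrelation screen over metabolic-cycle expression profiles.

Genes whose cycle profiles track the averaged profile of a small seed set of
known repressor targets (the targets peak half a cycle away from the
repressor itself) are ranked by Pearson correlation; the top-k list is the
candidate target set that promoter scanning is then intersected with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenResult", "reference_profile", "rank_by_correlation"]


@dataclass
class ScreenResult:
    """Correlation-ranked genes: sorted by r descending, ties broken
    lexicographically by gene id; constant profiles are assigned r = 0 and
    listed in ``constant_genes``."""

    ranked: list[tuple[str, float]]
    reference: np.ndarray
    k: int
    constant_genes: list[str] = field(default_factory=list)

    def top_ids(self) -> list[str]:
        return [gene for gene, _ in self.ranked[: self.k]]


def _check_profiles(profiles: pd.DataFrame) -> np.ndarray:
    values = profiles.to_numpy(dtype=float)
    if values.shape[1] < 4:
        raise ValueError("profiles need at least 4 cycle timepoints")
    if not np.isfinite(values).all():
        raise ValueError("profiles contain non-finite values")
    return values


def reference_profile(profiles: pd.DataFrame, seed_ids: list[str]) -> np.ndarray:
    """Average of the z-scored (population sd) seed-gene profiles.

    The >=4-timepoint requirement applies to the ranking step; the reference
    itself only needs a non-constant seed vector.
    """
    missing = [g for g in seed_ids if g not in profiles.index]
    if missing:
        raise ValueError(f"seed gene(s) not in profile table: {missing}")
    if not seed_ids:
        raise ValueError("at least one seed gene required")
    zscored = []
    for gene in seed_ids:
        vec = profiles.loc[gene].to_numpy(dtype=float)
        if not np.isfinite(vec).all():
            raise ValueError(f"seed gene {gene!r} has non-finite values")
        sd = vec.std()  # population convention (ddof=0)
        if sd == 0:
            raise ValueError(f"seed gene {gene!r} has a constant profile")
        zscored.append((vec - vec.mean()) / sd)
    return np.mean(zscored, axis=0)


def rank_by_correlation(
    profiles: pd.DataFrame, reference: np.ndarray, k: int = 100
) -> ScreenResult:
    """Pearson-correlate every profile with the reference and return top-k."""
    values = _check_profiles(profiles)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (values.shape[1],):
        raise ValueError(
            f"reference length {reference.shape} does not match "
            f"{values.shape[1]} timepoints"
        )
    if reference.std() == 0:
        raise ValueError("reference profile is constant")
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds the {values.shape[0]} available profiles")

    centered = values - values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1)
    ref_c = reference - reference.mean()
    ref_sd = reference.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ ref_c) / (values.shape[1] * sds * ref_sd)
    constant = sds == 0
    r = np.where(constant, 0.0, r)
    r = np.clip(r, -1.0, 1.0)

    genes = list(profiles.index)
    order = sorted(range(len(genes)), key=lambda i: (-r[i], genes[i]))
    ranked = [(genes[i], float(r[i])) for i in order]
    return ScreenResult(
        ranked=ranked,
        reference=reference,
        k=k,
        constant_genes=[genes[i] for i in np.flatnonzero(constant)],
    )
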