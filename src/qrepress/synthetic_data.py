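"""Ground-truthed synthetic fixtures for every pipeline stage.

The generator emulates the statistical structure of a two-strain (wild type
vs. repressor deletion) RNA-seq time course across the transition to
quiescence, plus companion promoter sequences and metabolic-cycle
oscillation profiles:

* promoters are i.i.d. background sequence (GC fraction 0.38, yeast-like)
  with exactly one ``CTCGA[G/A]`` site planted per direct target and all
  incidental matches scrubbed, so the planted set is exactly recoverable;
* counts are negative-binomially dispersed around per-gene baselines with
  per-sample depth factors, the derepression effect applied only in the
  deletion strain at post-diauxic-shift timepoints, and the repressor gene
  itself strongly induced in wild type from the shift onward and absent in
  the deletion strain;
* oscillation profiles are one-cycle sinusoids with Gaussian noise; the
  repressor peaks at phase 0 and targets at phase pi (anti-phase), while
  non-target phases avoid a pi/4 band around pi so that the planted
  anti-phase labels remain identifiable at realistic noise levels.

Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneModel, SampleTag
from .motif_scan import PromoterWindow, reverse_complement, scan_iupac

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_promoter_set",
    "simulate_counts",
    "simulate_ymc_profiles",
    "simulate_annotation",
    "build_toy_genome",
    "direct_ids",
    "indirect_ids",
    "write_truth_table",
    "read_truth_table",
]

MOTIF = "CTCGAR"
MOTIF_VARIANTS = ("CTCGAG", "CTCGAA")
_SCRUB_CAP = 100


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the scale of the recovery experiments: 2,000 genes, 100
    direct and 50 indirect planted targets with a 5-fold derepression
    effect, negative-binomial dispersion 0.05 and one replicate per
    strain/timepoint (the time-course design this emulates was single-
    replicate; replicates stay configurable).
    """

    n_genes: int = 2000
    n_direct: int = 100
    n_indirect: int = 50
    effect_fold: float = 5.0
    dispersion: float = 0.05
    promoter_length: int = 800
    gc_content: float = 0.38
    timepoints: tuple[str, ...] = ("8", "14", "18", "24", "48", "Q")
    post_ds_timepoints: tuple[str, ...] = ("18", "24", "48", "Q")
    replicates: int = 1
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    depth_range: tuple[float, float] = (0.5, 2.0)
    repressor_id: str = "XBP1"
    repressor_baseline: float = 50.0
    repressor_induction_fold: float = 50.0
    mutant_strain: str = "xbp1"
    wildtype_strain: str = "wt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_direct < 0 or self.n_indirect < 0:
            raise ValueError("target counts must be non-negative")
        if self.n_direct + self.n_indirect > self.n_genes:
            raise ValueError("n_direct + n_indirect exceeds n_genes")
        if self.promoter_length < len(MOTIF):
            raise ValueError(
                f"promoter_length must be >= {len(MOTIF)}, got {self.promoter_length}"
            )
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.effect_fold < 0:
            raise ValueError("effect_fold must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not set(self.post_ds_timepoints) <= set(self.timepoints):
            raise ValueError("post_ds_timepoints must be a subset of timepoints")
        if self.baseline_range[0] <= 0:
            raise ValueError("baselines must be positive")

    @property
    def gene_ids(self) -> list[str]:
        """Regular genes plus the repressor itself (appended last)."""
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)] + [
            self.repressor_id
        ]


@dataclass
class SyntheticTruth:
    """Per-gene ground truth the recovery experiments score against."""

    gene_id: str
    is_direct_target: bool = False
    is_indirect_target: bool = False
    effect_fold: float = 1.0
    motif_offsets: list[int] = field(default_factory=list)
    phase_radians: float = float("nan")

    def __post_init__(self) -> None:
        if self.is_direct_target and self.is_indirect_target:
            raise ValueError(f"{self.gene_id}: direct and indirect are exclusive")
        if self.effect_fold <= 0:
            raise ValueError(f"{self.gene_id}: effect_fold must be positive")


def direct_ids(truth: Sequence[SyntheticTruth]) -> set[str]:
    return {t.gene_id for t in truth if t.is_direct_target}


def indirect_ids(truth: Sequence[SyntheticTruth]) -> set[str]:
    return {t.gene_id for t in truth if t.is_indirect_target}


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stage])


def _assign_truth(config: SimulationConfig, rng: np.random.Generator) -> list[SyntheticTruth]:
    regular = config.gene_ids[:-1]
    chosen = rng.choice(len(regular), size=config.n_direct + config.n_indirect, replace=False)
    direct = {regular[i] for i in chosen[: config.n_direct]}
    indirect = {regular[i] for i in chosen[config.n_direct :]}
    truth = []
    for gene in config.gene_ids:
        is_d = gene in direct
        is_i = gene in indirect
        truth.append(
            SyntheticTruth(
                gene_id=gene,
                is_direct_target=is_d,
                is_indirect_target=is_i,
                effect_fold=config.effect_fold if (is_d or is_i) else 1.0,
            )
        )
    return truth


def _scrub_promoter(
    seq: list[str],
    rng: np.random.Generator,
    bases: str,
    probs: np.ndarray,
    keep_span: tuple[int, int] | None,
) -> None:
    """Resample 6-mer windows that match the motif until only the planted
    site (if any) remains.  Mutates ``seq`` in place."""
    m = len(MOTIF)
    for _ in range(_SCRUB_CAP):
        window = PromoterWindow(gene_id="_", sequence="".join(seq))
        hits = scan_iupac(window, MOTIF, both_strands=True)
        offending = [
            h for h in hits
            if keep_span is None or (h.offset, h.offset + m) != keep_span
        ]
        if not offending:
            return
        for hit in offending:
            for pos in range(hit.offset, hit.offset + m):
                if keep_span is not None and keep_span[0] <= pos < keep_span[1]:
                    continue
                seq[pos] = bases[rng.choice(4, p=probs)]
    raise RuntimeError("promoter scrubbing did not converge within 100 iterations")


def generate_promoter_set(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, GeneModel], list[SyntheticTruth]]:
    """Background promoters with one planted binding site per direct target.

    Every direct-target promoter carries exactly one ``CTCGA[G/A]`` site at
    a uniformly random offset, on a uniformly random strand, with the G/A
    variant chosen uniformly; all incidental matches (in every promoter)
    are scrubbed by resampling the offending hexamer.  Gene models place
    each gene on its own contig, promoter at [1, L], start codon at L+1.
    """
    rng = _rng(config.seed, 0)
    truth = _assign_truth(config, rng)
    L = config.promoter_length
    gc = config.gc_content
    bases = "ACGT"
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    promoters: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    direct = direct_ids(truth)
    for record in truth:
        gene = record.gene_id
        seq = [bases[i] for i in rng.choice(4, size=L, p=probs)]
        keep_span = None
        if gene in direct:
            offset = int(rng.integers(0, L - len(MOTIF) + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            variant = MOTIF_VARIANTS[int(rng.integers(0, 2))]
            word = variant if strand == "+" else reverse_complement(variant)
            seq[offset : offset + len(MOTIF)] = list(word)
            keep_span = (offset, offset + len(MOTIF))
            record.motif_offsets = [offset]
        _scrub_promoter(seq, rng, bases, probs, keep_span)
        promoters[gene] = "".join(seq)
        models[gene] = GeneModel(
            gene_id=gene,
            chrom=f"chr_{gene}",
            strand="+",
            translational_start=L + 1,
            exon_intervals=((L + 1, L + 600),),
        )
    return promoters, models, truth


def build_toy_genome(
    promoters: Mapping[str, str], models: Mapping[str, GeneModel]
) -> dict[str, str]:
    """Per-gene contigs consistent with the generated models: promoter
    followed by a 600-base coding sequence."""
    genome = {}
    for gene, promoter in promoters.items():
        cds = "ATG" + "A" * 594 + "TAA"
        genome[models[gene].chrom] = promoter + cds
    return genome


def simulate_counts(config: SimulationConfig, truth: Sequence[SyntheticTruth]) -> CountMatrix:
    """Negative-binomial counts with planted post-DS derepression.

    mean(gene, sample) = baseline x depth factor x effect, where the effect
    applies only in the deletion strain at post-DS timepoints for target
    genes.  The repressor gene is induced ``repressor_induction_fold``-fold
    in wild type from the diauxic shift onward and has zero mean in the
    deletion strain.  ``dispersion`` d gives variance mu + d mu^2; d = 0
    degenerates to deterministic rounded means.
    """
    if [t.gene_id for t in truth] != config.gene_ids:
        raise ValueError("truth records do not match the configured gene set")
    rng = _rng(config.seed, 1)
    genes = config.gene_ids
    n = len(genes)

    lo, hi = config.baseline_range
    # integer baselines keep the dispersion-0 degenerate case exact
    baselines = np.maximum(1, np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))))
    baselines[-1] = config.repressor_baseline  # the repressor itself

    samples: list[SampleTag] = []
    for strain in (config.wildtype_strain, config.mutant_strain):
        for tp in config.timepoints:
            for rep in range(1, config.replicates + 1):
                samples.append(SampleTag(strain, tp, f"r{rep}"))
    d_lo, d_hi = config.depth_range
    depths = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi), size=len(samples)))

    target = np.array(
        [t.is_direct_target or t.is_indirect_target for t in truth], dtype=bool
    )
    effects = np.array([t.effect_fold for t in truth])
    post_ds = set(config.post_ds_timepoints)
    ds_onward = set(config.timepoints[1:])  # induced from the shift onward

    means = np.empty((n, len(samples)))
    for j, tag in enumerate(samples):
        mu = baselines.copy()
        if tag.strain == config.mutant_strain and tag.timepoint in post_ds:
            mu = np.where(target, mu * effects, mu)
        # repressor row: induced in wild type at >= 14 h, absent in the mutant
        if tag.strain == config.wildtype_strain:
            if tag.timepoint in ds_onward:
                mu[-1] = config.repressor_baseline * config.repressor_induction_fold
        else:
            mu[-1] = 0.0
        means[:, j] = mu * depths[j]

    if config.dispersion == 0:
        counts = np.rint(means).astype(np.int64)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + means)
        counts = np.where(
            means > 0, rng.negative_binomial(r, p), 0
        ).astype(np.int64)
    return CountMatrix(list(genes), samples, counts)


def simulate_ymc_profiles(
    n_genes: int,
    n_timepoints: int,
    noise_sd: float,
    truth: Sequence[SyntheticTruth],
    seed: int,
    anti_phase_margin: float = math.pi / 4,
) -> pd.DataFrame:
    """One-cycle sinusoidal metabolic-cycle profiles with Gaussian noise.

    profile_g(t) = sin(2 pi t / n_timepoints + phase_g) + N(0, noise_sd).
    The repressor peaks at phase 0; planted targets at phase pi.  Non-target
    phases are uniform outside a ``anti_phase_margin`` band around pi — the
    band keeps planted anti-phase labels identifiable (a non-target at phase
    ~pi would be statistically indistinguishable from a planted one).
    Phases are recorded back onto the truth records.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 cycle timepoints")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_genes != len(truth):
        raise ValueError(f"n_genes={n_genes} but {len(truth)} truth records")
    rng = np.random.default_rng([seed, 2])
    two_pi = 2 * math.pi
    phases = np.empty(len(truth))
    for i, record in enumerate(truth):
        if record.gene_id.upper() == "XBP1" or record.gene_id.endswith("repressor"):
            phases[i] = 0.0
        elif record.is_direct_target or record.is_indirect_target:
            phases[i] = math.pi
        else:
            arc = two_pi - 2 * anti_phase_margin
            phases[i] = (math.pi + anti_phase_margin + rng.uniform(0, arc)) % two_pi
        record.phase_radians = float(phases[i])
    t = np.arange(n_timepoints)
    clean = np.sin(two_pi * t[None, :] / n_timepoints + phases[:, None])
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    values = clean + noise
    return pd.DataFrame(
        values,
        index=pd.Index([r.gene_id for r in truth], name="gene_id"),
        columns=[f"t{i:02d}" for i in range(n_timepoints)],
    )


def simulate_annotation(
    truth: Sequence[SyntheticTruth],
    seed: int,
    n_categories: int = 8,
    enriched_category: str = "target_process",
    enrichment_fraction: float = 0.6,
) -> dict[str, set[str]]:
    """A flat gene->category map with one category enriched for targets.

    Every gene gets one background category; a fraction of the planted
    targets is additionally pooled into ``enriched_category`` so that the
    enrichment stage has a planted positive to find.
    """
    rng = np.random.default_rng([seed, 3])
    categories: dict[str, set[str]] = {
        f"C{i + 1:02d}": set() for i in range(n_categories)
    }
    names = sorted(categories)
    for record in truth:
        categories[names[int(rng.integers(0, n_categories))]].add(record.gene_id)
    enriched = set()
    for record in truth:
        if (record.is_direct_target or record.is_indirect_target) and rng.uniform() < enrichment_fraction:
            enriched.add(record.gene_id)
    if enriched:
        categories[enriched_category] = enriched
    return categories


# ---------------------------------------------------------------------------
# Truth table round-trip
# ---------------------------------------------------------------------------

def write_truth_table(truth: Sequence[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "gene_id\tis_direct_target\tis_indirect_target\teffect_fold\t"
            "motif_offsets\tphase_radians\n"
        )
        for record in sorted(truth, key=lambda t: t.gene_id):
            offsets = ",".join(str(o) for o in record.motif_offsets)
            phase = "" if math.isnan(record.phase_radians) else f"{record.phase_radians:.10f}"
            handle.write(
                f"{record.gene_id}\t{record.is_direct_target}\t"
                f"{record.is_indirect_target}\t{record.effect_fold:.6g}\t"
                f"{offsets}\t{phase}\n"
            )


def read_truth_table(path: str | Path) -> list[SyntheticTruth]:
    truth = []
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            gene, is_d, is_i, fold, offsets, phase = line.rstrip("\n").split("\t")
            truth.append(
                SyntheticTruth(
                    gene_id=gene,
                    is_direct_target=is_d == "True",
                    is_indirect_target=is_i == "True",
                    effect_fold=float(fold),
                    motif_offsets=[int(o) for o in offsets.split(",") if o],
                    phase_radians=float(phase) if phase else float("nan"),
                )
            )
    return truth
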