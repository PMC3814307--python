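"""End-to-end orchestration: quantify -> call -> scan -> partition ->
consensus -> enrich, with the oscillation screen run alongside when cycle
profiles are supplied.

A single YAML config drives the run; one seed fans out deterministically to
any stage that draws random numbers.  Identical config + seed produce
byte-identical output files (floats are written with fixed formats and the
manifest carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .classify import (
    POST_DS_TIMEPOINTS,
    call_regulated,
    partition_targets,
    timepoint_tables,
)
from .enrich import enrich_gene_sets
from .io_formats import (
    parse_fasta,
    parse_gff3_gene_models,
    read_annotation_map,
    read_count_matrix,
    read_profile_table,
    write_target_table,
)
from .motif_scan import build_consensus_matrix, extract_promoter_window, scan_promoters
from .oscillation_screen import rank_by_correlation, reference_profile
from .quantify import (
    compute_log2_ratios,
    compute_mrpkbme,
    estimate_size_factors,
    log2_ratios_from_expression,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = logging.getLogger("qrepress")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Paths, parameters and toggles for a full run.

    Either ``promoters`` (a FASTA of promoter windows in promoter-strand
    orientation) or ``genome`` + ``gene_models`` (windows are then extracted
    upstream of each translational start) must be given.
    """

    counts: str
    promoters: str | None = None
    genome: str | None = None
    gene_models: str | None = None
    profiles: str | None = None
    annotation: str | None = None

    motif: str = "CTCGAR"
    window: int = 800
    threshold_fold: float = 3.0
    post_ds_timepoints: tuple[str, ...] = POST_DS_TIMEPOINTS
    pseudocount: float = 0.5
    k: int = 100
    screen_seed_genes: tuple[str, ...] = ()
    correction: str = "bonferroni"
    mutant_strain: str = "xbp1"
    wildtype_strain: str = "wt"
    seed: int = 0

    both_strands: bool = True
    first_called_only: bool = False
    ratio_mode: str = "ratio_of_means"
    ratio_basis: str = "size_factors"  # or "mrpkbme"

    def __post_init__(self) -> None:
        self.post_ds_timepoints = tuple(str(t) for t in self.post_ds_timepoints)
        self.screen_seed_genes = tuple(self.screen_seed_genes)
        if self.threshold_fold <= 1:
            raise ValueError(
                f"threshold_fold must be > 1, got {self.threshold_fold}"
            )
        if self.window < 6:
            raise ValueError(f"window must be >= 6, got {self.window}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.ratio_basis not in ("size_factors", "mrpkbme"):
            raise ValueError(f"unknown ratio basis {self.ratio_basis!r}")
        if self.ratio_mode not in ("ratio_of_means", "mean_of_ratios"):
            raise ValueError(f"unknown ratio mode {self.ratio_mode!r}")
        if self.correction not in ("bonferroni", "bh", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.promoters is None and (self.genome is None or self.gene_models is None):
            raise ValueError(
                "either 'promoters' or both 'genome' and 'gene_models' must be set"
            )
        if self.ratio_basis == "mrpkbme" and self.gene_models is None:
            raise ValueError("MRPKBME normalization requires gene_models")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["post_ds_timepoints"] = list(self.post_ds_timepoints)
        d["screen_seed_genes"] = list(self.screen_seed_genes)
        return d

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def check_paths(self) -> None:
        for name in ("counts", "promoters", "genome", "gene_models", "profiles", "annotation"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {value}")


def _stage(name: str):
    """Context manager that re-raises stage failures with the stage name."""
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Stage()


def run_all(config: PipelineConfig, outdir: str | Path, force: bool = False) -> dict[str, Any]:
    """Run the full analysis and write the results bundle into ``outdir``.

    Returns a dict with the in-memory results (target calls, summary,
    consensus matrix, screen result, enrichment list, manifest).
    """
    config.check_paths()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise PipelineError(
            f"output directory {outdir} is not empty; pass force=True/--force to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("quantify"):
        counts = read_count_matrix(config.counts)
        if config.ratio_basis == "size_factors":
            factors = estimate_size_factors(counts)
            ratios = compute_log2_ratios(
                counts, factors,
                pseudocount=config.pseudocount,
                mutant=config.mutant_strain, wildtype=config.wildtype_strain,
                ratio_mode=config.ratio_mode,
            )
        else:
            models = parse_gff3_gene_models(config.gene_models)
            expr = compute_mrpkbme(counts, models)
            ratios = log2_ratios_from_expression(
                expr,
                pseudocount=config.pseudocount,
                mutant=config.mutant_strain, wildtype=config.wildtype_strain,
                ratio_mode=config.ratio_mode,
            )

    with _stage("promoters"):
        if config.promoters is not None:
            promoters = parse_fasta(config.promoters)
        else:
            genome = parse_fasta(config.genome)
            models = parse_gff3_gene_models(config.gene_models)
            promoters = {
                gene_id: extract_promoter_window(m, genome, config.window).sequence
                for gene_id, m in models.items()
            }

    with _stage("scan"):
        hits_by_gene = scan_promoters(promoters, config.motif, config.both_strands)
        motif_genes = {g for g, hits in hits_by_gene.items() if hits}

    with _stage("classify"):
        up = call_regulated(ratios, config.threshold_fold, config.post_ds_timepoints, "up")
        down = call_regulated(ratios, config.threshold_fold, config.post_ds_timepoints, "down")
        calls, summary = partition_targets(
            ratios, up, down, motif_genes, set(promoters)
        )
        tables = timepoint_tables(
            calls, config.post_ds_timepoints, config.first_called_only
        )

    with _stage("consensus"):
        direct_genes = {c.gene_id for c in calls if c.cls == "direct"}
        direct_hits = [h for g in sorted(direct_genes) for h in hits_by_gene[g]]
        consensus = build_consensus_matrix(direct_hits) if direct_hits else None

    enrichment = None
    if config.annotation is not None:
        with _stage("enrich"):
            annotation = read_annotation_map(config.annotation)
            universe = set(counts.gene_ids)
            annotation = {
                cat: genes & universe
                for cat, genes in annotation.items()
                if genes & universe
            }
            derepressed = {c.gene_id for c in calls if c.cls != "none"}
            enrichment = enrich_gene_sets(
                derepressed & universe, annotation, universe, config.correction
            )

    screen = None
    if config.profiles is not None:
        with _stage("screen"):
            profiles = read_profile_table(config.profiles)
            if not config.screen_seed_genes:
                raise ValueError("screen_seed_genes must be set when profiles are given")
            reference = reference_profile(profiles, list(config.screen_seed_genes))
            screen = rank_by_correlation(profiles, reference, config.k)

    with _stage("write"):
        manifest = _write_outputs(
            config, outdir, calls, summary, tables, consensus, enrichment, screen
        )

    return {
        "calls": calls,
        "summary": summary,
        "timepoint_tables": tables,
        "consensus": consensus,
        "enrichment": enrichment,
        "screen": screen,
        "manifest": manifest,
    }


def _param_comments(config: PipelineConfig) -> list[str]:
    return [
        f"motif = {config.motif}",
        f"window = {config.window}",
        f"threshold_fold = {config.threshold_fold:g}",
        f"post_ds_timepoints = {','.join(config.post_ds_timepoints)}",
        f"pseudocount = {config.pseudocount:g}",
        f"both_strands = {config.both_strands}",
        f"ratio_basis = {config.ratio_basis}",
        f"seed = {config.seed}",
    ]


def _write_outputs(config, outdir, calls, summary, tables, consensus, enrichment, screen):
    comments = _param_comments(config)
    timepoints = list(calls[0].log2_ratio) if calls else []
    write_target_table(calls, timepoints, outdir / "targets.tsv", comments)
    outputs = ["targets.tsv"]

    for tp, frame in tables.items():
        name = f"timepoint_{tp}.tsv"
        with open(outdir / name, "w") as handle:
            for comment in comments:
                handle.write(f"# {comment}\n")
            handle.write("gene_id\tdirection\thas_motif\tclass\n")
            for _, row in frame.iterrows():
                flag = "TRUE" if row["has_motif"] else "FALSE"
                handle.write(f"{row['gene_id']}\t{row['direction']}\t{flag}\t{row['class']}\n")
        outputs.append(name)

    if consensus is not None:
        (outdir / "consensus.tsv").write_text(consensus.to_text())
        outputs.append("consensus.tsv")

    if enrichment is not None:
        with open(outdir / "enrichment.tsv", "w") as handle:
            for comment in comments:
                handle.write(f"# {comment}\n")
            handle.write("category\tk\tK\tn\tN\tp_raw\tp_corrected\n")
            for r in enrichment:
                handle.write(
                    f"{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                    f"{r.p_raw:.6g}\t{r.p_corrected:.6g}\n"
                )
        outputs.append("enrichment.tsv")

    if screen is not None:
        with open(outdir / "screen.tsv", "w") as handle:
            for comment in comments:
                handle.write(f"# {comment}\n")
            handle.write(f"# k = {screen.k}\n")
            handle.write("rank\tgene_id\tpearson_r\n")
            for rank, (gene, r) in enumerate(screen.ranked, 1):
                handle.write(f"{rank}\t{gene}\t{r:.6f}\n")
        outputs.append("screen.tsv")

    manifest = {
        "package": "qrepress",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "outputs": sorted(outputs),
        "summary": {
            "n_genes": summary.n_genes,
            "n_derepressed": summary.n_derepressed,
            "n_direct": summary.n_direct,
            "n_indirect": summary.n_indirect,
            "n_underrepresented": summary.n_underrepresented,
            "fraction_direct": round(summary.fraction_direct, 6),
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
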