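import numpy as np
import pytest
import yaml

from qrepress import SimulationConfig, generate_promoter_set
from qrepress.io_formats import CountMatrix, SampleTag


def make_counts(rows, samples):
    """Build a CountMatrix from {gene: [counts...]} and sample label strings."""
    tags = [SampleTag(*label.split("_")) for label in samples]
    genes = list(rows)
    counts = np.array([rows[g] for g in genes], dtype=np.int64)
    return CountMatrix(genes, tags, counts)


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study reused by several module tests."""
    config = SimulationConfig(
        n_genes=120, n_direct=20, n_indirect=10, seed=13, promoter_length=300
    )
    promoters, models, truth = generate_promoter_set(config)
    return config, promoters, models, truth


def build_fixture_study(root, seed=5):
    """Write the 200-gene regression fixture inputs under ``root/sim`` and
    return the path of a pipeline YAML config using paths relative to
    ``root``.  Deterministic in ``seed``."""
    from qrepress.io_formats import (
        write_annotation_map,
        write_count_matrix,
        write_fasta,
        write_gff3_gene_models,
        write_profile_table,
    )
    from qrepress.synthetic_data import (
        direct_ids,
        simulate_annotation,
        simulate_counts,
        simulate_ymc_profiles,
        write_truth_table,
    )

    sim = root / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(n_genes=200, n_direct=30, n_indirect=15, seed=seed)
    promoters, models, truth = generate_promoter_set(config)
    counts = simulate_counts(config, truth)
    profiles = simulate_ymc_profiles(len(truth), 36, 0.3, truth, config.seed)
    annotation = simulate_annotation(truth, config.seed)

    write_fasta(promoters, sim / "promoters.fa")
    write_gff3_gene_models(models, sim / "genes.gff3")
    write_count_matrix(counts, sim / "counts.tsv")
    write_profile_table(profiles, sim / "profiles.tsv")
    write_annotation_map(annotation, sim / "annotation.tsv")
    write_truth_table(truth, sim / "truth.tsv")

    pipeline_cfg = {
        "counts": "sim/counts.tsv",
        "promoters": "sim/promoters.fa",
        "profiles": "sim/profiles.tsv",
        "annotation": "sim/annotation.tsv",
        "screen_seed_genes": sorted(direct_ids(truth))[:3],
        "seed": seed,
    }
    cfg_path = root / "pipeline.yaml"
    with open(cfg_path, "w") as handle:
        yaml.safe_dump(pipeline_cfg, handle)
    return cfg_path, truth
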