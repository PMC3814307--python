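import numpy as np
import pytest

from qrepress.io_formats import write_fasta
from qrepress.motif_scan import scan_promoters
from qrepress.synthetic_data import (
    SimulationConfig,
    SyntheticTruth,
    direct_ids,
    generate_promoter_set,
    indirect_ids,
    read_truth_table,
    simulate_annotation,
    simulate_counts,
    simulate_ymc_profiles,
    write_truth_table,
)


class TestConfigValidation:
    def test_too_many_targets_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SimulationConfig(n_genes=10, n_direct=8, n_indirect=5)

    def test_promoter_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError, match="promoter_length"):
            SimulationConfig(n_genes=10, n_direct=0, n_indirect=0, promoter_length=5)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError, match="effect_fold"):
            SimulationConfig(n_genes=10, n_direct=1, n_indirect=0, effect_fold=-1)

    def test_direct_and_indirect_flags_exclusive(self):
        with pytest.raises(ValueError, match="exclusive"):
            SyntheticTruth("g1", is_direct_target=True, is_indirect_target=True)


class TestPromoterSet:
    def test_no_direct_targets_means_no_hits_anywhere(self):
        config = SimulationConfig(n_genes=40, n_direct=0, n_indirect=5,
                                  seed=1, promoter_length=200)
        promoters, _, _ = generate_promoter_set(config)
        hits = scan_promoters(promoters)
        assert all(not h for h in hits.values())

    def test_seeded_determinism_gives_identical_fasta(self, tmp_path):
        config = SimulationConfig(n_genes=50, n_direct=10, n_indirect=0, seed=1,
                                  promoter_length=150)
        a, _, _ = generate_promoter_set(config)
        b, _, _ = generate_promoter_set(config)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(a, pa)
        write_fasta(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_hit_bearing_genes_equal_planted_set(self):
        config = SimulationConfig(n_genes=500, n_direct=100, n_indirect=0, seed=7)
        promoters, _, truth = generate_promoter_set(config)
        hits = scan_promoters(promoters)
        assert {g for g, h in hits.items() if h} == direct_ids(truth)

    def test_direct_promoters_carry_exactly_one_site(self, small_study):
        _, promoters, _, truth = small_study
        hits = scan_promoters(promoters)
        for record in truth:
            if record.is_direct_target:
                assert len(hits[record.gene_id]) == 1
                assert hits[record.gene_id][0].offset == record.motif_offsets[0]
            else:
                assert record.motif_offsets == []

    def test_models_anchor_promoter_upstream_of_start(self, small_study):
        config, promoters, models, _ = small_study
        for gene, model in models.items():
            assert model.translational_start == config.promoter_length + 1
            assert len(promoters[gene]) == config.promoter_length


class TestCounts:
    def test_null_effect_unit_ratio_everywhere(self):
        config = SimulationConfig(n_genes=30, n_direct=5, n_indirect=0,
                                  effect_fold=1.0, dispersion=0.0,
                                  depth_range=(1.0, 1.0), seed=4,
                                  promoter_length=50)
        _, _, truth = generate_promoter_set(config)
        cm = simulate_counts(config, truth)
        n_tp = len(config.timepoints)
        wt = cm.counts[:, :n_tp]
        mut = cm.counts[:, n_tp:]
        regular = [i for i, g in enumerate(cm.gene_ids) if g != config.repressor_id]
        assert (wt[regular] == mut[regular]).all()

    def test_noise_free_effect_exact_fold(self):
        config = SimulationConfig(n_genes=30, n_direct=5, n_indirect=3,
                                  effect_fold=5.0, dispersion=0.0,
                                  depth_range=(1.0, 1.0), seed=4,
                                  promoter_length=50)
        _, _, truth = generate_promoter_set(config)
        cm = simulate_counts(config, truth)
        targets = direct_ids(truth) | indirect_ids(truth)
        post_ds = set(config.post_ds_timepoints)
        for i, gene in enumerate(cm.gene_ids):
            if gene == config.repressor_id:
                continue
            for j, tag in enumerate(cm.samples):
                wt_j = cm.samples.index(
                    type(tag)(config.wildtype_strain, tag.timepoint, tag.replicate)
                )
                ratio = cm.counts[i, j] / cm.counts[i, wt_j]
                if (tag.strain == config.mutant_strain and gene in targets
                        and tag.timepoint in post_ds):
                    assert ratio == 5.0
                else:
                    assert ratio == 1.0

    def test_repressor_induced_in_wt_absent_in_mutant(self):
        config = SimulationConfig(n_genes=20, n_direct=2, n_indirect=0,
                                  dispersion=0.0, depth_range=(1.0, 1.0),
                                  seed=4, promoter_length=50)
        _, _, truth = generate_promoter_set(config)
        cm = simulate_counts(config, truth)
        idx = cm.gene_ids.index(config.repressor_id)
        for j, tag in enumerate(cm.samples):
            count = cm.counts[idx, j]
            if tag.strain == config.mutant_strain:
                assert count == 0
            elif tag.timepoint == config.timepoints[0]:
                assert count == config.repressor_baseline
            else:
                assert count == config.repressor_baseline * config.repressor_induction_fold

    def test_seeded_determinism(self):
        config = SimulationConfig(n_genes=25, n_direct=5, n_indirect=0, seed=9,
                                  promoter_length=50)
        _, _, truth = generate_promoter_set(config)
        a = simulate_counts(config, truth)
        b = simulate_counts(config, truth)
        assert (a.counts == b.counts).all()

    def test_negative_binomial_moments(self):
        """Mean within 2% and variance within 5% of mu and mu + d mu^2."""
        reps = 50_000  # both strains draw at the same pre-DS mean -> 1e5 draws
        config = SimulationConfig(
            n_genes=1, n_direct=0, n_indirect=0, dispersion=0.05,
            depth_range=(1.0, 1.0), timepoints=("8",), post_ds_timepoints=(),
            replicates=reps, seed=21, promoter_length=50,
            baseline_range=(500.0, 500.0),
        )
        _, _, truth = generate_promoter_set(config)
        cm = simulate_counts(config, truth)
        draws = cm.counts[cm.gene_ids.index("g1"), :].astype(float)
        assert draws.size == 2 * reps
        mu = 500.0
        assert abs(draws.mean() - mu) / mu < 0.02
        expected_var = mu + 0.05 * mu**2
        assert abs(draws.var() - expected_var) / expected_var < 0.05


class TestProfilesAndAnnotation:
    def test_phase_assignment(self):
        config = SimulationConfig(n_genes=50, n_direct=10, n_indirect=5,
                                  seed=2, promoter_length=50)
        _, _, truth = generate_promoter_set(config)
        simulate_ymc_profiles(len(truth), 12, 0.0, truth, 2)
        for record in truth:
            if record.gene_id == config.repressor_id:
                assert record.phase_radians == 0.0
            elif record.is_direct_target or record.is_indirect_target:
                assert record.phase_radians == pytest.approx(np.pi)
            else:
                # guard band: non-targets stay away from exact anti-phase
                delta = abs((record.phase_radians - np.pi + np.pi) % (2 * np.pi) - np.pi)
                assert delta >= np.pi / 4 - 1e-12

    def test_too_few_timepoints_rejected(self):
        truth = [SyntheticTruth("g1")]
        with pytest.raises(ValueError, match="4 cycle"):
            simulate_ymc_profiles(1, 3, 0.1, truth, 0)

    def test_annotation_covers_all_genes(self):
        config = SimulationConfig(n_genes=40, n_direct=8, n_indirect=4,
                                  seed=3, promoter_length=50)
        _, _, truth = generate_promoter_set(config)
        annotation = simulate_annotation(truth, 3)
        annotated = set().union(*annotation.values())
        assert annotated == {t.gene_id for t in truth}
        assert "target_process" in annotation

    def test_truth_table_round_trip(self, tmp_path, small_study):
        _, _, _, truth = small_study
        path = tmp_path / "truth.tsv"
        write_truth_table(truth, path)
        back = read_truth_table(path)
        by_id = {t.gene_id: t for t in back}
        for record in truth:
            other = by_id[record.gene_id]
            assert other.is_direct_target == record.is_direct_target
            assert other.motif_offsets == record.motif_offsets
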