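"""Fold partitioning, training protocol, subsampling, fine-tuning."""

from dataclasses import replace

import numpy as np
import pytest

from diplonet.model import LossParams, ModelConfig, build_model
from diplonet.synthetic import SimConfig, simulate_panel
from diplonet.training import (
    TrainConfig,
    build_training_set,
    fine_tune,
    partition_folds,
    run_subsampling_experiment,
    subsample_panel,
    train_ensemble,
    train_model,
    train_reference_ablation,
    _dataset_loss,
)

# hg38 autosome lengths (GRCh38 assembly report)
HG38_AUTOSOMES = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559, "chr4": 190214555,
    "chr5": 181538259, "chr6": 170805979, "chr7": 159345973, "chr8": 145138636,
    "chr9": 138394717, "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189, "chr16": 90338345,
    "chr17": 83257441, "chr18": 80373285, "chr19": 58617616, "chr20": 64444167,
    "chr21": 46709983, "chr22": 50818468,
}


class TestPartitionFolds:
    def test_ten_equal_chromosomes_one_per_fold(self):
        lengths = {f"chr{i}": 1000 for i in range(10)}
        part = partition_folds(lengths, k=10, seed=0)
        assert sorted(part.assignment.values()) == list(range(10))

    def test_balance_property_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 31))
            lengths = {f"c{i}": int(rng.integers(50, 151)) for i in range(n)}
            part = partition_folds(lengths, k=10, seed=int(rng.integers(1000)))
            totals = np.zeros(10)
            for c, f in part.assignment.items():
                totals[f] += lengths[c]
            assert totals.max() / totals.min() <= 2.0

    def test_hg38_with_pinned_evaluation_fold(self):
        pinned = ["chr9", "chr13", "chr20", "chr21"]
        part = partition_folds(HG38_AUTOSOMES, k=10, seed=0, pinned_fold0=pinned)
        assert all(part.fold_of(c) == 0 for c in pinned)
        assert all(part.fold_of(c) != 0 for c in HG38_AUTOSOMES if c not in pinned)
        totals = np.zeros(10, dtype=np.int64)
        for c, f in part.assignment.items():
            totals[f] += HG38_AUTOSOMES[c]
        assert totals[1:].max() / totals[1:].min() <= 2.0

    def test_deterministic_under_seed(self):
        lengths = {f"c{i}": 100 for i in range(15)}
        assert partition_folds(lengths, k=10, seed=4).assignment == \
            partition_folds(lengths, k=10, seed=4).assignment

    def test_too_few_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            partition_folds({"chr1": 100}, k=10)

    def test_unknown_pinned_chromosome_rejected(self):
        lengths = {f"c{i}": 100 for i in range(12)}
        with pytest.raises(ValueError, match="not present"):
            partition_folds(lengths, k=10, pinned_fold0=["chrX"])


@pytest.fixture(scope="module")
def dup_panel():
    """4 donors, 2 extra isogenic replicate libraries (6 libraries)."""
    return simulate_panel(SimConfig(genome_length=4000, n_chromosomes=2,
                                    n_individuals=4, n_elements=2, n_snps=30,
                                    n_isogenic_duplicates=2, seed=5))


class TestSubsamplePanel:
    def test_never_two_replicates_of_one_donor(self, dup_panel):
        for s in range(300):
            sub = subsample_panel(dup_panel, 2, np.random.default_rng(s))
            assert len(set(sub.donors)) == 2

    def test_all_donors_when_n_equals_distinct(self, dup_panel):
        sub = subsample_panel(dup_panel, 4, np.random.default_rng(0))
        assert sorted(set(sub.donors)) == sorted(set(dup_panel.donors))
        assert len(sub.libraries) == 4

    def test_uniform_donor_selection(self, dup_panel):
        counts = {d: 0 for d in set(dup_panel.donors)}
        n_draws = 10_000
        rng = np.random.default_rng(0)
        for _ in range(n_draws):
            for d in set(subsample_panel(dup_panel, 2, rng).donors):
                counts[d] += 1
        for d, c in counts.items():
            assert c / n_draws == pytest.approx(2 / 4, abs=0.02), d

    def test_too_many_requested_rejected(self, dup_panel):
        with pytest.raises(ValueError, match="distinct donors"):
            subsample_panel(dup_panel, 5)

    def test_subset_is_consistent(self, dup_panel):
        sub = subsample_panel(dup_panel, 3, np.random.default_rng(1))
        for i, lib in enumerate(sub.libraries):
            orig = dup_panel.libraries.index(lib)
            assert np.array_equal(sub.genotypes[i], dup_panel.genotypes[orig])
            assert lib in sub.coverage


class TestTrainModel:
    def test_early_stopping_restores_best_weights(self, tiny_panel,
                                                  tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        ds = build_training_set(panel, part, tiny_model_config, jitter_max=0, seed=0)
        model = build_model(tiny_model_config, seed=0)
        loss_params = LossParams(lam=2.0)
        tr = ds.subset((ds.fold != 1) & (ds.fold != 0))
        va = ds.subset(ds.fold == 1)
        log = train_model(model, tr, va,
                          TrainConfig(max_epochs=6, patience=2, batch_size=64,
                                      learning_rate=0.01),
                          loss_params)
        restored_val = _dataset_loss(model, va, loss_params)
        assert restored_val == pytest.approx(log.best_val_loss, abs=1e-6)
        assert log.best_epoch <= len(log.epochs)

    def test_validation_improves_over_first_epoch(self, tiny_panel,
                                                  tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        for seed in (0, 1, 2):
            ds = build_training_set(panel, part, tiny_model_config, jitter_max=0,
                                    seed=seed)
            model = build_model(tiny_model_config, seed=seed)
            log = train_model(model, ds.subset((ds.fold != 1) & (ds.fold != 0)),
                              ds.subset(ds.fold == 1),
                              TrainConfig(max_epochs=5, patience=5, batch_size=64,
                                          learning_rate=0.005, seed=seed),
                              LossParams(lam=2.0))
            assert log.best_val_loss <= log.epochs[0]["val_loss"], f"seed {seed}"

    def test_empty_validation_rejected(self, tiny_panel, tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0)
        ds = build_training_set(panel, part, tiny_model_config, jitter_max=0, seed=0)
        model = build_model(tiny_model_config, seed=0)
        with pytest.raises(ValueError, match="validation"):
            train_model(model, ds, ds.subset(np.zeros(len(ds), bool)),
                        TrainConfig(max_epochs=1))


class TestTrainEnsemble:
    def test_fold_hygiene(self, tiny_ensemble_world):
        world = tiny_ensemble_world
        ensemble = world["ensemble"]
        assert sorted(ensemble.holdout_folds) == list(range(1, 10))
        for fold, log in ensemble.logs.items():
            assert fold not in log.train_folds
            assert 0 not in log.train_folds  # fold 0 never contributes gradients
            assert log.val_folds == (fold,)

    def test_fold0_elements_absent_from_training_logs(self, tiny_ensemble_world):
        world = tiny_ensemble_world
        fold0_elements = set(
            world["panel"].elements[
                [world["partition"].fold_of(c) == 0
                 for c in world["panel"].elements.chrom]].element_id)
        for log in world["ensemble"].logs.values():
            assert not fold0_elements & set(log.train_elements)

    def test_ensemble_prediction_is_mean_of_replicates(self, tiny_ensemble_world,
                                                       rng):
        world = tiny_ensemble_world
        ensemble = world["ensemble"]
        x = rng.integers(0, 3, (3, world["model_config"].input_length, 4)) \
            .astype(np.float32)
        profile, quantity = ensemble.forward(x)
        norm_profiles, quantities = [], []
        for m in ensemble.replicates.values():
            p, q = m.forward(x, train=False)
            tot = p.sum(axis=1, keepdims=True)
            norm_profiles.append(np.where(tot > 0, p / tot, 1.0 / p.shape[1]))
            quantities.append(q)
        assert np.allclose(profile, np.mean(norm_profiles, axis=0), atol=1e-6)
        assert np.allclose(quantity, np.mean(quantities, axis=0), atol=1e-6)

    def test_empty_validation_fold_rejected(self, tiny_panel, tiny_model_config):
        from diplonet.training import FoldPartition
        panel = tiny_panel
        # assign every chromosome to folds 0/1 -> folds 2..9 empty
        assignment = {c: (0 if i < 2 else 1)
                      for i, c in enumerate(panel.chrom_lengths)}
        part = FoldPartition(assignment=assignment, k=10)
        ds = build_training_set(panel, part, tiny_model_config, jitter_max=0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_ensemble(ds, part, tiny_model_config,
                           TrainConfig(max_epochs=1), LossParams())


class TestReferenceAblation:
    def test_masked_inputs_have_no_heterozygous_entries(self, tiny_panel,
                                                        tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        ds = build_training_set(panel, part, tiny_model_config, jitter_max=0,
                                masked=True, seed=0)
        assert (ds.X.sum(axis=2) == 2).all()
        assert not (ds.X == 1).any()

    def test_zero_snp_panel_masked_equals_personalized(self):
        cfg = SimConfig(genome_length=4000, n_chromosomes=10, n_individuals=3,
                        n_elements=10, n_snps=1, maf_range=(0.01, 0.01),
                        causal_fraction=0.0, seed=3)
        panel = simulate_panel(cfg)
        panel.genotypes[:] = 0  # force all-reference genotypes
        from diplonet.training import partition_folds as pf
        part = pf(panel.chrom_lengths, k=10, seed=0)
        mc = ModelConfig(input_length=200, output_length=100, scale_factor=0.125,
                         tower_layers=3)
        personalized = build_training_set(panel, part, mc, jitter_max=0, seed=0)
        masked = build_training_set(panel, part, mc, jitter_max=0, masked=True,
                                    seed=0, label_scale=personalized.label_scale)
        assert np.array_equal(personalized.X, masked.X)
        assert np.array_equal(personalized.Y, masked.Y)

    def test_labels_unchanged_by_masking(self, tiny_panel, tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        personalized = build_training_set(panel, part, tiny_model_config,
                                          jitter_max=0, seed=0)
        masked = build_training_set(panel, part, tiny_model_config, jitter_max=0,
                                    masked=True, seed=0,
                                    label_scale=personalized.label_scale)
        assert np.array_equal(personalized.Y, masked.Y)


class TestFineTune:
    @pytest.fixture(scope="class")
    def pretrained(self, tiny_panel, tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        ds = build_training_set(panel, part, tiny_model_config, jitter_max=0, seed=0)
        model = build_model(tiny_model_config, seed=0)
        tr = ds.subset((ds.fold != 1) & (ds.fold != 0))
        va = ds.subset(ds.fold == 1)
        train_model(model, tr, va,
                    TrainConfig(max_epochs=6, patience=6, batch_size=64,
                                learning_rate=0.005),
                    LossParams(lam=2.0))
        return {"model": model, "train": tr, "val": va, "partition": part}

    def test_warmup_epoch_logged_once(self, pretrained):
        tuned, log = fine_tune(pretrained["model"], pretrained["train"],
                               pretrained["val"],
                               TrainConfig(max_epochs=3, patience=3, batch_size=64),
                               loss_params=LossParams(lam=2.0))
        lrs = [e["lr"] for e in log.epochs]
        assert lrs.count(0.0001) == 1 and lrs[0] == 0.0001
        assert all(lr == 0.001 for lr in lrs[1:])

    def test_fine_tuning_on_same_data_is_stable(self, pretrained):
        loss_params = LossParams(lam=2.0)
        before = _dataset_loss(pretrained["model"], pretrained["val"], loss_params)
        tuned, log = fine_tune(pretrained["model"], pretrained["train"],
                               pretrained["val"],
                               TrainConfig(max_epochs=3, patience=3, batch_size=64),
                               loss_params=loss_params)
        after = _dataset_loss(tuned, pretrained["val"], loss_params)
        assert after <= before + 0.05 * abs(before)

    def test_input_model_untouched(self, pretrained):
        before = {k: v.copy() for k, v in pretrained["model"].state_dict().items()}
        fine_tune(pretrained["model"], pretrained["train"], pretrained["val"],
                  TrainConfig(max_epochs=1, patience=1, batch_size=64),
                  loss_params=LossParams(lam=2.0))
        after = pretrained["model"].state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_transfer_beats_frozen_model_on_shifted_panel(self, pretrained,
                                                          tiny_model_config):
        """Fine-tuning to a shifted 'cell type' (new seed, different rates)
        improves validation loss over the frozen pretrained model."""
        wins = 0
        for seed in (31, 32, 33):
            shifted = simulate_panel(SimConfig(
                genome_length=8000, n_chromosomes=12, n_individuals=6,
                n_elements=36, n_snps=900, causal_fraction=0.4,
                effect_window=200, base_rate=700.0, base_logit=1.5, seed=seed))
            part = pretrained["partition"]
            ds = build_training_set(shifted, part, tiny_model_config,
                                    jitter_max=0, seed=seed)
            tr = ds.subset((ds.fold != 1) & (ds.fold != 0))
            va = ds.subset(ds.fold == 1)
            loss_params = LossParams(lam=2.0)
            frozen = _dataset_loss(pretrained["model"], va, loss_params)
            tuned, _ = fine_tune(pretrained["model"], tr, va,
                                 TrainConfig(max_epochs=8, patience=8, batch_size=32,
                                             learning_rate=0.01, seed=seed),
                                 loss_params=loss_params)
            tuned_loss = _dataset_loss(tuned, va, loss_params)
            if tuned_loss < frozen:
                wins += 1
        assert wins >= 2


class TestSubsamplingExperiment:
    def test_toy_run_produces_finite_metrics(self, tiny_panel, tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        table = run_subsampling_experiment(
            panel, part, tiny_model_config,
            TrainConfig(max_epochs=6, patience=6, batch_size=32,
                        learning_rate=0.01),
            LossParams(lam=2.0), n_values=(2,), runs_per_n=1, seed=0)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n == 2 and np.isfinite(row.profile_median_r)
        assert np.isfinite(row.quantity_r)

    def test_performance_improves_with_more_individuals(self):
        """Subsampling trend: models trained on 30 individuals beat models
        trained on 5 at cross-loci prediction (mean over 3 panel seeds)."""
        import pandas as pd
        tables = []
        for seed in (101, 102, 103):
            panel = simulate_panel(SimConfig(
                genome_length=18000, n_chromosomes=12, n_individuals=30,
                n_elements=96, n_snps=2400, causal_fraction=0.35,
                quantity_effect_sd=0.8, strength_log2_per_copy=1.6,
                directionality_effect_sd=1.0, direction_logit_per_copy=2.0,
                maf_range=(0.3, 0.5), effect_window=200, seed=seed))
            part = partition_folds(panel.chrom_lengths, k=10, seed=0,
                                   pinned_fold0=list(panel.chrom_lengths)[:2])
            config = ModelConfig(input_length=300, output_length=150,
                                 scale_factor=0.125, tower_layers=5)
            tables.append(run_subsampling_experiment(
                panel, part, config,
                TrainConfig(max_epochs=10, patience=10, batch_size=32,
                            learning_rate=0.005),
                LossParams(lam=2.0), n_values=(5, 30), runs_per_n=1,
                jitter_max=0, seed=seed))
        means = pd.concat(tables).groupby("n").mean()
        assert means.profile_median_r[30] > means.profile_median_r[5]
        assert means.quantity_r[30] > means.quantity_r[5]

    def test_seeds_recorded_for_rerun(self, tiny_panel, tiny_model_config):
        from diplonet.training import partition_folds as pf
        panel = tiny_panel
        part = pf(panel.chrom_lengths, k=10, seed=0,
                  pinned_fold0=list(panel.chrom_lengths)[:2])
        kwargs = dict(n_values=(2, 3), runs_per_n=1, seed=9)
        t1 = run_subsampling_experiment(panel, part, tiny_model_config,
                                        TrainConfig(max_epochs=1, patience=1,
                                                    batch_size=64),
                                        LossParams(lam=2.0), **kwargs)
        t2 = run_subsampling_experiment(panel, part, tiny_model_config,
                                        TrainConfig(max_epochs=1, patience=1,
                                                    batch_size=64),
                                        LossParams(lam=2.0), **kwargs)
        assert t1.seed.tolist() == t2.seed.tolist()
        assert np.allclose(t1.profile_median_r, t2.profile_median_r)
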