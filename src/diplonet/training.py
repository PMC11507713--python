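"""Chromosome-fold partitioning, dataset materialization and training.

Training follows a leave-one-out fold scheme: the genome is split along
chromosome boundaries into ``k`` roughly equally sized folds, fold 0 is
reserved for final evaluation and never contributes a gradient, and one
replicate model is trained per remaining fold with that fold as its early
stopping validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import GenomicWindow, extract_window
from .model import (
    LossParams,
    ModelConfig,
    ProfileQuantityCNN,
    ProfileQuantityPrediction,
    build_model,
    multiscale_loss_batch,
    output_slice,
)
from .nn import Adam, clip_global_norm

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPartition",
    "TrainConfig",
    "TrainingSet",
    "TrainLog",
    "EnsembleModel",
    "partition_folds",
    "build_training_set",
    "encode_panel_window",
    "train_model",
    "train_ensemble",
    "subsample_panel",
    "run_subsampling_experiment",
    "train_reference_ablation",
    "fine_tune",
    "predict_batched",
]


# ---------------------------------------------------------------------------
# fold partitioning

@dataclass(frozen=True)
class FoldPartition:
    assignment: dict[str, int]
    k: int
    holdout_fold: int = 0

    def fold_of(self, chrom: str) -> int:
        if chrom not in self.assignment:
            raise KeyError(f"chromosome {chrom!r} not assigned to any fold")
        return self.assignment[chrom]

    def chromosomes(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]


def partition_folds(chrom_lengths: dict[str, int], k: int = 10, seed: int = 0,
                    pinned_fold0: list[str] | None = None) -> FoldPartition:
    """Greedy longest-first bin packing of chromosomes into ``k`` folds.

    Ties between equal-length chromosomes are broken by a seeded shuffle;
    ``pinned_fold0`` forces the listed chromosomes into the evaluation fold
    (fold 0), with the rest packed into folds 1..k-1.
    """
    if len(chrom_lengths) < k:
        raise ValueError(f"need at least {k} chromosomes for {k} folds, "
                         f"got {len(chrom_lengths)}")
    rng = np.random.default_rng(seed)
    names = list(chrom_lengths)
    rng.shuffle(names)
    names.sort(key=lambda c: -chrom_lengths[c])
    assignment: dict[str, int] = {}
    totals = np.zeros(k, dtype=np.int64)
    candidates = list(range(k))
    if pinned_fold0 is not None:
        missing = set(pinned_fold0) - set(names)
        if missing:
            raise ValueError(f"pinned chromosomes not present: {sorted(missing)}")
        for c in pinned_fold0:
            assignment[c] = 0
            totals[0] += chrom_lengths[c]
        names = [c for c in names if c not in assignment]
        candidates = list(range(1, k))
    for c in names:
        fold = min(candidates, key=lambda f: (totals[f], f))
        assignment[c] = fold
        totals[fold] += chrom_lengths[c]
    return FoldPartition(assignment=assignment, k=k)


# ---------------------------------------------------------------------------
# dataset materialization

@dataclass
class TrainingSet:
    X: np.ndarray          # (n, input_length, 4) uint8 two-hot
    Y: np.ndarray          # (n, 2*output_length) float32 scaled RPM coverage
    fold: np.ndarray       # (n,) fold of origin
    element_id: np.ndarray
    library: np.ndarray
    label_scale: float

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(self.X[mask], self.Y[mask], self.fold[mask],
                           self.element_id[mask], self.library[mask], self.label_scale)


def _reference_onehot(seq: str) -> np.ndarray:
    lut = np.zeros((256, 4), dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b), i] = 1
        lut[ord(b.lower()), i] = 1
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    return lut[codes]


def encode_panel_window(panel, window: GenomicWindow, library: str | None = None,
                        masked: bool = False,
                        onehot_cache: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Two-hot encode a window of a simulated panel.

    With ``masked=True`` (or no library) all variants are ignored and the
    window encodes as homozygous reference.
    """
    if onehot_cache is not None:
        if window.chrom not in onehot_cache:
            onehot_cache[window.chrom] = _reference_onehot(panel.reference[window.chrom])
        ref_oh = onehot_cache[window.chrom][window.start:window.end]
    else:
        ref_oh = _reference_onehot(panel.reference[window.chrom][window.start:window.end])
    x = (2 * ref_oh).astype(np.int16)
    if masked or library is None:
        return x.astype(np.uint8)
    li = panel.libraries.index(library)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for snp in panel.snps_in_window(window).itertuples():
        dos = int(panel.genotypes[li, snp.Index])
        if dos == 0:
            continue
        rel = snp.pos - window.start
        x[rel, base_idx[snp.ref]] -= dos
        x[rel, base_idx[snp.alt]] += dos
    if (x < 0).any():
        raise ValueError("inconsistent genotype: negative allele count")
    return x.astype(np.uint8)


def build_training_set(panel, partition: FoldPartition, model_config: ModelConfig,
                       jitter_max: int = 250, masked: bool = False,
                       label_scale: float | None = None, seed: int = 0,
                       libraries: list[str] | None = None) -> TrainingSet:
    """Materialize (window, track) training examples for every
    (element, library) pair.

    Windows are jittered once at materialization. Labels are RPM-scaled
    per-library coverage over the central output window (plus strand then
    minus strand), multiplied by ``label_scale``. When ``label_scale`` is
    None it is chosen so the median window total is 1.0, which keeps the
    quantity head in a trainable numeric range; metrics downstream are
    invariant to this choice.
    """
    rng = np.random.default_rng(seed)
    libraries = list(libraries or panel.libraries)
    rpm = {lib: 1e6 / panel.library_totals(lib) for lib in libraries}
    out_sl = output_slice(model_config)
    W = model_config.input_length
    cache: dict[str, np.ndarray] = {}
    xs, ys, folds, eids, libs = [], [], [], [], []
    chrom_lengths = panel.chrom_lengths
    for elem in panel.elements.itertuples():
        fold = partition.fold_of(elem.chrom)
        for lib in libraries:
            window = extract_window(elem.chrom, int(elem.center), chrom_lengths[elem.chrom],
                                    width=W, jitter_max=jitter_max, rng=rng)
            xs.append(encode_panel_window(panel, window, library=lib, masked=masked,
                                          onehot_cache=cache))
            cov = panel.coverage_window(lib, window)
            ys.append(np.concatenate([cov.plus[out_sl], cov.minus[out_sl]]) * rpm[lib])
            folds.append(fold)
            eids.append(elem.element_id)
            libs.append(lib)
    X = np.stack(xs).astype(np.uint8)
    Y = np.stack(ys)
    if label_scale is None:
        med = float(np.median(Y.sum(axis=1)))
        label_scale = 1.0 / med if med > 0 else 1.0
    Y = (Y * label_scale).astype(np.float32)
    return TrainingSet(X, Y, np.asarray(folds), np.asarray(eids), np.asarray(libs),
                       label_scale)


# ---------------------------------------------------------------------------
# training

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    clip_norm: float = 10.0
    #: warmup epochs run at warmup_lr before switching to learning_rate
    warmup_epochs: int = 0
    warmup_lr: float = 0.0001
    #: when > 0, halve the learning rate every lr_step epochs (after warmup)
    lr_step: int = 0
    #: initialize the quantity head offset from the label mean
    init_output_stats: bool = True

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    train_folds: tuple[int, ...] = ()
    val_folds: tuple[int, ...] = ()
    train_elements: tuple[str, ...] = ()


def predict_batched(model: ProfileQuantityCNN, X: np.ndarray, batch_size: int = 256
                    ) -> tuple[np.ndarray, np.ndarray]:
    profiles, quantities = [], []
    for i in range(0, X.shape[0], batch_size):
        p, q = model.forward(X[i:i + batch_size].astype(np.float32), train=False)
        profiles.append(p)
        quantities.append(q)
    return np.concatenate(profiles), np.concatenate(quantities)


def _dataset_loss(model: ProfileQuantityCNN, data: TrainingSet,
                  loss_params: LossParams, batch_size: int = 256) -> float:
    profile, quantity = predict_batched(model, data.X, batch_size)
    loss, _, _ = multiscale_loss_batch(data.Y, profile, quantity, loss_params)
    return loss


def train_model(model: ProfileQuantityCNN, train: TrainingSet, val: TrainingSet,
                config: TrainConfig = TrainConfig(),
                loss_params: LossParams = LossParams()) -> TrainLog:
    """Adam training with early stopping on validation loss; the weights of
    the best validation epoch are restored before returning."""
    if len(val) == 0:
        raise ValueError("validation set is empty")
    if len(train) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    if config.init_output_stats:
        # data-mean output initialization: puts the quantity head on the
        # label scale immediately instead of spending epochs drifting there
        model.quantity_bn.params["beta"][0] = float(train.Y.sum(axis=1).mean())
    opt = Adam(model.parameters(), lr=config.learning_rate)
    log = TrainLog(train_folds=tuple(sorted(set(train.fold.tolist()))),
                   val_folds=tuple(sorted(set(val.fold.tolist()))),
                   train_elements=tuple(sorted(set(train.element_id.tolist()))))
    # the starting weights are the epoch-0 candidate, so training (and in
    # particular fine-tuning a converged model) never ends worse than it
    # began on the monitored set
    log.best_val_loss = _dataset_loss(model, val, loss_params)
    log.best_epoch = 0
    best_state = model.state_dict()
    bad_epochs = 0
    n = len(train)
    for epoch in range(1, config.max_epochs + 1):
        if epoch <= config.warmup_epochs:
            lr = config.warmup_lr
        else:
            lr = config.learning_rate
            if config.lr_step > 0:
                lr *= 0.5 ** ((epoch - config.warmup_epochs - 1) // config.lr_step)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            x = train.X[idx].astype(np.float32)
            y = train.Y[idx]
            profile, quantity = model.forward(x, train=True)
            loss, dprof, dquant = multiscale_loss_batch(y, profile, quantity, loss_params)
            model.zero_grad()
            model.backward(dprof, dquant)
            grads = model.gradients()
            clip_global_norm(grads, config.clip_norm)
            opt.step(grads)
            epoch_loss += loss
            n_batches += 1
        val_loss = _dataset_loss(model, val, loss_params)
        log.epochs.append({"epoch": epoch, "lr": lr,
                           "train_loss": epoch_loss / max(1, n_batches),
                           "val_loss": val_loss})
        if val_loss < log.best_val_loss:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.load_state_dict(best_state)
    return log


# ---------------------------------------------------------------------------
# ensembling

class EnsembleModel:
    """Nine (or k-1) replicate models, each tagged with its holdout fold.

    The ensemble prediction is the mean of the replicate predictions:
    profiles are normalized to sum one per replicate before averaging and
    quantities are averaged directly.
    """

    def __init__(self, replicates: dict[int, ProfileQuantityCNN],
                 logs: dict[int, TrainLog] | None = None):
        if not replicates:
            raise ValueError("ensemble needs at least one replicate")
        self.replicates = dict(sorted(replicates.items()))
        self.logs = logs or {}

    @property
    def holdout_folds(self) -> list[int]:
        return list(self.replicates)

    @property
    def config(self) -> ModelConfig:
        return next(iter(self.replicates.values())).config

    def replicate(self, fold: int) -> ProfileQuantityCNN:
        return self.replicates[fold]

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        profiles, quantities = [], []
        for m in self.replicates.values():
            p, q = m.forward(x, train=False)
            tot = p.sum(axis=1, keepdims=True)
            profiles.append(np.divide(p, tot, out=np.full_like(p, 1.0 / p.shape[1]),
                                      where=tot > 0))
            quantities.append(q)
        return np.mean(profiles, axis=0), np.mean(quantities, axis=0)

    def predict(self, x: np.ndarray):
        single = x.ndim == 2
        batch = x[None] if single else x
        profile, quantity = self.forward(batch.astype(np.float32))
        preds = [ProfileQuantityPrediction(profile[i], float(quantity[i]))
                 for i in range(batch.shape[0])]
        return preds[0] if single else preds


def train_ensemble(dataset: TrainingSet, partition: FoldPartition,
                   model_config: ModelConfig, train_config: TrainConfig = TrainConfig(),
                   loss_params: LossParams = LossParams(), seed: int = 0,
                   folds: list[int] | None = None) -> EnsembleModel:
    """Leave-one-out replicate training over folds 1..k-1.

    Replicate ``i`` trains on all non-holdout folds except ``i`` and uses
    fold ``i`` for early stopping; fold 0 is never seen by any replicate.
    """
    train_folds = folds or [f for f in range(partition.k) if f != partition.holdout_fold]
    if (dataset.fold == partition.holdout_fold).all():
        raise ValueError("dataset contains only holdout-fold examples")
    replicates: dict[int, ProfileQuantityCNN] = {}
    logs: dict[int, TrainLog] = {}
    for i in train_folds:
        val_mask = dataset.fold == i
        train_mask = (dataset.fold != i) & (dataset.fold != partition.holdout_fold)
        if not val_mask.any():
            raise ValueError(f"validation fold {i} is empty")
        model = build_model(model_config, seed=seed + i)
        cfg = replace(train_config, seed=train_config.seed + i)
        logs[i] = train_model(model, dataset.subset(train_mask), dataset.subset(val_mask),
                              cfg, loss_params)
        replicates[i] = model
        logger.info("replicate holdout=%d best_val=%.4f epochs=%d",
                    i, logs[i].best_val_loss, len(logs[i].epochs))
    return EnsembleModel(replicates, logs)


# ---------------------------------------------------------------------------
# ablations and transfer

def subsample_panel(panel, n_individuals: int, rng: np.random.Generator | None = None):
    """Subsample ``n_individuals`` libraries from distinct donors, uniformly
    without replacement (never two isogenic replicates of one donor)."""
    rng = rng or np.random.default_rng()
    donors = sorted(set(panel.donors))
    if n_individuals > len(donors):
        raise ValueError(f"requested {n_individuals} individuals but only "
                         f"{len(donors)} distinct donors")
    chosen_donors = rng.choice(donors, size=n_individuals, replace=False)
    libs = []
    for d in chosen_donors:
        options = [lib for lib, dd in zip(panel.libraries, panel.donors) if dd == d]
        libs.append(options[int(rng.integers(len(options)))])
    idx = [panel.libraries.index(lib) for lib in libs]
    return replace(panel,
                    genotypes=panel.genotypes[idx, :],
                    libraries=[panel.libraries[i] for i in idx],
                    donors=[panel.donors[i] for i in idx],
                    coverage={panel.libraries[i]: panel.coverage[panel.libraries[i]]
                              for i in idx})


def train_reference_ablation(panel, partition: FoldPartition, model_config: ModelConfig,
                             train_config: TrainConfig = TrainConfig(),
                             loss_params: LossParams = LossParams(),
                             jitter_max: int = 250, label_scale: float | None = None,
                             seed: int = 0, val_fold: int = 1
                             ) -> tuple[ProfileQuantityCNN, TrainLog, TrainingSet]:
    """Identical training protocol with every input variant-masked
    (reference sequence); labels stay per-individual."""
    dataset = build_training_set(panel, partition, model_config, jitter_max=jitter_max,
                                 masked=True, label_scale=label_scale, seed=seed)
    model = build_model(model_config, seed=seed)
    log = train_model(model, dataset.subset((dataset.fold != val_fold)
                                            & (dataset.fold != partition.holdout_fold)),
                      dataset.subset(dataset.fold == val_fold), train_config, loss_params)
    return model, log, dataset


def fine_tune(model: ProfileQuantityCNN, train: TrainingSet, val: TrainingSet,
              config: TrainConfig = TrainConfig(), warmup_lr: float = 0.0001,
              warmup_epochs: int = 1, loss_params: LossParams = LossParams()
              ) -> tuple[ProfileQuantityCNN, TrainLog]:
    """All-weights fine-tuning with an initial warmup epoch at a reduced
    learning rate. Returns a tuned copy; the input model is untouched."""
    tuned = model.clone()
    cfg = replace(config, warmup_epochs=warmup_epochs, warmup_lr=warmup_lr,
                  init_output_stats=False)
    log = train_model(tuned, train, val, cfg, loss_params)
    return tuned, log


def run_subsampling_experiment(panel, partition: FoldPartition, model_config: ModelConfig,
                               train_config: TrainConfig = TrainConfig(),
                               loss_params: LossParams = LossParams(),
                               n_values=(5, 10, 15, 20, 30), runs_per_n: int = 5,
                               jitter_max: int = 0, seed: int = 0, val_fold: int = 1):
    """Subsample n individuals, train, and benchmark; repeated runs per n.

    Returns a DataFrame with one row per (n, run): cross-loci profile and
    quantity metrics plus QTL effect-score correlations, and the seeds
    needed to re-run each configuration. Models are trained on the
    subsample but always benchmarked against the full panel, so rows are
    comparable across n.
    """
    import pandas as pd

    from . import qtl as qtl_eval

    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        for run in range(runs_per_n):
            sub_seed = int(rng.integers(2 ** 31))
            sub = subsample_panel(panel, n, np.random.default_rng(sub_seed))
            dataset = build_training_set(sub, partition, model_config,
                                         jitter_max=jitter_max, seed=sub_seed)
            model = build_model(model_config, seed=sub_seed)
            cfg = replace(train_config, seed=sub_seed)
            train_model(model,
                        dataset.subset((dataset.fold != val_fold)
                                       & (dataset.fold != partition.holdout_fold)),
                        dataset.subset(dataset.fold == val_fold), cfg, loss_params)
            metrics = qtl_eval.benchmark_panel_model(panel, model, partition,
                                                     model_config,
                                                     eval_folds=(partition.holdout_fold,
                                                                 val_fold))
            rows.append({"n": n, "run": run, "seed": sub_seed,
                         "profile_median_r": metrics["profile_median_r"],
                         "quantity_r": metrics["quantity_r"],
                         "qtl_r": metrics["qtl_r"],
                         "tiqtl_r": metrics["tiqtl_r"],
                         "diqtl_r": metrics["diqtl_r"]})
    return pd.DataFrame(rows)
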