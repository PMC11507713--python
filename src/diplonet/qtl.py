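"""Initiation-QTL effect scoring and cross-loci prediction metrics.

The QTL effect score bins individuals by genotype at the lead SNP and
takes the L2 norm of the difference between the averaged homozygous
reference track and the averaged homozygous alternate track
(heterozygotes are excluded). Predicted effects apply the same score to
per-individual predicted tracks (profile normalized times quantity).

Holdout-aware compositing: QTLs on the fully withheld fold 0 are scored
with the whole replicate ensemble; QTLs on any other fold are scored only
with the replicate that held that fold out, so no QTL is ever scored by a
model trained on its chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import GenomicWindow, extract_window
from .model import ModelConfig, ProfileQuantityPrediction, output_slice, predicted_track
from .training import EnsembleModel, FoldPartition, encode_panel_window

logger = logging.getLogger(__name__)

__all__ = [
    "QTLRecord",
    "l2_effect",
    "qtls_from_panel",
    "observed_qtl_effect",
    "predicted_qtl_effect",
    "composite_prediction",
    "cross_loci_metrics",
    "qtl_benchmark",
    "benchmark_panel_model",
]

NO_EFFECT_DECIMALS = 8


@dataclass
class QTLRecord:
    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str                      # "tiQTL" or "diQTL"
    genotypes: dict[str, int]      # library -> alt-allele dosage
    window: GenomicWindow
    element_id: str | None = None

    def __post_init__(self) -> None:
        doses = list(self.genotypes.values())
        if 0 not in doses or 2 not in doses:
            raise ValueError(f"{self.snp_id}: need at least one homozygous-reference "
                             "and one homozygous-alternate individual")


def l2_effect(tracks_by_individual: dict[str, np.ndarray],
              genotypes: dict[str, int]) -> float:
    """L2 norm of (mean hom-ref track - mean hom-alt track)."""
    ref_tracks = [np.asarray(tracks_by_individual[k], dtype=np.float64)
                  for k, d in genotypes.items() if d == 0 and k in tracks_by_individual]
    alt_tracks = [np.asarray(tracks_by_individual[k], dtype=np.float64)
                  for k, d in genotypes.items() if d == 2 and k in tracks_by_individual]
    if not ref_tracks:
        raise ValueError("homozygous-reference bin is empty")
    if not alt_tracks:
        raise ValueError("homozygous-alternate bin is empty")
    lengths = {t.shape for t in ref_tracks + alt_tracks}
    if len(lengths) != 1:
        raise ValueError("all tracks must have the same length")
    # averaging relative to a common baseline keeps the score exactly zero
    # when every track is identical, regardless of bin sizes
    baseline = ref_tracks[0]
    diff = np.mean([t - baseline for t in ref_tracks], axis=0) \
        - np.mean([t - baseline for t in alt_tracks], axis=0)
    return float(np.linalg.norm(diff))


def qtls_from_panel(panel, input_length: int) -> list[QTLRecord]:
    """QTL records for every planted effect whose genotype bins are usable
    (at least one hom-ref and one hom-alt library) and whose window fits.

    Kind is tiQTL for quantity effects and diQTL for directionality
    effects; windows are centered on the element (jitter 0).
    """
    records = []
    elem_center = dict(zip(panel.elements.element_id, panel.elements.center))
    snp_rows = {sid: j for j, sid in enumerate(panel.snps.snp_id)}
    for eff in panel.truth.itertuples():
        j = snp_rows[eff.snp_id]
        snp = panel.snps.iloc[j]
        doses = panel.genotypes[:, j]
        if (doses == 0).sum() == 0 or (doses == 2).sum() == 0:
            continue
        center = int(elem_center[eff.element_id])
        try:
            window = extract_window(snp.chrom, center, panel.chrom_lengths[snp.chrom],
                                    width=input_length, jitter_max=0)
        except ValueError:
            continue
        kind = "tiQTL" if eff.quantity_log2fc != 0 else "diQTL"
        records.append(QTLRecord(snp_id=snp.snp_id, chrom=snp.chrom, pos=int(snp.pos),
                                 ref=snp.ref, alt=snp.alt, kind=kind,
                                 genotypes={lib: int(d) for lib, d
                                            in zip(panel.libraries, doses)},
                                 window=window, element_id=eff.element_id))
    return records


def observed_qtl_effect(panel, qtl: QTLRecord, model_config: ModelConfig) -> float:
    """L2 effect on observed RPM coverage over the central output window."""
    out_sl = output_slice(model_config)
    tracks = {}
    for lib in panel.libraries:
        rpm = 1e6 / panel.library_totals(lib)
        cov = panel.coverage_window(lib, qtl.window)
        tracks[lib] = np.concatenate([cov.plus[out_sl], cov.minus[out_sl]]) * rpm
    return l2_effect(tracks, qtl.genotypes)


def predicted_qtl_effect(model, qtl: QTLRecord, panel, masked: bool = False) -> float:
    """L2 effect on per-individual predicted tracks.

    ``model`` is a single network or an ensemble. With ``masked=True`` the
    inputs are variant-masked (all individuals identical), which forces a
    predicted effect of exactly zero; this is the evaluation mode of the
    reference-trained ablation.
    """
    encoded: dict[bytes, np.ndarray] = {}
    keys = {}
    for lib in qtl.genotypes:
        x = encode_panel_window(panel, qtl.window, library=lib, masked=masked)
        b = x.tobytes()
        encoded.setdefault(b, x)
        keys[lib] = b
    unique = list(encoded)
    batch = np.stack([encoded[b] for b in unique]).astype(np.float32)
    if isinstance(model, EnsembleModel):
        profiles, quantities = model.forward(batch)
    else:
        profiles, quantities = model.forward(batch, train=False)
    track_of = {b: predicted_track(ProfileQuantityPrediction(profiles[i],
                                                             float(quantities[i])))
                for i, b in enumerate(unique)}
    tracks = {lib: track_of[keys[lib]] for lib in qtl.genotypes}
    return l2_effect(tracks, qtl.genotypes)


def composite_prediction(ensemble: EnsembleModel, qtl: QTLRecord,
                         partition: FoldPartition):
    """Select the leakage-free prediction source for one QTL.

    Returns (model, source_tag): the full ensemble for fold-0 QTLs,
    otherwise the single replicate whose holdout fold contains the QTL.
    """
    fold = partition.fold_of(qtl.chrom)
    if fold == partition.holdout_fold:
        return ensemble, "ensemble"
    if fold not in ensemble.replicates:
        raise KeyError(f"no replicate holds out fold {fold}")
    return ensemble.replicate(fold), f"replicate:{fold}"


def cross_loci_metrics(predictions: np.ndarray, observations: np.ndarray,
                       pseudocount: float = 1e-6) -> dict:
    """Median per-locus Pearson r between predicted and observed tracks,
    plus the Pearson r of log10 total coverage across loci.

    Loci where either track is constant are excluded from the profile
    metric (with a logged count).
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    observations = np.asarray(observations, dtype=np.float64)
    if predictions.shape != observations.shape or predictions.shape[0] < 2:
        raise ValueError("need aligned predictions/observations for >= 2 loci")
    rs = []
    n_excluded = 0
    for p, o in zip(predictions, observations):
        if p.std() == 0 or o.std() == 0:
            n_excluded += 1
            continue
        rs.append(stats.pearsonr(p, o).statistic)
    if n_excluded:
        logger.warning("excluded %d loci with constant tracks from profile metric",
                       n_excluded)
    lq_pred = np.log10(predictions.sum(axis=1) + pseudocount)
    lq_obs = np.log10(observations.sum(axis=1) + pseudocount)
    quantity_r = stats.pearsonr(lq_pred, lq_obs).statistic
    return {"profile_median_r": float(np.median(rs)) if rs else float("nan"),
            "quantity_r": float(quantity_r),
            "n_loci": predictions.shape[0],
            "n_excluded": n_excluded}


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant effect-score vector; reporting r = 0 by convention")
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def qtl_benchmark(predicted_scores: dict[str, np.ndarray], observed_scores: np.ndarray,
                  kinds: np.ndarray | None = None) -> pd.DataFrame:
    """Per-model Pearson r between predicted and observed effect scores and
    the fraction of QTLs predicted as having no effect (score exactly zero
    after rounding to 1e-8). Constant prediction vectors get r = 0."""
    observed = np.asarray(observed_scores, dtype=np.float64)
    if observed.size < 2:
        raise ValueError("need at least 2 QTLs")
    rows = []
    for name, pred in predicted_scores.items():
        pred = np.asarray(pred, dtype=np.float64)
        if pred.shape != observed.shape:
            raise ValueError(f"{name}: score vector misaligned with observations")
        # flush sub-threshold scores (numerical noise) to an exact zero so
        # the no-effect fraction and the correlation see the same values
        pred = np.where(np.abs(pred) < 10.0 ** -NO_EFFECT_DECIMALS, 0.0, pred)
        groups = [("all", np.ones_like(observed, dtype=bool))]
        if kinds is not None:
            groups += [(k, np.asarray(kinds) == k) for k in sorted(set(kinds))]
        for kind, mask in groups:
            if mask.sum() < 2:
                continue
            no_effect = float(np.mean(np.round(pred[mask], NO_EFFECT_DECIMALS) == 0.0))
            rows.append({"model": name, "kind": kind, "n": int(mask.sum()),
                         "r": _safe_pearson(pred[mask], observed[mask]),
                         "no_effect_fraction": no_effect})
    return pd.DataFrame(rows)


def benchmark_panel_model(panel, model, partition: FoldPartition,
                          model_config: ModelConfig,
                          eval_folds: tuple[int, ...] = (0,),
                          masked_inputs: bool = False,
                          cross_loci_folds: tuple[int, ...] | None = None) -> dict:
    """Convenience benchmark of one model (or ensemble) on a panel.

    Cross-loci metrics use reference-sequence inputs and individual-averaged
    RPM coverage on ``cross_loci_folds`` (default: the holdout fold); QTL
    effect correlations use per-individual personalized inputs (or masked
    ones for the reference-evaluation mode) on ``eval_folds``.
    """
    out_sl = output_slice(model_config)
    chrom_lengths = panel.chrom_lengths
    rpm = {lib: 1e6 / panel.library_totals(lib) for lib in panel.libraries}

    if cross_loci_folds is None:
        cross_loci_folds = (partition.holdout_fold,)
    holdout = panel.elements[[partition.fold_of(c) in cross_loci_folds
                              for c in panel.elements.chrom]]
    obs_rows, windows = [], []
    for elem in holdout.itertuples():
        window = extract_window(elem.chrom, int(elem.center), chrom_lengths[elem.chrom],
                                width=model_config.input_length, jitter_max=0)
        windows.append(window)
        tracks = [np.concatenate([cov.plus[out_sl], cov.minus[out_sl]]) * rpm[lib]
                  for lib in panel.libraries
                  for cov in [panel.coverage_window(lib, window)]]
        obs_rows.append(np.mean(tracks, axis=0))
    X = np.stack([encode_panel_window(panel, w, masked=True) for w in windows]
                 ).astype(np.float32)
    if isinstance(model, EnsembleModel):
        profiles, quantities = model.forward(X)
    else:
        profiles, quantities = model.forward(X, train=False)
    pred_rows = [predicted_track(ProfileQuantityPrediction(profiles[i], float(quantities[i])))
                 for i in range(X.shape[0])]
    metrics = cross_loci_metrics(np.stack(pred_rows), np.stack(obs_rows))

    qtls = [q for q in qtls_from_panel(panel, model_config.input_length)
            if partition.fold_of(q.chrom) in eval_folds]
    out = {**metrics, "n_qtls": len(qtls), "tiqtl_r": float("nan"),
           "diqtl_r": float("nan"), "qtl_r": float("nan"),
           "no_effect_fraction": float("nan")}
    if len(qtls) >= 2:
        observed = np.array([observed_qtl_effect(panel, q, model_config) for q in qtls])
        predicted = np.array([predicted_qtl_effect(model, q, panel, masked=masked_inputs)
                              for q in qtls])
        kinds = np.array([q.kind for q in qtls])
        table = qtl_benchmark({"model": predicted}, observed, kinds)
        for _, row in table.iterrows():
            if row["kind"] == "all":
                out["qtl_r"] = row["r"]
                out["no_effect_fraction"] = row["no_effect_fraction"]
            elif row["kind"] == "tiQTL":
                out["tiqtl_r"] = row["r"]
            elif row["kind"] == "diQTL":
                out["diqtl_r"] = row["r"]
    return out
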