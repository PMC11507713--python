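"""Reporter-construct variant effect prediction and emVar benchmarking.

A 200 bp oligo is inserted directly upstream of a minimal TATA promoter in
a reporter backbone; the model scores each SNP as the log2 ratio of the
alternate over reference allele quantity predictions. Classification of
expression-modulating variants (emVars) uses the squared score as the
predictor of a precision-recall curve; model comparisons use bootstrap
resampling of the holdout SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve

from .encoding import two_hot_encode
from .training import EnsembleModel

logger = logging.getLogger(__name__)

__all__ = [
    "MPRAOligo",
    "ReporterConstruct",
    "MINIMAL_PROMOTER",
    "default_backbone",
    "assemble_construct",
    "predict_snp_effect",
    "emvar_prc",
    "bootstrap_delta_auprc",
    "effect_agreement",
]

OLIGO_LENGTH = 200

#: canonical TATA-box minimal promoter (synthetic stand-in; the real
#: reporter plasmid can be supplied as a FASTA backbone instead)
MINIMAL_PROMOTER = "AGAGGGTATATAATGGAAGCTCGACTTCCAG"

_BACKBONE_SEED = 715517


def default_backbone(length: int = 6000, promoter_offset: int = 3000) -> tuple[str, int]:
    """Deterministic synthetic reporter backbone.

    Returns (sequence, promoter_offset); the minimal promoter occupies
    ``backbone[promoter_offset : promoter_offset + len(MINIMAL_PROMOTER)]``
    and oligos are inserted immediately upstream of it.
    """
    rng = np.random.default_rng(_BACKBONE_SEED)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return (seq[:promoter_offset] + MINIMAL_PROMOTER
            + seq[promoter_offset + len(MINIMAL_PROMOTER):], promoter_offset)


@dataclass
class MPRAOligo:
    id: str
    snp_id: str
    allele: str                      # "ref" or "alt"
    sequence: str
    observed_log2fc: float = float("nan")
    emvar_label: str = "untested"    # "emVar", "non-emVar" or "untested"

    def __post_init__(self) -> None:
        if len(self.sequence) != OLIGO_LENGTH:
            raise ValueError(f"oligo {self.id}: length {len(self.sequence)} != {OLIGO_LENGTH}")
        if self.allele not in ("ref", "alt"):
            raise ValueError("allele must be 'ref' or 'alt'")


@dataclass
class ReporterConstruct:
    sequence: str
    oligo_span: tuple[int, int]
    window_length: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.window_length:
            raise ValueError("construct length does not match window length")
        s, e = self.oligo_span
        if not (0 <= s < e <= self.window_length):
            raise ValueError("oligo span not contained in window")


def assemble_construct(oligo: MPRAOligo, backbone: str | None = None,
                       promoter_offset: int | None = None,
                       input_length: int = 1000,
                       oligo_end: int | None = None) -> ReporterConstruct:
    """Insert the oligo directly upstream of the minimal promoter and window
    the reporter to the model input length.

    ``oligo_end`` positions the oligo 3' end within the extracted window
    (default: centered oligo); padding on both sides comes from the
    backbone, so longer-context models just request a larger
    ``input_length``.
    """
    if backbone is None:
        backbone, promoter_offset = default_backbone()
    if promoter_offset is None:
        raise ValueError("promoter_offset required with a custom backbone")
    if oligo_end is None:
        oligo_end = (input_length + OLIGO_LENGTH) // 2
    if not OLIGO_LENGTH <= oligo_end <= input_length:
        raise ValueError("oligo does not fit at the requested position")
    full = backbone[:promoter_offset] + oligo.sequence + backbone[promoter_offset:]
    ins_end = promoter_offset + OLIGO_LENGTH   # oligo 3' end in the full reporter
    start = ins_end - oligo_end
    end = start + input_length
    if start < 0 or end > len(full):
        raise ValueError("backbone too short to pad the construct to input_length")
    return ReporterConstruct(sequence=full[start:end],
                             oligo_span=(oligo_end - OLIGO_LENGTH, oligo_end),
                             window_length=input_length)


def _predict_quantity(model, sequences: list[str]) -> np.ndarray:
    X = np.stack([two_hot_encode(s) for s in sequences]).astype(np.float32)
    if isinstance(model, EnsembleModel):
        _, q = model.forward(X)
    else:
        _, q = model.forward(X, train=False)
    return q


def predict_snp_effect(model, ref_construct: ReporterConstruct,
                       alt_construct: ReporterConstruct,
                       pseudocount: float = 1e-6) -> float:
    """log2((quantity_alt + pc) / (quantity_ref + pc)); positive means the
    alternate allele increases predicted initiation."""
    if ref_construct.window_length != alt_construct.window_length:
        raise ValueError("constructs must have equal length")
    q = _predict_quantity(model, [ref_construct.sequence, alt_construct.sequence])
    return float(np.log2((q[1] + pseudocount) / (q[0] + pseudocount)))


def emvar_prc(scores: np.ndarray, labels: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and auPRC with squared scores as predictor.

    ``labels`` is a boolean emVar indicator; auPRC uses the
    average-precision summation rule. Raises on single-class labels.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.all() or not labels.any():
        raise ValueError("need both emVar and non-emVar labels")
    predictor = scores ** 2
    precision, recall, _ = precision_recall_curve(labels, predictor)
    auprc = float(average_precision_score(labels, predictor))
    return precision, recall, auprc


def bootstrap_delta_auprc(score_sets: dict[str, np.ndarray], labels: np.ndarray,
                          reference_model: str, n_boot: int = 1000, seed: int = 0
                          ) -> pd.DataFrame:
    """Bootstrap ΔauPRC of every model against a reference model.

    Each bootstrap resamples SNPs with replacement (the same resample for
    all models); Δ = auPRC(other) − auPRC(reference); the one-sided
    empirical p is the fraction of bootstraps with Δ >= 0. Single-class
    resamples are redrawn (logged).
    """
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    sets = {k: np.asarray(v, dtype=np.float64) for k, v in score_sets.items()}
    if reference_model not in sets:
        raise KeyError(f"reference model {reference_model!r} not in score sets")
    for k, v in sets.items():
        if v.shape != (n,):
            raise ValueError(f"{k}: scores not aligned to labels")
    rng = np.random.default_rng(seed)
    deltas = {k: np.empty(n_boot) for k in sets if k != reference_model}
    n_redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if labels[idx].any() and not labels[idx].all():
                break
            n_redraws += 1
        ref_auprc = emvar_prc(sets[reference_model][idx], labels[idx])[2]
        for k in deltas:
            deltas[k][b] = emvar_prc(sets[k][idx], labels[idx])[2] - ref_auprc
    if n_redraws:
        logger.warning("redrew %d single-class bootstrap resamples", n_redraws)
    rows = [{"model": k, "mean_delta": float(d.mean()),
             "p_value": float(np.mean(d >= 0)), "deltas": d}
            for k, d in deltas.items()]
    return pd.DataFrame(rows)


def effect_agreement(predicted: np.ndarray, observed: np.ndarray,
                     decimals: int = 8) -> tuple[float, float, int]:
    """Pearson r between predicted and observed log2FCs plus the sign
    mismatch fraction among pairs where both are nonzero after rounding.

    Returns (r, sign_mismatch_fraction, n_excluded).
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("need >= 2 paired values")
    r = float(stats.pearsonr(predicted, observed).statistic)
    pr = np.round(predicted, decimals)
    ob = np.round(observed, decimals)
    ok = (pr != 0) & (ob != 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d zero-valued pairs from sign comparison", n_excluded)
    if not ok.any():
        raise ValueError("all pairs excluded from sign comparison")
    mismatch = float(np.mean(np.sign(pr[ok]) != np.sign(ob[ok])))
    return r, mismatch, n_excluded
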