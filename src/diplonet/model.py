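"""Dilated convolutional profile + quantity model and its training loss.

The network follows the BPNet-style layout used for base-resolution
initiation modelling: two convolutional layers (ELU then ReLU activations),
a tower of exponentially dilated convolutions with skip connections, max
pooling, and two output heads. The *profile* head is a single fully
connected layer predicting the strand-concatenated base-resolution track;
the *quantity* head is average pooling followed by a fully connected layer
predicting total signal. Batch normalization follows every convolutional
and fully connected layer; both heads end in ReLU so outputs are
nonnegative.

The training loss is a multiscale objective::

    loss = -cos(p_obs, y_profile)
           + lambda * (log(sum(p_obs) + alpha) - log(y_quantity + alpha))**2

with natural logs, ``alpha`` a pseudocount and ``lambda`` a balancing
weight (defaults 1e-6 and 1/500).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm,
    Conv1D,
    Dense,
    ELU,
    Flatten,
    GlobalAvgPool1D,
    MaxPool1D,
    ReLU,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "LossParams",
    "ProfileQuantityPrediction",
    "ProfileQuantityCNN",
    "build_model",
    "multiscale_loss",
    "multiscale_loss_batch",
    "predicted_track",
    "output_slice",
]


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 1000
    output_length: int = 500
    conv1_filters: int = 64
    conv1_width: int = 8
    conv2_filters: int = 128
    conv2_width: int = 4
    tower_layers: int = 9
    tower_filters: int = 64
    tower_width: int = 3
    pool_width: int = 2
    #: multiplier applied to all filter counts, for desk-scale CPU runs
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.output_length > self.input_length:
            raise ValueError("output_length must not exceed input_length")
        if min(self.conv1_filters, self.conv2_filters, self.tower_filters) < 1:
            raise ValueError("filter counts must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def dilations(self) -> list[int]:
        return [2 ** i for i in range(self.tower_layers)]

    def scaled(self, filters: int) -> int:
        return max(1, round(filters * self.scale_factor))


@dataclass(frozen=True)
class LossParams:
    lam: float = 1.0 / 500.0
    alpha: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.alpha <= 0:
            raise ValueError("lam and alpha must be positive")


@dataclass
class ProfileQuantityPrediction:
    """Model output for one window: base-resolution profile (plus strand
    positions followed by minus strand positions) and a scalar quantity."""

    profile: np.ndarray
    quantity: float


def output_slice(config: ModelConfig) -> slice:
    """Output window centered within the input window (input coordinates)."""
    start = (config.input_length - config.output_length) // 2
    return slice(start, start + config.output_length)


class ProfileQuantityCNN:
    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        f1, f2, ft = c.scaled(c.conv1_filters), c.scaled(c.conv2_filters), c.scaled(c.tower_filters)

        self.conv1 = Conv1D(4, f1, c.conv1_width, rng=rng)
        self.bn1 = BatchNorm(f1)
        self.act1 = ELU()
        self.pool1 = MaxPool1D(c.pool_width)

        self.conv2 = Conv1D(f1, f2, c.conv2_width, rng=rng)
        self.bn2 = BatchNorm(f2)
        self.act2 = ReLU()
        self.pool2 = MaxPool1D(c.pool_width)

        self.tower: list[tuple[Conv1D, BatchNorm, ReLU, bool]] = []
        in_ch = f2
        for dil in c.dilations:
            conv = Conv1D(in_ch, ft, c.tower_width, dilation=dil, rng=rng)
            # residual connections only where channel counts line up
            self.tower.append((conv, BatchNorm(ft), ReLU(), in_ch == ft))
            in_ch = ft
        self.pool3 = MaxPool1D(c.pool_width)
        self.flatten = Flatten()

        body_len = c.input_length
        for _ in range(3):
            body_len //= c.pool_width
        self._body_len = body_len

        self.profile_dense = Dense(body_len * ft, 2 * c.output_length, rng=rng)
        self.profile_bn = BatchNorm(2 * c.output_length)
        self.profile_act = ReLU()

        self.gap = GlobalAvgPool1D()
        self.quantity_dense = Dense(ft, 1, rng=rng)
        self.quantity_bn = BatchNorm(1)
        self.quantity_act = ReLU()

    # ---- layer bookkeeping -------------------------------------------------
    def _named_layers(self):
        yield "conv1", self.conv1
        yield "bn1", self.bn1
        yield "conv2", self.conv2
        yield "bn2", self.bn2
        for i, (conv, bn, _, _) in enumerate(self.tower):
            yield f"tower{i}.conv", conv
            yield f"tower{i}.bn", bn
        yield "profile_dense", self.profile_dense
        yield "profile_bn", self.profile_bn
        yield "quantity_dense", self.quantity_dense
        yield "quantity_bn", self.quantity_bn

    def parameters(self) -> list[np.ndarray]:
        return [layer.params[k] for _, layer in self._named_layers() for k in sorted(layer.params)]

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[k] for _, layer in self._named_layers() for k in sorted(layer.grads)]

    def zero_grad(self) -> None:
        for _, layer in self._named_layers():
            layer.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self._named_layers():
            for k, v in layer.params.items():
                state[f"{name}.{k}"] = v.copy()
            if isinstance(layer, BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean.copy()
                state[f"{name}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._named_layers():
            for k in layer.params:
                layer.params[k][...] = state[f"{name}.{k}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]

    def clone(self) -> "ProfileQuantityCNN":
        other = ProfileQuantityCNN(self.config, seed=0)
        other.load_state_dict(copy.deepcopy(self.state_dict()))
        return other

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path, ) -> "ProfileQuantityCNN":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config, seed=0)
        with np.load(path.with_suffix(".npz")) as state:
            model.load_state_dict({k: state[k] for k in state.files})
        return model

    # ---- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim != 3 or x.shape[1] != self.config.input_length or x.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (n, {self.config.input_length}, 4), got {x.shape}")
        h = x.astype(np.float32, copy=False)
        h = self.pool1.forward(self.act1.forward(self.bn1.forward(self.conv1.forward(h, train), train)), train)
        h = self.pool2.forward(self.act2.forward(self.bn2.forward(self.conv2.forward(h, train), train)), train)
        for conv, bn, act, skip in self.tower:
            out = act.forward(bn.forward(conv.forward(h, train), train))
            h = h + out if skip else out
        h = self.pool3.forward(h, train)
        flat = self.flatten.forward(h)
        profile = self.profile_act.forward(self.profile_bn.forward(self.profile_dense.forward(flat), train))
        pooled = self.gap.forward(h)
        quantity = self.quantity_act.forward(self.quantity_bn.forward(self.quantity_dense.forward(pooled), train))
        return profile, quantity[:, 0]

    def backward(self, dprofile: np.ndarray, dquantity: np.ndarray) -> None:
        dflat = self.profile_dense.backward(self.profile_bn.backward(self.profile_act.backward(dprofile)))
        dpooled = self.quantity_dense.backward(
            self.quantity_bn.backward(self.quantity_act.backward(dquantity[:, None])))
        dh = self.flatten.backward(dflat) + self.gap.backward(dpooled)
        dh = self.pool3.backward(dh)
        for conv, bn, act, skip in reversed(self.tower):
            dconv_in = conv.backward(bn.backward(act.backward(dh)))
            dh = dconv_in + dh if skip else dconv_in
        dh = self.pool2.backward(dh)
        dh = self.conv2.backward(self.bn2.backward(self.act2.backward(dh)))
        dh = self.pool1.backward(dh)
        self.conv1.backward(self.bn1.backward(self.act1.backward(dh)))

    def predict(self, x: np.ndarray) -> ProfileQuantityPrediction | list[ProfileQuantityPrediction]:
        """Inference-mode prediction for a single (L, 4) window or a batch."""
        single = x.ndim == 2
        batch = x[None] if single else x
        profile, quantity = self.forward(batch, train=False)
        preds = [ProfileQuantityPrediction(profile[i], float(quantity[i]))
                 for i in range(batch.shape[0])]
        return preds[0] if single else preds


def build_model(config: ModelConfig, seed: int = 0) -> ProfileQuantityCNN:
    return ProfileQuantityCNN(config, seed=seed)


# ---- loss ------------------------------------------------------------------

def _cosine_and_grad(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise cosine similarity between 2-D arrays and d(cos)/dy.

    Rows where either vector has zero norm get cosine 0 and zero gradient
    (maximally uninformative by convention).
    """
    pn = np.linalg.norm(p, axis=1)
    yn = np.linalg.norm(y, axis=1)
    ok = (pn > 0) & (yn > 0)
    if not ok.all():
        logger.warning("cosine term set to 0 for %d window(s) with a zero-norm vector",
                       int((~ok).sum()))
    denom = np.where(ok, pn * yn, 1.0)
    cos = np.where(ok, (p * y).sum(axis=1) / denom, 0.0)
    grad = np.where(ok[:, None],
                    p / denom[:, None] - cos[:, None] * y / np.where(ok, yn ** 2, 1.0)[:, None],
                    0.0)
    return cos, grad


def multiscale_loss(p_obs: np.ndarray, prediction: ProfileQuantityPrediction,
                    params: LossParams = LossParams()) -> float:
    """Scalar loss for a single observed track / prediction pair."""
    p = np.asarray(p_obs, dtype=np.float64)
    y = np.asarray(prediction.profile, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"profile length mismatch: {p.shape} vs {y.shape}")
    loss, _, _ = multiscale_loss_batch(p[None], y[None],
                                       np.array([prediction.quantity]), params)
    return float(loss)


def multiscale_loss_batch(p_obs: np.ndarray, y_profile: np.ndarray,
                          y_quantity: np.ndarray, params: LossParams = LossParams()
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean loss over a batch plus gradients w.r.t. profile and quantity."""
    p = np.asarray(p_obs, dtype=np.float64)
    y = np.asarray(y_profile, dtype=np.float64)
    q = np.asarray(y_quantity, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"profile shape mismatch: {p.shape} vs {y.shape}")
    n = p.shape[0]
    cos, dcos_dy = _cosine_and_grad(p, y)
    log_diff = np.log(p.sum(axis=1) + params.alpha) - np.log(q + params.alpha)
    loss = float(np.mean(-cos + params.lam * log_diff ** 2))
    dprofile = (-dcos_dy / n).astype(np.float32)
    dquantity = (-2.0 * params.lam * log_diff / (q + params.alpha) / n).astype(np.float32)
    return loss, dprofile, dquantity


def predicted_track(prediction: ProfileQuantityPrediction) -> np.ndarray:
    """Single coverage-scale track: profile normalized to sum one, times the
    predicted quantity. An all-zero profile falls back to uniform."""
    profile = np.asarray(prediction.profile, dtype=np.float64)
    total = profile.sum()
    if total <= 0:
        logger.warning("all-zero profile; falling back to a uniform profile")
        shape = np.full_like(profile, 1.0 / profile.size)
    else:
        shape = profile / total
    return shape * prediction.quantity
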