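"""MIL network variants: shared CNN encoder, scoring head, attention module.

Five bag classifiers are assembled from three building blocks:

* **Subnet 1** — a small shared CNN encoder mapping an RGB patch of any
  supported side to a 128-vector via global average pooling.
* **Subnet 2** — a dropout/dense scoring head with a single sigmoid unit.
* **Attention module** — a two-layer dense network (tanh, then a sigmoid
  unit) producing one attention logit per instance; the logit vector is
  turned into an attention distribution by the softmax or the sparsemax.

Embedding-based variants (EMIL_*) aggregate the instance embeddings and
score the aggregate; instance-based variants (IMIL_*) score every instance
and aggregate the scores.  Aggregation is max pooling (``*_M``), softmax
attention (``*_A``), or sparsemax attention (``IMIL_SA``).  The encoder
weights are shared across all instances of a bag, so the parameter count is
independent of both the patch side and the bag size.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aggregation import (
    RegularizerWeights,
    softmax_transform,
    sparsemax_transform,
    sparsemax_jacobian_vector,
)
from .nn import Conv2D, Dense, Dropout, GlobalAvgPool, MaxPool2D, Sequential

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ModelVariant",
    "BagForwardResult",
    "VARIANTS",
    "build_subnet1",
    "build_subnet2",
    "build_attention_module",
    "assemble_model",
    "count_parameters",
    "resnet50_parameter_count",
    "MILModel",
    "save_checkpoint",
    "load_checkpoint",
]

EMBEDDING_DIM = 128
PAPER_PATCH_SIDES = (86, 129, 172, 258, 344)


@dataclass(frozen=True)
class LayerSpec:
    kind: str                      # conv2d | maxpool2d | global_avg_pool | dense | dropout
    filters: int = 0
    window: tuple = ()
    activation: str = "none"
    dropout_rate: float = 0.0
    param_count: int = 0


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    layers: tuple
    input_contract: str
    output_contract: str

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)


def _conv_spec(in_ch, filters, k, activation):
    return LayerSpec("conv2d", filters, (k, k), activation,
                     param_count=(k * k * in_ch + 1) * filters)


def _dense_spec(in_dim, out_dim, activation):
    return LayerSpec("dense", out_dim, (), activation,
                     param_count=(in_dim + 1) * out_dim)


def build_subnet1() -> NetworkSpec:
    """Shared CNN instance encoder: five same-padded conv stages and a GAP.

    Pooling windows shrink the spatial grid (floor division) while global
    average pooling at the end makes the 128-dim output independent of the
    patch side.  245,792 parameters.
    """
    layers = (
        _conv_spec(3, 16, 5, "relu"),
        LayerSpec("maxpool2d", window=(3, 3)),
        _conv_spec(16, 32, 3, "relu"),
        LayerSpec("maxpool2d", window=(2, 2)),
        _conv_spec(32, 64, 3, "relu"),
        LayerSpec("maxpool2d", window=(2, 2)),
        _conv_spec(64, 128, 3, "relu"),
        LayerSpec("maxpool2d", window=(2, 2)),
        _conv_spec(128, 128, 3, "relu"),
        LayerSpec("global_avg_pool"),
    )
    return NetworkSpec("subnet1", layers, "patch side x side x 3 RGB",
                       f"embedding of length {EMBEDDING_DIM}")


def build_subnet2() -> NetworkSpec:
    """Scoring head: dropout 0.5, dense 256 ReLU, dropout 0.5, dense 1 sigmoid.

    33,281 parameters; the sigmoid unit yields a probability in (0, 1).
    """
    layers = (
        LayerSpec("dropout", dropout_rate=0.5),
        _dense_spec(EMBEDDING_DIM, 256, "relu"),
        LayerSpec("dropout", dropout_rate=0.5),
        _dense_spec(256, 1, "sigmoid"),
    )
    return NetworkSpec("subnet2", layers, f"embedding of length {EMBEDDING_DIM}",
                       "scalar score in (0, 1)")


def build_attention_module() -> NetworkSpec:
    """Attention scorer: dense 256 tanh, then a single sigmoid unit per instance.

    33,281 parameters; emits one logit in (0, 1) per instance.
    """
    layers = (
        LayerSpec("dropout", dropout_rate=0.5),
        _dense_spec(EMBEDDING_DIM, 256, "tanh"),
        LayerSpec("dropout", dropout_rate=0.5),
        _dense_spec(256, 1, "sigmoid"),
    )
    return NetworkSpec("attention", layers, f"embedding of length {EMBEDDING_DIM}",
                       "one attention logit per instance")


@dataclass(frozen=True)
class ModelVariant:
    name: str
    mil_mode: str        # embedding | instance
    aggregator: str      # max | softmax_attention | sparsemax_attention
    regularizers: RegularizerWeights = field(default_factory=RegularizerWeights)


VARIANTS = {
    "EMIL_A": ModelVariant("EMIL_A", "embedding", "softmax_attention"),
    "EMIL_M": ModelVariant("EMIL_M", "embedding", "max"),
    "IMIL_A": ModelVariant("IMIL_A", "instance", "softmax_attention"),
    "IMIL_M": ModelVariant("IMIL_M", "instance", "max"),
    "IMIL_SA": ModelVariant("IMIL_SA", "instance", "sparsemax_attention"),
}


@dataclass
class BagForwardResult:
    bag_probability: float
    embeddings: np.ndarray                 # L x 128
    instance_scores: np.ndarray | None     # instance mode only
    attention: np.ndarray | None           # attention variants only; sums to 1


def _build_sequential(spec: NetworkSpec, rng, dtype) -> Sequential:
    layers, in_ch, in_dim = [], 3, EMBEDDING_DIM
    for ls in spec.layers:
        if ls.kind == "conv2d":
            layers.append(Conv2D(in_ch, ls.filters, ls.window[0], ls.activation, rng, dtype))
            in_ch = ls.filters
        elif ls.kind == "maxpool2d":
            layers.append(MaxPool2D(ls.window[0]))
        elif ls.kind == "global_avg_pool":
            layers.append(GlobalAvgPool())
        elif ls.kind == "dropout":
            layers.append(Dropout(ls.dropout_rate))
        elif ls.kind == "dense":
            layers.append(Dense(in_dim, ls.filters, ls.activation, rng, dtype))
            in_dim = ls.filters
        else:
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    return Sequential(layers)


class MILModel:
    """One assembled MIL variant, holding its networks and bag-level passes.

    ``attention_sigmoid=False`` (the ablation switch) replaces the sigmoid
    on the final attention dense layer with the identity, letting the logits
    range over the whole real line.
    """

    def __init__(self, variant: ModelVariant, patch_side: int, seed: int = 0,
                 dtype=np.float32, attention_sigmoid: bool = True):
        if patch_side < 32:
            raise ValueError(f"patch_side must be >= 32, got {patch_side}")
        self.variant = variant
        self.patch_side = patch_side
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.subnet1 = _build_sequential(build_subnet1(), rng, dtype)
        self.subnet2 = _build_sequential(build_subnet2(), rng, dtype)
        if variant.aggregator in ("softmax_attention", "sparsemax_attention"):
            spec = build_attention_module()
            if not attention_sigmoid:
                last = spec.layers[-1]
                spec = NetworkSpec(spec.name, spec.layers[:-1] + (
                    LayerSpec("dense", last.filters, (), "none",
                              param_count=last.param_count),),
                    spec.input_contract, spec.output_contract)
            self.attention = _build_sequential(spec, rng, dtype)
        else:
            self.attention = None
        self._cache = None

    # ------------------------------------------------------------- params
    def params(self):
        out = self.subnet1.params() + self.subnet2.params()
        if self.attention is not None:
            out += self.attention.params()
        return out

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    def zero_grads(self):
        for p in self.params():
            p.grad[...] = 0.0

    # ------------------------------------------------------------ forward
    def forward_bag(self, patches, train: bool = False, rng=None) -> BagForwardResult:
        """Run one bag (L x side x side x 3, values in [0, 1]) to a bag probability."""
        patches = np.ascontiguousarray(patches, dtype=self.dtype)
        if patches.ndim != 4 or patches.shape[0] < 1:
            raise ValueError(f"bag must be L x h x w x 3 with L >= 1, got {patches.shape}")
        if patches.shape[1] != self.patch_side or patches.shape[2] != self.patch_side:
            raise ValueError(
                f"patch side {patches.shape[1:3]} does not match model side {self.patch_side}")
        emb = self.subnet1.forward(patches, train=train, rng=rng)
        cache = {"emb": emb}

        attn = None
        sm = None
        if self.attention is not None:
            logits = self.attention.forward(emb, train=train, rng=rng)[:, 0]
            if self.variant.aggregator == "softmax_attention":
                attn = softmax_transform(logits.astype(np.float64))
            else:
                sm = sparsemax_transform(logits.astype(np.float64))
                attn = sm.probabilities
            cache.update(logits=logits, attn=attn, sparsemax=sm)

        if self.variant.mil_mode == "embedding":
            if self.variant.aggregator == "max":
                amax = emb.argmax(axis=0)
                z = emb[amax, np.arange(emb.shape[1])]
                cache["amax"] = amax
            else:
                z = (attn @ emb.astype(np.float64)).astype(self.dtype)
            q = float(self.subnet2.forward(z[None], train=train, rng=rng)[0, 0])
            scores = None
        else:
            scores = self.subnet2.forward(emb, train=train, rng=rng)[:, 0]
            if self.variant.aggregator == "max":
                imax = int(scores.argmax())
                q = float(scores[imax])
                cache["imax"] = imax
            else:
                q = float(attn @ scores.astype(np.float64))
            cache["scores"] = scores
        self._cache = cache if train else None
        return BagForwardResult(bag_probability=q, embeddings=emb,
                                instance_scores=scores, attention=attn)

    # ----------------------------------------------------------- backward
    def backward_bag(self, dq: float, d_attention=None) -> None:
        """Accumulate gradients for the last train-mode forward pass.

        ``dq`` is dLoss/d(bag probability); ``d_attention`` (optional) is an
        extra gradient w.r.t. the attention probabilities, used for the
        differentiable regularizer terms.
        """
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward_bag requires a prior train-mode forward_bag")
        emb = cache["emb"]
        L, D = emb.shape
        da = None

        if self.variant.mil_mode == "embedding":
            if self.variant.aggregator == "max":
                dz = self.subnet2.backward(np.array([[dq]], dtype=self.dtype))[0]
                demb = np.zeros_like(emb)
                demb[cache["amax"], np.arange(D)] = dz
            else:
                dz = self.subnet2.backward(np.array([[dq]], dtype=self.dtype))[0]
                attn = cache["attn"]
                demb = (attn[:, None] * dz.astype(np.float64)).astype(self.dtype)
                da = emb.astype(np.float64) @ dz.astype(np.float64)
        else:
            scores = cache["scores"]
            if self.variant.aggregator == "max":
                dscores = np.zeros((L, 1), dtype=self.dtype)
                dscores[cache["imax"], 0] = dq
            else:
                attn = cache["attn"]
                dscores = (attn[:, None] * dq).astype(self.dtype)
                da = scores.astype(np.float64) * dq
            demb = self.subnet2.backward(dscores)

        if self.attention is not None:
            if da is None:
                da = np.zeros(L)
            if d_attention is not None:
                da = da + d_attention
            if self.variant.aggregator == "softmax_attention":
                attn = cache["attn"]
                dlogits = attn * (da - float(attn @ da))
            else:
                dlogits = sparsemax_jacobian_vector(cache["sparsemax"], da)
            demb_att = self.attention.backward(dlogits[:, None].astype(self.dtype))
            demb = demb + demb_att

        self.subnet1.backward(demb, input_grad=False)
        self._cache = None


def assemble_model(variant, patch_side: int, reg: RegularizerWeights | None = None,
                   seed: int = 0, dtype=np.float32,
                   attention_sigmoid: bool = True) -> MILModel:
    """Build one of the five MIL variants for a given patch side.

    ``variant`` is a :class:`ModelVariant` or one of the names
    ``EMIL_A, EMIL_M, IMIL_A, IMIL_M, IMIL_SA``.
    """
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}") from None
    if reg is not None:
        variant = ModelVariant(variant.name, variant.mil_mode, variant.aggregator, reg)
    return MILModel(variant, patch_side, seed=seed, dtype=dtype,
                    attention_sigmoid=attention_sigmoid)


def count_parameters(model: MILModel) -> int:
    """Total number of scalar weights and biases in an assembled model."""
    return sum(p.size for p in model.params())


def resnet50_parameter_count(num_outputs: int = 1) -> int:
    """Parameter count of a ResNet-50 v1 image-classifier baseline.

    Convolutions carry biases, every batch-norm contributes four per-channel
    arrays (scale, offset, moving mean, moving variance), and the head is a
    global average pool followed by a dense layer with ``num_outputs`` units
    (a single sigmoid unit by default).
    """
    def conv(cin, cout, k):
        return (k * k * cin + 1) * cout

    def bn(c):
        return 4 * c

    total = conv(3, 64, 7) + bn(64)
    cin = 64
    for n_blocks, width in zip((3, 4, 6, 3), (64, 128, 256, 512)):
        cout = 4 * width
        for b in range(n_blocks):
            total += conv(cin, width, 1) + bn(width)
            total += conv(width, width, 3) + bn(width)
            total += conv(width, cout, 1) + bn(cout)
            if b == 0:  # projection shortcut at each stage entry
                total += conv(cin, cout, 1) + bn(cout)
            cin = cout
    total += (cin + 1) * num_outputs
    return total


# ---------------------------------------------------------------- persistence

def save_checkpoint(model: MILModel, path) -> None:
    """Save weights as an .npz plus a JSON sidecar describing the variant."""
    path = Path(path)
    arrays = {f"param_{i:03d}": p.value for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    reg = model.variant.regularizers
    sidecar = {
        "variant": model.variant.name,
        "patch_side": model.patch_side,
        "parameter_count": count_parameters(model),
        "lambda_l0": reg.lambda_l0,
        "lambda_mer": reg.lambda_mer,
        "mer_sign": reg.mer_sign,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> MILModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    reg = RegularizerWeights(lambda_l0=sidecar["lambda_l0"],
                             lambda_mer=sidecar["lambda_mer"],
                             mer_sign=sidecar["mer_sign"])
    model = assemble_model(sidecar["variant"], sidecar["patch_side"], reg=reg)
    with np.load(path.with_suffix(".npz")) as data:
        weights = [data[f"param_{i:03d}"] for i in range(len(data.files))]
    model.set_weights(weights)
    return model
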