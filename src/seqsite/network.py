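"""Deep convolutional classifier for per-residue binding-site labeling.

The encoder stacks LN-GLU-Conv blocks in two stages.  Each BasicBlock
computes

    s_i^l = W^l( GLU( LN[ s^(l-1) window of width k ] ) ) + s_i^(l-1)

i.e. layer normalization over channels, a gated linear unit halving 2c
channels to c, a width-k convolution back to 2c channels (zero-padded
(k-1)/2 per side so the sequence length m is preserved), and a residual
connection.  The first block of each stage is "Plain": identical but
without the residual.  One layer normalization sits at the top of each
stage.  Stacking n width-k convolutions at stride 1 gives a receptive
field (input field) of 1 + n(k-1) residues, so depth controls precisely
how long a dependency the classifier can exploit.

Two decoders share the encoder:

* the standard decoder applies two 1x1-convolution (dense) layers with
  output widths c and 2, dropout around the first, removes padded rows
  and applies a 2-way softmax;
* the context-aware decoder additionally consumes a context prediction
  (an m x 2 probability/label tensor), transformed by k x 2 kernels into
  2c channels and processed by two parallel causal stages of M blocks --
  one seeing only context strictly left of each position, one strictly
  right -- whose outputs are added to the encoder output before the
  standard decoding path.  Inference runs the decoder twice: first with
  zero context, then with the first pass's probabilities as context.

Padded (dummy) residues are zeroed before every convolution, which makes
each protein's predictions exactly independent of batch composition and
padding amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .features import FeatureMap, N_FEATURES, dummy_feature_row

__all__ = [
    "NetworkConfig",
    "Weights",
    "SequenceBatch",
    "PredictionResult",
    "receptive_field",
    "encoder_conv_layers",
    "init_weights",
    "extend_to_en",
    "encoder_forward",
    "std_decoder_forward",
    "en_decoder_forward",
    "forward_logits",
    "pad_batch",
    "predict",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.4
LN_EPS = 1e-5


def receptive_field(n: int, k: int) -> int:
    """Input-field size of n stacked width-k convolutions at stride 1."""
    if n < 0 or k < 1:
        raise ValueError("receptive_field requires n >= 0 and k >= 1")
    return 1 + n * (k - 1)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the classifier.

    ``c`` is the channel half-width: blocks carry 2c channels and the GLU
    gates them down to c.  ``blocks_per_stage`` (N) counts blocks in each
    of the two encoder stages; ``context_blocks`` (M) counts blocks in each
    causal context stage of the en decoder.
    """

    k: int = 5
    blocks_per_stage: int = 10
    context_blocks: int = 2
    c: int = 256
    d: int = N_FEATURES
    dropout: float = 0.5
    mode: str = "std"

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"kernel width k must be odd and >= 1, got {self.k}")
        if self.blocks_per_stage < 1 or self.context_blocks < 1:
            raise ValueError("blocks_per_stage and context_blocks must be >= 1")
        if self.c < 1:
            raise ValueError("channel half-width c must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.mode not in ("std", "en"):
            raise ValueError(f"mode must be 'std' or 'en', got {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "blocks_per_stage": self.blocks_per_stage,
            "context_blocks": self.context_blocks,
            "c": self.c,
            "d": self.d,
            "dropout": self.dropout,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkConfig":
        return cls(**{k: d[k] for k in (
            "k", "blocks_per_stage", "context_blocks", "c", "d", "dropout", "mode")})


def encoder_conv_layers(config: NetworkConfig) -> int:
    """Number of width-k convolutions in the encoder (input transform + blocks)."""
    return 1 + 2 * config.blocks_per_stage


class Weights:
    """All learnable tensors, keyed by dotted names.

    Encoder parameters are prefixed ``enc.``, standard-decoder parameters
    ``dec.``, and context-branch parameters ``ctxl.`` / ``ctxr.``.  Kernel
    parameters (names ending ``.W``) are the ones the L2 penalty covers;
    biases and layer-norm gains/offsets are excluded.
    """

    def __init__(self, params: dict[str, Tensor], config: NetworkConfig):
        self.params = params
        self.config = config

    def __getitem__(self, name: str) -> Tensor:
        return self.params[name]

    def names(self) -> list[str]:
        return sorted(self.params)

    def tensors(self) -> list[Tensor]:
        return [self.params[n] for n in self.names()]

    def kernel_params(self) -> list[Tensor]:
        return [self.params[n] for n in self.names() if n.endswith(".W")]

    def encoder_names(self) -> list[str]:
        return [n for n in self.names() if n.startswith("enc.")]

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def copy(self) -> "Weights":
        return Weights(
            {n: Tensor(t.data.copy(), requires_grad=True, name=n)
             for n, t in self.params.items()},
            self.config,
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self.params.items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            missing = set(self.params) - set(state)
            extra = set(state) - set(self.params)
            raise ValueError(f"weight name mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for n, arr in state.items():
            if self.params[n].data.shape != np.asarray(arr).shape:
                raise ValueError(
                    f"shape mismatch for {n}: have {self.params[n].data.shape}, "
                    f"checkpoint has {np.asarray(arr).shape}")
            self.params[n].data = np.array(arr, dtype=np.float64)


def _param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, name: str) -> Tensor:
    data = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape)
    return Tensor(data, requires_grad=True, name=name)


def _const(value: np.ndarray, name: str) -> Tensor:
    return Tensor(value, requires_grad=True, name=name)


def _block_params(rng, prefix: str, k: int, c: int) -> dict[str, Tensor]:
    return {
        f"{prefix}.ln.g": _const(np.ones(2 * c), f"{prefix}.ln.g"),
        f"{prefix}.ln.b": _const(np.zeros(2 * c), f"{prefix}.ln.b"),
        f"{prefix}.conv.W": _param(rng, (k, c, 2 * c), k * c, f"{prefix}.conv.W"),
        f"{prefix}.conv.b": _const(np.zeros(2 * c), f"{prefix}.conv.b"),
    }


def init_weights(config: NetworkConfig, rng: np.random.Generator) -> Weights:
    """Variance-scaled (fan-in) random initialization of all parameters."""
    k, c, d = config.k, config.c, config.d
    p: dict[str, Tensor] = {
        "enc.in.W": _param(rng, (k, d, 2 * c), k * d, "enc.in.W"),
        "enc.in.b": _const(np.zeros(2 * c), "enc.in.b"),
    }
    for s in (1, 2):
        for j in range(config.blocks_per_stage):
            p.update(_block_params(rng, f"enc.s{s}.b{j}", k, c))
        p[f"enc.s{s}.ln.g"] = _const(np.ones(2 * c), f"enc.s{s}.ln.g")
        p[f"enc.s{s}.ln.b"] = _const(np.zeros(2 * c), f"enc.s{s}.ln.b")
    p["dec.fc1.W"] = _param(rng, (2 * c, c), 2 * c, "dec.fc1.W")
    p["dec.fc1.b"] = _const(np.zeros(c), "dec.fc1.b")
    p["dec.fc2.W"] = _param(rng, (c, 2), c, "dec.fc2.W")
    p["dec.fc2.b"] = _const(np.zeros(2), "dec.fc2.b")
    if config.mode == "en":
        p.update(_context_params(config, rng))
    return Weights(p, config)


def _context_params(config: NetworkConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    k, c = config.k, config.c
    p: dict[str, Tensor] = {}
    for side in ("ctxl", "ctxr"):
        p[f"{side}.in.W"] = _param(rng, (k, 2, 2 * c), 2 * k, f"{side}.in.W")
        p[f"{side}.in.b"] = _const(np.zeros(2 * c), f"{side}.in.b")
        for j in range(config.context_blocks):
            p.update(_block_params(rng, f"{side}.b{j}", k, c))
        # stage-top LN zero-initialized: the context branch contributes exactly
        # zero before fine-tuning, so the en network starts prediction-identical
        # to the std network it was seeded from.
        p[f"{side}.ln.g"] = _const(np.zeros(2 * c), f"{side}.ln.g")
        p[f"{side}.ln.b"] = _const(np.zeros(2 * c), f"{side}.ln.b")
    return p


def extend_to_en(std_weights: Weights, rng: np.random.Generator) -> Weights:
    """Seed an en-mode weight set from trained std weights.

    Encoder and standard-decoder tensors are copied; the context branches
    are freshly initialized (with zeroed stage-top layer norms).
    """
    cfg = replace(std_weights.config, mode="en")
    p = {n: Tensor(t.data.copy(), requires_grad=True, name=n)
         for n, t in std_weights.params.items() if not n.startswith(("ctxl.", "ctxr."))}
    p.update(_context_params(cfg, rng))
    return Weights(p, cfg)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

@dataclass
class SequenceBatch:
    """Feature maps padded to a common length with a per-residue validity mask.

    Padded positions hold the dummy-residue embedding row; ``mask`` is False
    there.  The network zeroes masked rows internally, so predictions on the
    valid rows never depend on how much padding a batch carries.
    """

    features: np.ndarray  # (B, m_pad, d)
    mask: np.ndarray  # (B, m_pad) bool
    lengths: np.ndarray  # (B,)
    ids: list[str]
    labels: np.ndarray | None = None  # (B, m_pad) int; 0 at padded rows

    def __post_init__(self) -> None:
        if self.features.shape[:2] != self.mask.shape:
            raise ValueError("mask shape must match features (B, m)")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def pad_batch(
    maps: Sequence[FeatureMap],
    labels: Sequence[np.ndarray] | None = None,
    pad_to: int | None = None,
) -> SequenceBatch:
    """Pad feature maps to a common length with dummy-residue rows."""
    if not maps:
        raise ValueError("cannot build a batch from zero proteins")
    lengths = np.array([fm.length for fm in maps])
    m_pad = int(lengths.max()) if pad_to is None else int(pad_to)
    if m_pad < lengths.max():
        raise ValueError("pad_to is smaller than the longest sequence")
    bsz = len(maps)
    feats = np.tile(dummy_feature_row(), (bsz, m_pad, 1))
    mask = np.zeros((bsz, m_pad), dtype=bool)
    for i, fm in enumerate(maps):
        feats[i, : fm.length] = fm.values
        mask[i, : fm.length] = True
    lab = None
    if labels is not None:
        if len(labels) != bsz:
            raise ValueError("labels must match the number of proteins")
        lab = np.zeros((bsz, m_pad), dtype=int)
        for i, l in enumerate(labels):
            l = np.asarray(l, dtype=int)
            if l.shape[0] != lengths[i]:
                raise ValueError(f"label length mismatch for protein {maps[i].protein_id!r}")
            lab[i, : lengths[i]] = l
    return SequenceBatch(feats, mask, lengths, [fm.protein_id for fm in maps], lab)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _basic_block(
    h: Tensor,
    weights: Weights,
    prefix: str,
    mask: np.ndarray,
    residual: bool,
    pad_left: int | None = None,
    pad_right: int | None = None,
) -> Tensor:
    w = weights.params
    z = ad.layer_norm(h, w[f"{prefix}.ln.g"], w[f"{prefix}.ln.b"], eps=LN_EPS)
    z = ad.glu(z)
    z = ad.mask_rows(z, mask)  # padded rows must enter the conv as zeros
    z = ad.conv1d(z, w[f"{prefix}.conv.W"], w[f"{prefix}.conv.b"],
                  pad_left=pad_left, pad_right=pad_right)
    if residual:
        z = ad.add(z, h)
    return ad.mask_rows(z, mask)


def encoder_forward(features, mask: np.ndarray, weights: Weights) -> Tensor:
    """Encode a padded batch: (B, m, d) features -> (B, m, 2c) representation."""
    cfg = weights.config
    x = features if isinstance(features, Tensor) else Tensor(np.asarray(features, dtype=np.float64))
    if x.data.ndim != 3 or x.data.shape[-1] != cfg.d:
        raise ValueError(f"encoder expects (B, m, {cfg.d}) features, got {x.data.shape}")
    w = weights.params
    h = ad.mask_rows(x, mask)
    h = ad.conv1d(h, w["enc.in.W"], w["enc.in.b"])
    h = ad.mask_rows(h, mask)
    for s in (1, 2):
        for j in range(cfg.blocks_per_stage):
            h = _basic_block(h, weights, f"enc.s{s}.b{j}", mask, residual=(j > 0))
        h = ad.layer_norm(h, w[f"enc.s{s}.ln.g"], w[f"enc.s{s}.ln.b"], eps=LN_EPS)
        h = ad.mask_rows(h, mask)
    return h


def std_decoder_forward(
    encoding: Tensor,
    mask: np.ndarray,
    weights: Weights,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Standard decoding path: two 1x1 projections to c then 2 logits."""
    cfg = weights.config
    w = weights.params
    if training and rng is None:
        raise ValueError("training-mode decoding needs an rng for dropout")
    z = ad.linear(encoding, w["dec.fc1.W"], w["dec.fc1.b"])
    z = ad.dropout(z, cfg.dropout, rng, training)
    z = ad.linear(z, w["dec.fc2.W"], w["dec.fc2.b"])
    return ad.mask_rows(z, mask)


def _context_branch(
    context: Tensor,
    mask: np.ndarray,
    weights: Weights,
    side: str,
) -> Tensor:
    """One causal context stage.  ``side`` 'ctxl' sees strictly-left context
    (output at i depends only on context at positions < i); 'ctxr' mirrors."""
    cfg = weights.config
    w = weights.params
    k = cfg.k
    if side == "ctxl":
        shifted = ad.shift_sequence(context, +1)  # drop last element, start mark = 0
        pads = dict(pad_left=k - 1, pad_right=0)
    else:
        shifted = ad.shift_sequence(context, -1)  # drop first element, end mark = 0
        pads = dict(pad_left=0, pad_right=k - 1)
    z = ad.mask_rows(shifted, mask)
    z = ad.conv1d(z, w[f"{side}.in.W"], w[f"{side}.in.b"], **pads)
    z = ad.mask_rows(z, mask)
    for j in range(cfg.context_blocks):
        z = _basic_block(z, weights, f"{side}.b{j}", mask, residual=(j > 0), **pads)
    z = ad.layer_norm(z, w[f"{side}.ln.g"], w[f"{side}.ln.b"], eps=LN_EPS)
    return ad.mask_rows(z, mask)


def en_decoder_forward(
    encoding: Tensor,
    context,
    mask: np.ndarray,
    weights: Weights,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Context-aware decoding: causal context stages added to the encoding.

    ``context`` is (B, m, 2) -- one-hot labels during teacher forcing, softmax
    probabilities at the second inference pass, or zeros for the first pass.
    """
    ctx = context if isinstance(context, Tensor) else Tensor(np.asarray(context, dtype=np.float64))
    if ctx.data.shape[:2] != encoding.data.shape[:2] or ctx.data.shape[-1] != 2:
        raise ValueError(
            f"context must be (B, m, 2) matching the encoding, got {ctx.data.shape}")
    left = _context_branch(ctx, mask, weights, "ctxl")
    right = _context_branch(ctx, mask, weights, "ctxr")
    h = ad.add(ad.add(encoding, left), right)
    h = ad.mask_rows(h, mask)
    return std_decoder_forward(h, mask, weights, training=training, rng=rng)


def forward_logits(
    batch: SequenceBatch,
    weights: Weights,
    context: np.ndarray | None = None,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full forward pass to per-residue logits (B, m, 2).

    In en mode, ``context`` defaults to zeros (first-pass behavior).
    """
    enc = encoder_forward(batch.features, batch.mask, weights)
    if weights.config.mode == "en":
        if context is None:
            context = np.zeros(batch.features.shape[:2] + (2,))
        return en_decoder_forward(enc, context, batch.mask, weights, training=training, rng=rng)
    if context is not None:
        raise ValueError("std-mode network takes no context input")
    return std_decoder_forward(enc, batch.mask, weights, training=training, rng=rng)


def softmax_probabilities(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row softmax over valid rows; masked rows are zero (removed from output)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs * np.asarray(mask, dtype=float)[..., None]


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Per-residue class probabilities and thresholded labels for one protein."""

    protein_id: str
    probabilities: np.ndarray  # (L, 2): columns (non-binding, binding)
    labels: np.ndarray  # (L,) int {0,1}
    threshold: float

    @property
    def positive_probability(self) -> np.ndarray:
        return self.probabilities[:, 1]


def predict(
    weights: Weights,
    maps: Sequence[FeatureMap] | FeatureMap,
    threshold: float = DEFAULT_THRESHOLD,
    context: np.ndarray | None = None,
) -> list[PredictionResult]:
    """Predict binding residues for one or more proteins.

    std mode runs a single decoding pass.  en mode runs the decoder twice:
    pass 1 with zero context, pass 2 with pass-1 probabilities as context
    (unless an explicit ``context`` array overrides both, which yields a
    single teacher-forced pass).  A residue is called positive when its
    binding-class probability is >= ``threshold``.
    """
    single = isinstance(maps, FeatureMap)
    if single:
        maps = [maps]
    batch = pad_batch(maps)
    if batch.n_valid == 0:
        raise ValueError("all residues are masked; nothing to predict")
    enc = encoder_forward(batch.features, batch.mask, weights)
    if weights.config.mode == "en":
        if context is None:
            zero_ctx = np.zeros(batch.features.shape[:2] + (2,))
            logits1 = en_decoder_forward(enc, zero_ctx, batch.mask, weights)
            probs1 = softmax_probabilities(logits1.data, batch.mask)
            logits = en_decoder_forward(enc, probs1, batch.mask, weights)
        else:
            logits = en_decoder_forward(enc, context, batch.mask, weights)
    else:
        if context is not None:
            raise ValueError("std-mode network takes no context input")
        logits = std_decoder_forward(enc, batch.mask, weights)
    probs = softmax_probabilities(logits.data, batch.mask)
    results = []
    for i, fm in enumerate(maps):
        p = probs[i, : fm.length]
        results.append(PredictionResult(
            protein_id=fm.protein_id,
            probabilities=p,
            labels=(p[:, 1] >= threshold).astype(int),
            threshold=threshold,
        ))
    return results
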