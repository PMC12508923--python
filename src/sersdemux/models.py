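"""The three demultiplexing architectures and their sklearn-style wrappers.

All three are 1-D encoder-decoder networks on length-896 single-channel
spectra normalized to [-1, 1]:

* ``unet`` -- four encoder blocks (double conv-PReLU, max-pool halving the
  length), a bottleneck block, and four mirrored decoder blocks (transposed
  convolution upsampling, concatenating the encoder skip), ending in a
  1x1 convolution with Tanh;
* ``resnet_unet`` -- the same topology with an additive shortcut across each
  double-conv block;
* ``trans_unet`` -- the ResNet UNet plus a transformer branch (patch
  embedding with learnable position embeddings, pre-norm residual
  MSA/MLP layers) whose output is projected to the bottleneck shape and
  element-wise multiplied with the bottleneck activation.

The length trace at depth 4 is 896 -> 448 -> 224 -> 112 -> 56 and the
decoder mirrors it exactly; the transformer patch length (16 by default)
is chosen so the 56 patches line up with the 56-point bottleneck for the
multiplicative fusion.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigurationError
from .nn import (
    Conv1d,
    ConvTranspose1d,
    Linear,
    MaxPool1d,
    Module,
    Parameter,
    PReLU,
    Tanh,
    TransformerLayer,
)

__all__ = [
    "ModelConfig", "ConvBlock", "UNet1d", "TransUNet1d", "build_model",
    "transformer_encode", "demultiplex", "save_checkpoint", "load_checkpoint",
    "UNetDemultiplexer", "ResNetUNetDemultiplexer", "TransUNetDemultiplexer",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("unet", "resnet_unet", "trans_unet")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``base_channels`` doubles per encoder block (base, 2b, 4b, 8b; bottleneck
    16b).  ``patch_length`` must divide the input length, and for the
    transformer fusion the patch count must equal the bottleneck length
    (input_length / 2**depth).
    """

    family: str = "trans_unet"
    input_length: int = 896
    base_channels: int = 32
    depth: int = 4
    patch_length: int = 16
    embed_dim: int = 128
    n_heads: int = 4
    n_layers: int = 4
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(
                f"unknown architecture {self.family!r}; choose from {MODEL_FAMILIES}"
            )
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.input_length % (2 ** self.depth):
            raise ConfigurationError(
                f"input length {self.input_length} not divisible by "
                f"2**{self.depth}"
            )
        if self.family == "trans_unet":
            if self.input_length % self.patch_length:
                raise ConfigurationError(
                    f"patch length {self.patch_length} does not divide "
                    f"input length {self.input_length}"
                )
            n_patches = self.input_length // self.patch_length
            bottleneck = self.input_length // 2 ** self.depth
            if n_patches != bottleneck:
                raise ConfigurationError(
                    f"fusion shape mismatch: {n_patches} transformer patches "
                    f"vs bottleneck length {bottleneck}"
                )
            if self.embed_dim % self.n_heads:
                raise ConfigurationError(
                    f"embed dim {self.embed_dim} not divisible by "
                    f"{self.n_heads} heads"
                )

    @property
    def bottleneck_length(self) -> int:
        return self.input_length // 2 ** self.depth

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type


class ConvBlock(Module):
    """Double conv-PReLU block (kernel 3, stride 1, padding 1); the ResNet
    variant adds a shortcut (identity, or 1x1 conv when channels change)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 resnet: bool, dtype):
        self.conv1 = Conv1d(c_in, c_out, 3, rng, dtype)
        self.act1 = PReLU(c_out, dtype)
        self.conv2 = Conv1d(c_out, c_out, 3, rng, dtype)
        self.act2 = PReLU(c_out, dtype)
        self.resnet = resnet
        self.shortcut = (
            Conv1d(c_in, c_out, 1, rng, dtype)
            if resnet and c_in != c_out else None
        )
        if resnet:
            # damp the residual branch at initialisation so stacking many
            # blocks keeps the activation variance near the shortcut's and
            # the final Tanh out of its saturated regime
            self.conv2.weight.value *= np.asarray(0.1, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))
        if self.resnet:
            y = y + (x if self.shortcut is None else self.shortcut.forward(x))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.conv1.backward(self.act1.backward(
            self.conv2.backward(self.act2.backward(dy))))
        if self.resnet:
            dx = dx + (dy if self.shortcut is None else self.shortcut.backward(dy))
        return dx


class _TransformerBranch(Module):
    """Patch embedding + position embeddings + L pre-norm transformer layers,
    projected to the bottleneck activation's shape for multiplicative fusion.

    With zero layers the output degenerates to the projected patch
    embeddings plus position embeddings (a learned gate)."""

    def __init__(self, config: ModelConfig, c_bottleneck: int,
                 rng: np.random.Generator, dtype):
        self.patch_length = config.patch_length
        self.n_patches = config.input_length // config.patch_length
        self.patch_embed = Linear(config.patch_length, config.embed_dim, rng, dtype)
        self.pos_embed = Parameter(
            (0.02 * rng.standard_normal((self.n_patches, config.embed_dim))).astype(dtype))
        self.layers = [
            TransformerLayer(config.embed_dim, config.n_heads, rng, dtype)
            for _ in range(config.n_layers)
        ]
        self.out_proj = Linear(config.embed_dim, c_bottleneck, rng, dtype)
        # open-gate initialisation: the projected transformer output starts
        # near 1, so the multiplicative fusion is identity-like at first and
        # the UNet path trains unimpeded while the gate specialises
        self.out_proj.bias.value += np.asarray(1.0, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        tokens = x.reshape(n, self.n_patches, self.patch_length)
        z = self.patch_embed.forward(tokens) + self.pos_embed.value
        for layer in self.layers:
            z = layer.forward(z)
        # (n, patches, c_b) -> channel-first (c_b, n, patches) to match the
        # bottleneck activation's layout
        return np.ascontiguousarray(self.out_proj.forward(z).transpose(2, 0, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.out_proj.backward(np.ascontiguousarray(dy.transpose(1, 2, 0)))
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        self.pos_embed.grad += dz.sum(axis=0)
        dtokens = self.patch_embed.backward(dz)
        n = dtokens.shape[0]
        return dtokens.reshape(n, 1, self.n_patches * self.patch_length)


class UNet1d(Module):
    """Plain or ResNet 1-D UNet; see the module docstring for the topology."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        if config.family == "trans_unet" and type(self) is UNet1d:
            raise ConfigurationError("use TransUNet1d for the trans_unet family")
        self.config = config
        rng = np.random.default_rng(config.seed) if rng is None else rng
        dtype = config.np_dtype
        resnet = config.family in ("resnet_unet", "trans_unet")
        chans = [config.base_channels * 2 ** i for i in range(config.depth)]
        self.encoders = []
        c_prev = 1
        for c in chans:
            self.encoders.append(ConvBlock(c_prev, c, rng, resnet, dtype))
            c_prev = c
        self.pools = [MaxPool1d(2) for _ in chans]
        self.c_bottleneck = config.base_channels * 2 ** config.depth
        self.bottleneck = ConvBlock(c_prev, self.c_bottleneck, rng, resnet, dtype)
        self.upsamples = []
        self.decoders = []
        c_up = self.c_bottleneck
        for c in reversed(chans):
            self.upsamples.append(ConvTranspose1d(c_up, c, 2, rng, dtype))
            self.decoders.append(ConvBlock(2 * c, c, rng, resnet, dtype))
            c_up = c
        self.head = Conv1d(chans[0], 1, 1, rng, dtype)
        # moderately damped head init: keeps the initial pre-Tanh output out
        # of the saturated regime without throttling how fast the output
        # amplitude can grow during training
        self.head.weight.value *= np.asarray(0.5, dtype=dtype)
        self.out_act = Tanh()
        self._chans = chans

    # hook points for the transformer fusion
    def _fuse_forward(self, b: np.ndarray, x: np.ndarray) -> np.ndarray:
        return b

    def _fuse_backward(self, db: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        return db, None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # external contract is (batch, 1, length); internally the conv path
        # runs channel-first (channels, batch, length)
        h = np.ascontiguousarray(x.transpose(1, 0, 2))
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        b = self.bottleneck.forward(h)
        h = self._fuse_forward(b, x)
        for up, dec, skip in zip(self.upsamples, self.decoders, reversed(skips)):
            h = up.forward(h)
            h = dec.forward(np.concatenate([skip, h], axis=0))
        y = self.out_act.forward(self.head.forward(h))
        return np.ascontiguousarray(y.transpose(1, 0, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.head.backward(
            self.out_act.backward(np.ascontiguousarray(dy.transpose(1, 0, 2))))
        # decoder stage i consumed encoder skip (depth-1-i); walking the
        # decoders from the output end inwards therefore yields the skip
        # gradients in encoder order
        dskips = []
        for i in range(len(self.decoders) - 1, -1, -1):
            c = self._chans[len(self._chans) - 1 - i]
            dcat = self.decoders[i].backward(dh)
            dskips.append(dcat[:c])
            dh = self.upsamples[i].backward(dcat[c:])
        db, dx_branch = self._fuse_backward(dh)
        dh = self.bottleneck.backward(db)
        for i in range(len(self.encoders) - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.encoders[i].backward(dh)
        dx = np.ascontiguousarray(dh.transpose(1, 0, 2))
        if dx_branch is not None:
            dx = dx + dx_branch
        return dx


class TransUNet1d(UNet1d):
    """ResNet UNet with a transformer branch multiplied into the bottleneck."""

    def __init__(self, config: ModelConfig):
        if config.family != "trans_unet":
            raise ConfigurationError("TransUNet1d requires family='trans_unet'")
        rng = np.random.default_rng(config.seed)
        super().__init__(config, rng)
        self.transformer = _TransformerBranch(config, self.c_bottleneck, rng,
                                              config.np_dtype)
        self._fusion_cache: tuple[np.ndarray, np.ndarray] | None = None

    def _fuse_forward(self, b: np.ndarray, x: np.ndarray) -> np.ndarray:
        t = self.transformer.forward(x)
        if t.shape != b.shape:
            raise ConfigurationError(
                f"fusion shape mismatch: transformer {t.shape} vs bottleneck {b.shape}"
            )
        self._fusion_cache = (b, t)
        return b * t

    def _fuse_backward(self, dfused: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, t = self._fusion_cache
        db = dfused * t
        dx_branch = self.transformer.backward(dfused * b)  # (n, 1, length)
        return db, dx_branch


def build_model(config: ModelConfig) -> UNet1d:
    """Construct a seeded, trainable network for the requested family."""
    if config.family == "trans_unet":
        return TransUNet1d(config)
    return UNet1d(config)


def transformer_encode(model: "TransUNet1d", mixture: np.ndarray) -> np.ndarray:
    """Run only the transformer branch of a Trans UNet.

    Splits the normalized input into patches, applies the learned patch
    embedding, position embeddings and the pre-norm attention/MLP stack, and
    returns the encoding already projected to the bottleneck shape used by
    the multiplicative fusion: ``(batch, bottleneck_channels, n_patches)``.
    """
    if not isinstance(model, TransUNet1d):
        raise ConfigurationError("transformer_encode requires a trans_unet model")
    x = np.asarray(mixture, dtype=model.config.np_dtype)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != model.config.input_length:
        raise ValueError(
            f"expected spectra of length {model.config.input_length}, got {x.shape}"
        )
    enc = model.transformer.forward(x[:, None, :])  # (c_b, n, patches)
    enc = np.ascontiguousarray(enc.transpose(1, 0, 2))
    return enc[0] if single else enc


def demultiplex(model: UNet1d, mixture: np.ndarray) -> np.ndarray:
    """Run a (fitted or freshly built) network on normalized mixtures.

    Accepts a single length-``input_length`` spectrum or a batch
    ``(n, input_length)``; returns the PFOS-component estimate in [-1, 1]
    with matching shape.  Deterministic for fixed parameters.
    """
    x = np.asarray(mixture, dtype=model.config.np_dtype)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != model.config.input_length:
        raise ValueError(
            f"expected spectra of length {model.config.input_length}, got {x.shape}"
        )
    y = model.forward(x[:, None, :])[:, 0, :]
    return y[0] if single else y


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path: str | Path, model: UNet1d,
                    extra: dict | None = None) -> None:
    """Serialize parameters plus the embedded ModelConfig to one .npz file."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    cfg = asdict(model.config)
    np.savez(path,
             config_keys=np.array(list(cfg), dtype="U32"),
             config_values=np.array([str(v) for v in cfg.values()], dtype="U64"),
             extra_keys=np.array(list(extra or {}), dtype="U32"),
             extra_values=np.array([str(v) for v in (extra or {}).values()], dtype="U64"),
             **arrays)


def load_checkpoint(path: str | Path, family: str | None = None) -> UNet1d:
    """Rebuild a network from a checkpoint.

    Refuses to load when ``family`` is given and does not match the stored
    configuration.
    """
    with np.load(path) as data:
        keys = [str(k) for k in data["config_keys"]]
        values = [str(v) for v in data["config_values"]]
        cfg_raw = dict(zip(keys, values))
        cfg = ModelConfig(
            family=cfg_raw["family"],
            input_length=int(cfg_raw["input_length"]),
            base_channels=int(cfg_raw["base_channels"]),
            depth=int(cfg_raw["depth"]),
            patch_length=int(cfg_raw["patch_length"]),
            embed_dim=int(cfg_raw["embed_dim"]),
            n_heads=int(cfg_raw["n_heads"]),
            n_layers=int(cfg_raw["n_layers"]),
            seed=int(cfg_raw["seed"]),
            dtype=cfg_raw["dtype"],
        )
        if family is not None and family != cfg.family:
            raise ConfigurationError(
                f"checkpoint holds a {cfg.family!r} model, not {family!r}"
            )
        model = build_model(cfg)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ConfigurationError(
                    f"checkpoint parameter {i} has shape {stored.shape}, "
                    f"expected {p.value.shape}"
                )
            p.value[...] = stored
    return model


# ---------------------------------------------------------------------------
# sklearn-style estimators

class _BaseDemultiplexer(BaseEstimator, RegressorMixin):
    """Shared fit/predict plumbing for the three architectures.

    X and y are ``(n_samples, input_length)`` arrays in [-1, 1] (see
    :func:`sersdemux.evaluation.records_to_arrays`); ``fit`` trains with
    Adam on the mean-absolute-error objective and keeps the
    best-validation-MAE parameters when a validation set is supplied.
    """

    _family: str = ""

    def __init__(self, base_channels: int = 32, depth: int = 4,
                 patch_length: int = 16, embed_dim: int = 128, n_heads: int = 4,
                 n_layers: int = 4, learning_rate: float = 1e-4,
                 epochs: int = 50, batch_size: int = 8, seed: int = 0,
                 dtype: str = "float32"):
        self.base_channels = base_channels
        self.depth = depth
        self.patch_length = patch_length
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.dtype = dtype

    @property
    def model_id(self) -> str:
        return self._family

    def _model_config(self, input_length: int) -> ModelConfig:
        return ModelConfig(
            family=self._family, input_length=input_length,
            base_channels=self.base_channels, depth=self.depth,
            patch_length=self.patch_length, embed_dim=self.embed_dim,
            n_heads=self.n_heads, n_layers=self.n_layers, seed=self.seed,
            dtype=self.dtype,
        )

    def fit(self, X, y, X_val=None, y_val=None, verbose: bool = False):
        from .training import TrainConfig, fit_arrays

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape != y.shape:
            raise ValueError(f"X and y must be (n, length) with equal shapes, "
                             f"got {X.shape} and {y.shape}")
        self.config_ = self._model_config(X.shape[1])
        self.network_ = build_model(self.config_)
        tc = TrainConfig(learning_rate=self.learning_rate, epochs=self.epochs,
                         batch_size=self.batch_size, seed=self.seed)
        self.network_, self.history_ = fit_arrays(
            self.network_, X, y, X_val, y_val, tc, verbose=verbose)
        return self

    def predict(self, X):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        return demultiplex(self.network_, np.asarray(X, dtype=float))


class UNetDemultiplexer(_BaseDemultiplexer):
    """Plain 1-D UNet demultiplexer."""
    _family = "unet"


class ResNetUNetDemultiplexer(_BaseDemultiplexer):
    """1-D UNet with residual double-conv blocks."""
    _family = "resnet_unet"


class TransUNetDemultiplexer(_BaseDemultiplexer):
    """ResNet UNet with a transformer branch fused multiplicatively into the
    bottleneck."""
    _family = "trans_unet"
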