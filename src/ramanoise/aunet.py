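"""1-D attention U-net mapping noisy-spectrum DCT coefficients to noise coefficients.

The backbone is a standard U-net: an encoder of conv blocks with factor-2 max
pooling, a bottleneck, and a decoder of factor-2 transposed convolutions with
skip connections concatenated from the matching encoder level.  Every conv
block's output is refined by a channel-attention gate (global pooling ->
bottleneck MLP -> sigmoid) followed by a spatial-attention gate
(channel-pooled maps -> convolution -> sigmoid) before it is passed on.  Both
gates scale features by factors strictly inside (0, 1), so refined feature
magnitudes never exceed the raw ones; disabling attention reduces the model
to a plain 1-D U-net with identical shapes and contracts.

Inputs whose length is not a multiple of 2**depth are zero-padded
symmetrically in coefficient space and cropped on output — harmless because
the padding touches only coefficients beyond the measured band.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ConfigError, ShapeError

__all__ = [
    "ModelConfig", "AttentionUNet", "TrainedModel", "build_model",
    "predict_noise_coeffs", "ZeroPredictor", "OraclePredictor", "pad_length",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``base_channels`` doubles at every encoder level, capped at
    ``max_channels`` to keep the deepest levels affordable; ``reduction`` is
    the channel-attention bottleneck ratio.  ``n_input`` is the nominal
    coefficient length; the network itself is fully convolutional and accepts
    any length divisible by ``2**depth`` after padding.
    """

    n_input: int = 1024
    depth: int = 4
    base_channels: int = 32
    max_channels: int = 128
    kernel_size: int = 3
    attention: bool = True
    reduction: int = 8
    sa_kernel: int = 7
    residual: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 8:
            raise ConfigError(f"base_channels must be >= 8, got {self.base_channels}")
        if self.n_input < 2 ** self.depth:
            raise ConfigError(
                f"n_input {self.n_input} too short for depth {self.depth}")
        if self.kernel_size % 2 != 1:
            raise ConfigError("kernel_size must be odd")

    def channels(self, level: int) -> int:
        return min(self.base_channels * 2 ** level, self.max_channels)


def pad_length(n: int, depth: int) -> int:
    mult = 2 ** depth
    return ((n + mult - 1) // mult) * mult


def _pad_batch(x: np.ndarray, depth: int) -> tuple[np.ndarray, int, int]:
    n = x.shape[-1]
    np_ = pad_length(n, depth)
    left = (np_ - n) // 2
    right = np_ - n - left
    if left or right:
        x = np.pad(x, ((0, 0), (left, right)))
    return x, left, n


class CoefficientPredictor:
    """Interface: batched coefficient-to-coefficient map with the padding policy.

    ``predict`` takes a (B, N) array, symmetrically zero-pads each row to the
    next multiple of ``2**depth``, runs the concrete ``_forward_padded`` and
    crops the result back to N.
    """

    depth: int = 0

    def predict(self, coeffs: np.ndarray) -> np.ndarray:
        x = np.asarray(coeffs, dtype=float)
        if x.ndim != 2:
            raise ShapeError(f"expected a (batch, N) array, got shape {x.shape}")
        xp, left, n = _pad_batch(x, self.depth)
        out = self._forward_padded(xp.astype(nn.DTYPE))
        return np.asarray(out, dtype=float)[:, left:left + n]

    def _forward_padded(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class AttentionUNet(CoefficientPredictor):
    """The trainable network; see the module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.depth = cfg.depth
        rng = np.random.default_rng(cfg.seed)
        k, att, red, sak = cfg.kernel_size, cfg.attention, cfg.reduction, cfg.sa_kernel

        self.enc_blocks: list[nn.ConvBlock] = []
        self.pools: list[nn.MaxPool2] = []
        c_in = 1
        for lvl in range(cfg.depth):
            c_out = cfg.channels(lvl)
            self.enc_blocks.append(nn.ConvBlock(c_in, c_out, k, rng, att, red, sak))
            self.pools.append(nn.MaxPool2())
            c_in = c_out
        self.bottleneck = nn.ConvBlock(c_in, cfg.channels(cfg.depth), k, rng, att, red, sak)

        self.up_convs: list[nn.UpConv2] = []
        self.dec_blocks: list[nn.ConvBlock] = []
        c_prev = cfg.channels(cfg.depth)
        for lvl in reversed(range(cfg.depth)):
            c_skip = cfg.channels(lvl)
            self.up_convs.append(nn.UpConv2(c_prev, c_skip, rng))
            self.dec_blocks.append(nn.ConvBlock(2 * c_skip, c_skip, k, rng, att, red, sak))
            c_prev = c_skip
        self.final = nn.Conv1d(cfg.channels(0), 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[nn.Layer]:
        return [*self.enc_blocks, self.bottleneck, *self.up_convs,
                *self.dec_blocks, self.final]

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.all_params())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.all_grads())
        return out

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ShapeError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ShapeError(f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, 1, L) with L divisible by 2**depth; returns (B, 1, L).

        With ``residual`` the convolutional stack predicts a correction to
        the input coefficients: in the DCT domain the noise equals the input
        wherever the (smooth) signal has no energy, so the identity is the
        natural starting point and the network learns the low-frequency
        correction.
        """
        x0 = x
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.up_convs, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = dec.forward(np.concatenate([skip, x], axis=1))
        out = self.final.forward(x)
        return out + x0 if self.cfg.residual else out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy_res = dy if self.cfg.residual else 0.0
        dy = self.final.backward(dy)
        dskips = []
        for up, dec, c_skip in zip(reversed(self.up_convs), reversed(self.dec_blocks),
                                   reversed(self._skip_channels)):
            dcat = dec.backward(dy)
            dskips.append(dcat[:, :c_skip])
            dy = up.backward(dcat[:, c_skip:])
        dy = self.bottleneck.backward(dy)
        # dskips are collected shallow-first; the encoder unwinds deepest-first
        dy_enc = dy
        for block, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                      reversed(dskips)):
            dy_enc = pool.backward(dy_enc) + dskip
            dy_enc = block.backward(dy_enc)
        return dy_enc + dy_res

    def _forward_padded(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x[:, None, :])[:, 0, :]


@dataclass
class TrainedModel:
    """Network weights + config + training provenance, checkpointable to .npz."""

    config: ModelConfig
    network: AttentionUNet
    metadata: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return self.config.depth

    def predict(self, coeffs: np.ndarray) -> np.ndarray:
        return self.network.predict(coeffs)

    def save(self, path) -> None:
        arrays = {f"w{i:04d}": w for i, w in enumerate(self.network.parameters())}
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "metadata": _json_safe(self.metadata),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ConfigError(
                    f"unsupported checkpoint version {meta.get('version')}")
            cfg = ModelConfig(**meta["config"])
            net = AttentionUNet(cfg)
            keys = sorted(k for k in data.files if k.startswith("w"))
            net.set_weights([data[k] for k in keys])
        return cls(cfg, net, meta["metadata"])


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def build_model(cfg: ModelConfig) -> TrainedModel:
    """Deterministically initialize an untrained model from its config seed."""
    return TrainedModel(cfg, AttentionUNet(cfg), metadata={"trained": False})


def predict_noise_coeffs(model, coeffs):
    """Predict noise DCT coefficients for a batch of noisy-spectrum coefficients.

    ``model`` is a TrainedModel or any CoefficientPredictor; ``coeffs`` is a
    (B, N) array or a DctCoeffs whose values are 1-D or 2-D.  Returns the same
    type as the input.
    """
    from .dct import DctCoeffs

    if isinstance(coeffs, DctCoeffs):
        vals = coeffs.values
        squeeze = vals.ndim == 1
        out = model.predict(vals[None] if squeeze else vals)
        return DctCoeffs(out[0] if squeeze else out, coeffs.norm)
    return model.predict(np.asarray(coeffs, dtype=float))


class ZeroPredictor(CoefficientPredictor):
    """Stub that predicts zero noise everywhere (denoising becomes identity)."""

    def __init__(self, depth: int = 0):
        self.depth = depth

    def _forward_padded(self, x: np.ndarray) -> np.ndarray:
        return np.zeros_like(x)


class OraclePredictor(CoefficientPredictor):
    """Stub that returns a stored target batch regardless of input.

    The stored target is held at the unpadded length and padded on the way
    out, so a predict() call exercises the full padding round-trip.
    """

    def __init__(self, target: np.ndarray, depth: int = 0):
        self.target = np.atleast_2d(np.asarray(target, dtype=float))
        self.depth = depth

    def _forward_padded(self, x: np.ndarray) -> np.ndarray:
        t, _, _ = _pad_batch(self.target, self.depth)
        if t.shape != x.shape:
            raise ShapeError(
                f"oracle target shape {t.shape} does not match batch {x.shape}")
        return t
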