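"""Noise-learning training: pair assembly and the SGD loop.

Noise-learning (NL) pairs are built on the fly: a fresh random ground-truth
spectrum is generated at every step, a measured (or simulated) noise spectrum
is added, and the network is trained to map DCT(noisy) to DCT(noise).  The
noise bank is split 80/20 into training and validation pools *before* any
pairing, so no noise spectrum leaks across the split; validation ground-truth
spectra are frozen at run start so the validation loss is comparable across
epochs.

Conventional supervised learning (CSL) uses the same loop on a fixed list of
matched (low-SNR, high-SNR) spectra, with DCT(low - high) as the target; it
exists for the NL-vs-CSL generalization comparison on synthetic data.

Optimization is stochastic gradient descent with momentum under a cosine
annealing learning-rate schedule; the loss is the shared ``evaluation.mse``
applied to coefficient vectors.  The checkpoint returned is the one with the
best validation loss.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, replace

import numpy as np
import scipy.fft

from .aunet import TrainedModel, _pad_batch
from .dct import DctCoeffs, dct_forward
from .errors import ConfigError, ShapeError
from .evaluation import mse
from .noise import NoiseBank
from .synth import (GeneratorConfig, Spectrum, SyntheticSpectrum,
                    generate_gt_spectrum, snr_scale_for_signal)

__all__ = [
    "TrainingPair", "TrainConfig", "make_training_pair",
    "cosine_annealing_lr", "train_nl", "train_csl", "SGDMomentum",
]


@dataclass(frozen=True)
class TrainingPair:
    """DCT coefficients of a normalized noisy spectrum and of its noise."""

    input: DctCoeffs
    target: DctCoeffs
    scale: float

    def __post_init__(self):
        if len(self.input) != len(self.target):
            raise ShapeError("input/target coefficient lengths differ")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults: 200 epochs, SGD momentum 0.9 with initial learning rate 0.05
    annealed to zero by a cosine schedule, batch 32, 80/20 train/validation
    split.  ``steps_per_epoch=None`` means one full pass over the training
    noise pool per epoch.
    """

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    val_fraction: float = 0.2
    steps_per_epoch: int | None = None
    max_val_pairs: int | None = 128
    seed: int = 0
    mode: str = "NL"

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch_size >= 1")
        if self.mode not in ("NL", "CSL"):
            raise ConfigError(f"mode must be 'NL' or 'CSL', got {self.mode!r}")


def cosine_annealing_lr(lr0: float, epoch: int, n_epochs: int) -> float:
    """Cosine annealing from lr0 (epoch 0) to 0 (final epoch)."""
    if n_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + float(np.cos(np.pi * epoch / (n_epochs - 1))))


class SGDMomentum:
    """Classical momentum SGD over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], momentum: float = 0.9):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= lr * g
            p += v


def _normalize(noisy: np.ndarray) -> float:
    scale = float(np.max(np.abs(noisy)))
    return scale if scale > 0 else 1.0


def make_training_pair(noise: np.ndarray, gen_cfg: GeneratorConfig, rng=None) -> TrainingPair:
    """Build one NL pair from a noise vector: fresh GT, compose, normalize, DCT.

    When the generator config carries a ``target_snr_db`` interval the
    ground-truth spectrum is rescaled so the composed spectrum's SNR hits a
    value drawn uniformly from it (the noise stays at instrument scale).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != (gen_cfg.axis.n_points,):
        raise ShapeError(
            f"noise length {noise.shape} does not match axis ({gen_cfg.axis.n_points},)")
    gt = generate_gt_spectrum(gen_cfg, rng)
    if gen_cfg.target_snr_db is not None:
        target = float(rng.uniform(*gen_cfg.target_snr_db))
        gt = gt.scaled(snr_scale_for_signal(gt.clean, noise, target))
    noisy = gt.clean + noise
    scale = _normalize(noisy)
    return TrainingPair(dct_forward(noisy / scale), dct_forward(noise / scale), scale)


def _batch_pairs(noise_rows: np.ndarray, gen_cfg: GeneratorConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pair assembly for a batch of noise rows (B, N)."""
    B, N = noise_rows.shape
    clean = np.empty_like(noise_rows)
    for i in range(B):
        gt = generate_gt_spectrum(gen_cfg, rng)
        c = gt.clean
        if gen_cfg.target_snr_db is not None:
            target = float(rng.uniform(*gen_cfg.target_snr_db))
            c = c * snr_scale_for_signal(c, noise_rows[i], target)
        clean[i] = c
    noisy = clean + noise_rows
    scales = np.max(np.abs(noisy), axis=1)
    scales[scales == 0] = 1.0
    x = scipy.fft.dct(noisy / scales[:, None], type=2, norm="ortho", axis=-1)
    t = scipy.fft.dct(noise_rows / scales[:, None], type=2, norm="ortho", axis=-1)
    return x, t, scales


def _forward_loss(net, x: np.ndarray, t: np.ndarray) -> float:
    """Validation loss without gradient bookkeeping, batched for memory."""
    losses = []
    for i in range(0, len(x), 64):
        pred = net.predict(x[i:i + 64])
        losses.append(mse(t[i:i + 64].ravel(), pred.ravel()))
        n = len(x[i:i + 64])
        losses[-1] *= n
    return float(sum(losses) / len(x))


def _train_loop(model: TrainedModel, draw_batch, val_data, cfg: TrainConfig,
                extra_meta: dict) -> TrainedModel:
    """Shared SGD loop for NL and CSL; ``draw_batch(step_rng)`` yields (x, t)."""
    net = model.network
    opt = SGDMomentum(net.parameters(), cfg.momentum)
    x_val, t_val = val_data
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, net.get_weights())
    n_pad = None
    t0 = time.time()

    for epoch in range(cfg.epochs):
        lr = cosine_annealing_lr(cfg.learning_rate, epoch, cfg.epochs)
        epoch_losses = []
        for x, t in draw_batch(epoch):
            if n_pad is None:
                n_pad = x.shape[1]
            net.zero_grad()
            pred = net.predict(x)
            loss = mse(t.ravel(), pred.ravel())
            # d(mse)/d(pred): 2 (pred - t) / (B * N), back through the pad crop
            dy = (2.0 / pred.size) * (pred - t)
            dyp, _, _ = _pad_batch(dy, net.depth)
            net.backward(dyp.astype(np.float32)[:, None, :])
            opt.step(net.gradients(), lr)
            epoch_losses.append(loss)
        val_loss = _forward_loss(net, x_val, t_val)
        history["train_loss"].append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best[0]:
            best = (val_loss, net.get_weights())

    if cfg.epochs > 0:
        net.set_weights(best[1])
    model.metadata = {
        "trained": cfg.epochs > 0,
        "mode": cfg.mode,
        "epochs": cfg.epochs,
        "loss_history": history,
        "best_val_loss": None if np.isinf(best[0]) else float(best[0]),
        "train_config": asdict(cfg),
        "wall_time_s": time.time() - t0,
        **extra_meta,
    }
    return model


def train_nl(model: TrainedModel, noise_bank: NoiseBank, gen_cfg: GeneratorConfig,
             train_cfg: TrainConfig) -> TrainedModel:
    """Noise-learning training against a noise bank.

    The bank's columns are split (1 - val_fraction)/val_fraction into
    disjoint train/validation pools.  Training pairs use freshly generated
    ground truth every step; validation pairs are frozen at run start.
    """
    if train_cfg.mode != "NL":
        train_cfg = replace(train_cfg, mode="NL")
    n = noise_bank.n_spectra
    n_val = max(1, int(round(train_cfg.val_fraction * n)))
    n_train = n - n_val
    if n_train < 1:
        raise ConfigError(f"bank of {n} spectra leaves no training pool")

    root = np.random.default_rng(train_cfg.seed)
    split_rng, val_rng, train_rng = root.spawn(3)
    perm = split_rng.permutation(n)
    train_idx, val_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train_pool = noise_bank.matrix[:, train_idx].T.copy()
    val_pool = noise_bank.matrix[:, val_idx].T.copy()

    # loss monitoring may use a (seeded) subset of the validation pool; the
    # 80/20 noise split itself is untouched and remains disjoint
    if train_cfg.max_val_pairs is not None and len(val_pool) > train_cfg.max_val_pairs:
        sel = val_rng.choice(len(val_pool), size=train_cfg.max_val_pairs,
                             replace=False)
        val_pool = val_pool[np.sort(sel)]

    x_val, t_val, _ = _batch_pairs(val_pool, gen_cfg, val_rng)

    steps = train_cfg.steps_per_epoch or int(np.ceil(n_train / train_cfg.batch_size))

    def draw_batch(epoch: int):
        for _ in range(steps):
            rows = train_pool[train_rng.integers(0, n_train, size=train_cfg.batch_size)]
            x, t, _ = _batch_pairs(rows, gen_cfg, train_rng)
            yield x, t

    return _train_loop(model, draw_batch, (x_val, t_val), train_cfg, {
        "n_noise_train": int(n_train),
        "n_noise_val": int(n_val),
        "train_indices": train_idx.tolist(),
        "val_indices": val_idx.tolist(),
        "generator_config": asdict(gen_cfg),
    })


def _spectrum_values(s) -> np.ndarray:
    if isinstance(s, Spectrum):
        return s.intensities
    if isinstance(s, SyntheticSpectrum):
        return s.clean
    return np.asarray(s, dtype=float)


def train_csl(model: TrainedModel, pairs, train_cfg: TrainConfig) -> TrainedModel:
    """Conventional supervised training on fixed (low-SNR, high-SNR) pairs.

    The target is DCT(low - high): the residual noise of each fixed pair.
    """
    if train_cfg.mode != "CSL":
        train_cfg = replace(train_cfg, mode="CSL")
    lows, highs = [], []
    for pair in pairs:
        if len(pair) != 2:
            raise ShapeError("each CSL item must be a (low, high) pair")
        lo, hi = (_spectrum_values(p) for p in pair)
        if lo.shape != hi.shape:
            raise ShapeError("paired spectra must share their axis")
        lows.append(lo)
        highs.append(hi)
    low = np.asarray(lows)
    high = np.asarray(highs)
    n = len(low)
    if n < 2:
        raise ConfigError("need at least 2 pairs")

    scales = np.max(np.abs(low), axis=1)
    scales[scales == 0] = 1.0
    x_all = scipy.fft.dct(low / scales[:, None], type=2, norm="ortho", axis=-1)
    t_all = scipy.fft.dct((low - high) / scales[:, None], type=2, norm="ortho", axis=-1)

    root = np.random.default_rng(train_cfg.seed)
    split_rng, train_rng = root.spawn(2)
    n_val = max(1, int(round(train_cfg.val_fraction * n)))
    perm = split_rng.permutation(n)
    tr, va = perm[:-n_val], perm[-n_val:]
    if len(tr) < 1:
        raise ConfigError("no training pairs left after the split")

    steps = train_cfg.steps_per_epoch or int(np.ceil(len(tr) / train_cfg.batch_size))

    def draw_batch(epoch: int):
        order = train_rng.permutation(len(tr))
        for s in range(steps):
            sel = tr[order[(s * train_cfg.batch_size) % len(tr):][:train_cfg.batch_size]]
            if len(sel) == 0:
                sel = tr[order[:train_cfg.batch_size]]
            yield x_all[sel], t_all[sel]

    return _train_loop(model, draw_batch, (x_all[va], t_all[va]), train_cfg, {
        "n_pairs_train": int(len(tr)),
        "n_pairs_val": int(len(va)),
    })
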