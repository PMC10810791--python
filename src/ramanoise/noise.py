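"""Instrument-noise banks: simulation and SVD-based estimation.

A noise bank is a matrix ``S`` of m channels x n spectra acquired on a
Raman-inactive reference (a smooth Au film on the real instrument).  Such
spectra contain a large smooth background (photoluminescence + reflected
light) plus the additive instrumental noise: photon shot noise, detector
readout noise and dark-current noise.  Singular value decomposition separates
the two: the leading component(s) capture the low-rank background, and
removing them leaves the noise,

    Noise = S - sum_{j in J} sigma_j * u_j * v_j^T,

with J the background component index set (default {1}: the first component
carries the vast majority of the background).

The simulator in this module is a synthetic stand-in for the Au-film
measurement, so the whole pipeline runs without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ParameterError, ShapeError
from .synth import SpectralAxis, default_axis

__all__ = [
    "NoiseBank",
    "NoiseSimConfig",
    "SvdDecomposition",
    "simulate_noise_bank",
    "svd_decompose",
    "estimate_noise_svd",
    "select_background_components",
    "sample_noise",
    "sample_noise_batch",
]


@dataclass(frozen=True)
class NoiseBank:
    """m x n matrix of noise(-contaminated) spectra; spectra are columns.

    ``integration_times_s`` records the per-column acquisition time;
    ``metadata`` carries any further acquisition details (laser power etc.).
    """

    matrix: np.ndarray
    axis: SpectralAxis
    integration_times_s: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ShapeError(f"bank matrix must be 2-D, got {m.ndim}-D")
        if m.shape[0] != self.axis.n_points:
            raise ShapeError(
                f"bank has {m.shape[0]} channels but axis has {self.axis.n_points}")
        if m.shape[1] < 2:
            raise ShapeError("bank needs at least 2 spectra")
        if not np.all(np.isfinite(m)):
            raise ParameterError("bank contains non-finite entries")
        object.__setattr__(self, "matrix", m)
        if self.integration_times_s is not None:
            t = np.asarray(self.integration_times_s, dtype=float)
            if t.shape != (m.shape[1],):
                raise ShapeError("integration_times_s length does not match n spectra")
            object.__setattr__(self, "integration_times_s", t)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class NoiseSimConfig:
    """Synthetic Au-film-like acquisition: smooth background + three noise sources.

    background_level
        Background counts per second at the background-shape maximum; each
        column's mean is ``background_level * t * shape(x)``.
    readout_sigma
        Gaussian readout noise, counts RMS (integration-time independent).
    dark_rate
        Dark-current rate, counts/s; contributes to the Poisson shot term.
    integration_times_s / n_per_condition
        Acquisition times and number of spectra per time.
    """

    axis: SpectralAxis = field(default_factory=default_axis)
    background_level: float = 1000.0
    readout_sigma: float = 3.0
    dark_rate: float = 10.0
    integration_times_s: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    n_per_condition: int = 500
    seed: int | None = None

    def __post_init__(self):
        if self.background_level < 0 or self.readout_sigma < 0 or self.dark_rate < 0:
            raise ConfigError("noise levels must be >= 0")
        if any(t <= 0 for t in self.integration_times_s):
            raise ConfigError("integration times must be > 0")
        if self.n_per_condition < 1:
            raise ConfigError("n_per_condition must be >= 1")


def background_shape(axis: SpectralAxis) -> np.ndarray:
    """Smooth photoluminescence-like background profile, normalized to max 1."""
    x = axis.grid
    u = (x - x[0]) / (x[-1] - x[0])
    shape = 0.3 + 0.7 * np.exp(-(((u - 0.45) / 0.35) ** 2))
    return shape / shape.max()


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_noise_bank(cfg: NoiseSimConfig, rng=None) -> NoiseBank:
    """Simulate a noise bank column by column.

    Each column is ``bg(t) + [Poisson(bg(t) + dark*t) - (bg(t) + dark*t)]
    + Normal(0, readout_sigma)`` with ``bg(t) = background_level * t * shape``.
    Columns are independent; the draw is reproducible from the seed.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    shape = background_shape(cfg.axis)
    m = cfg.axis.n_points
    cols, times = [], []
    for t in cfg.integration_times_s:
        bg = cfg.background_level * t * shape
        lam = bg + cfg.dark_rate * t
        for _ in range(cfg.n_per_condition):
            shot = rng.poisson(lam).astype(float) - lam if lam.max() > 0 else np.zeros(m)
            readout = rng.normal(0.0, cfg.readout_sigma, size=m) if cfg.readout_sigma > 0 \
                else np.zeros(m)
            cols.append(bg + shot + readout)
            times.append(t)
    matrix = np.column_stack(cols)
    return NoiseBank(matrix, cfg.axis, np.asarray(times),
                     metadata={"simulated": True})


@dataclass(frozen=True)
class SvdDecomposition:
    """Thin SVD of a bank: S = U diag(s) V^T with singular values descending."""

    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray
    background_indices: tuple[int, ...] = (1,)

    @property
    def rank(self) -> int:
        return len(self.s)


def svd_decompose(bank: NoiseBank) -> SvdDecomposition:
    u, s, vt = np.linalg.svd(bank.matrix, full_matrices=False)
    return SvdDecomposition(u, s, vt)


def _validate_components(J, rank: int) -> tuple[int, ...]:
    J = tuple(int(j) for j in J)
    if len(J) == 0:
        raise ParameterError("component index set J must be non-empty")
    for j in J:
        if not 1 <= j <= rank:
            raise IndexError(f"component index {j} out of range 1..{rank}")
    return J


def estimate_noise_svd(bank: NoiseBank, J=(1,)) -> NoiseBank:
    """Remove the background components J (1-based) from a measured bank.

    Returns a noise-only bank of the same shape: the measured matrix minus the
    rank-|J| background reconstruction.  The default J = {1} removes the first
    component, which carries almost all of the smooth background.
    """
    dec = svd_decompose(bank)
    J = _validate_components(J, dec.rank)
    background = np.zeros_like(bank.matrix)
    for j in J:
        background += dec.s[j - 1] * np.outer(dec.u[:, j - 1], dec.vt[j - 1])
    return NoiseBank(bank.matrix - background, bank.axis,
                     bank.integration_times_s,
                     metadata={**bank.metadata, "svd_components_removed": J})


def select_background_components(bank: NoiseBank, threshold: float = 0.8,
                                 max_components: int | None = None) -> tuple[int, ...]:
    """Automatic surrogate for manual inspection of the singular vectors.

    Background components vary smoothly across the acquisition sequence, so
    their right-singular vectors have high lag-1 autocorrelation; noise
    components do not.  Components with autocorrelation above ``threshold``
    are flagged as background.  Falls back to {1} if none qualify.
    """
    dec = svd_decompose(bank)
    upper = dec.rank if max_components is None else min(max_components, dec.rank)
    selected = []
    for j in range(1, upper + 1):
        v = dec.vt[j - 1]
        v = v - v.mean()
        denom = float(np.dot(v, v))
        if denom == 0:
            continue
        ac1 = float(np.dot(v[:-1], v[1:])) / denom
        if ac1 > threshold:
            selected.append(j)
    return tuple(selected) if selected else (1,)


def sample_noise_batch(bank: NoiseBank, n: int, rng=None,
                       amplitude_jitter: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Draw ``n`` noise spectra (rows) uniformly from the bank's columns.

    Each draw is optionally scaled by a jitter factor uniform over
    ``amplitude_jitter``; seed-reproducible.
    """
    if bank.n_spectra == 0:
        raise ShapeError("noise bank is empty")
    lo, hi = amplitude_jitter
    if lo > hi:
        raise ParameterError(f"amplitude_jitter interval is empty: {amplitude_jitter}")
    rng = _as_rng(rng)
    idx = rng.integers(0, bank.n_spectra, size=n)
    out = bank.matrix[:, idx].T.copy()
    if (lo, hi) != (1.0, 1.0):
        out *= rng.uniform(lo, hi, size=(n, 1))
    return out


def sample_noise(bank: NoiseBank, rng=None,
                 amplitude_jitter: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Draw one noise spectrum from the bank (see ``sample_noise_batch``)."""
    return sample_noise_batch(bank, 1, rng, amplitude_jitter)[0]
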