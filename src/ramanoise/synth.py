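"""Physics-based synthesis of ground-truth Raman spectra.

Raman line shapes are modelled as pseudo-Voigt profiles — the weighted sum of
a normalized Gaussian and a normalized Lorentzian sharing one full width at
half maximum (FWHM).  A synthetic spectrum is a random superposition of such
peaks on a broad, smooth baseline built from the same profile family, which
emulates fluorescence / photoluminescence backgrounds.  Noisy spectra are
obtained by plain addition of an instrument-noise vector: the noise model is
purely additive, so clean + noise decompositions stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ParameterError, ShapeError

__all__ = [
    "SpectralAxis",
    "PeakParams",
    "GeneratorConfig",
    "SyntheticSpectrum",
    "Spectrum",
    "gaussian",
    "lorentzian",
    "pseudo_voigt",
    "generate_gt_spectrum",
    "compose_noisy",
    "snr_scale_for_noise",
    "snr_scale_for_signal",
    "default_axis",
]

#: Gaussian fraction of the pseudo-Voigt profile used throughout this work.
DEFAULT_RHO = 0.6785

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform wavenumber grid in cm^-1.

    Parameters
    ----------
    start_cm1
        Wavenumber of the first channel.
    step_cm1
        Channel spacing; must be positive.
    n_points
        Number of channels; at least 16.
    """

    start_cm1: float
    step_cm1: float
    n_points: int

    def __post_init__(self):
        if self.step_cm1 <= 0:
            raise ParameterError(f"step_cm1 must be > 0, got {self.step_cm1}")
        if self.n_points < 16:
            raise ParameterError(f"n_points must be >= 16, got {self.n_points}")

    @property
    def stop_cm1(self) -> float:
        return self.start_cm1 + self.step_cm1 * (self.n_points - 1)

    @property
    def grid(self) -> np.ndarray:
        return self.start_cm1 + self.step_cm1 * np.arange(self.n_points)

    @classmethod
    def from_range(cls, start_cm1: float, stop_cm1: float, n_points: int) -> "SpectralAxis":
        if n_points < 2:
            raise ParameterError("n_points must be >= 2")
        return cls(start_cm1, (stop_cm1 - start_cm1) / (n_points - 1), n_points)

    @classmethod
    def from_grid(cls, grid: np.ndarray, rtol: float = 1e-6) -> "SpectralAxis":
        grid = np.asarray(grid, dtype=float)
        steps = np.diff(grid)
        if len(steps) == 0 or not np.allclose(steps, steps[0], rtol=rtol, atol=1e-12):
            raise ParameterError("grid is not uniformly spaced")
        return cls(float(grid[0]), float(steps[0]), len(grid))


def default_axis() -> SpectralAxis:
    """1024 channels spanning 0-1600 cm^-1 (~1.56 cm^-1/pixel).

    A power-of-two length simplifies the encoder/decoder pooling of the
    denoising network; the sampling density is configurable to match any
    instrument (e.g. 1.2 cm^-1/pixel for a high-dispersion grating).
    """
    return SpectralAxis.from_range(0.0, 1600.0, 1024)


@dataclass(frozen=True)
class PeakParams:
    """One Raman peak: amplitude (area scale), position mu and FWHM w (cm^-1)."""

    amplitude: float
    position_cm1: float
    fwhm_cm1: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ParameterError(f"amplitude must be > 0, got {self.amplitude}")
        if self.fwhm_cm1 <= 0:
            raise ParameterError(f"fwhm must be > 0, got {self.fwhm_cm1}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling laws for the random ground-truth spectrum generator.

    Defaults reproduce the preset used for a confocal Raman microscope with a
    0-1600 cm^-1 window: 1-10 peaks, FWHM 5-200 cm^-1, positions 1-1600 cm^-1
    and Gaussian fraction rho = 0.6785.  Peak amplitudes are log-uniform over
    ``amplitude_range`` (relative units) so weak and strong peaks are equally
    represented; the absolute counts scale is set per spectrum, either directly
    (``counts_scale``) or by targeting a signal-to-noise ratio drawn from
    ``target_snr_db`` when the spectrum is paired with a noise vector.

    The baseline is built from the same pseudo-Voigt family: 1-3 very broad
    components (FWHM 300-2000 cm^-1) with amplitudes up to
    ``baseline_amp_factor`` times the strongest peak amplitude.
    """

    axis: SpectralAxis = field(default_factory=default_axis)
    n_peaks_range: tuple[int, int] = (1, 10)
    fwhm_range: tuple[float, float] = (5.0, 200.0)
    fwhm_distribution: str = "uniform"
    position_range: tuple[float, float] = (1.0, 1600.0)
    amplitude_range: tuple[float, float] = (0.1, 1.0)
    rho: float = DEFAULT_RHO
    baseline_enabled: bool = True
    baseline_n_range: tuple[int, int] = (1, 3)
    baseline_fwhm_range: tuple[float, float] = (300.0, 2000.0)
    baseline_amp_factor: float = 3.0
    counts_scale: float = 1.0
    target_snr_db: tuple[float, float] | None = (-5.0, 5.0)
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_peaks_range", "fwhm_range", "position_range",
                     "amplitude_range", "baseline_n_range", "baseline_fwhm_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ConfigError(f"{name} is empty: {(lo, hi)}")
        if self.n_peaks_range[0] < 1:
            raise ConfigError("n_peaks_range lower bound must be >= 1")
        if self.fwhm_range[0] <= 0:
            raise ConfigError("fwhm_range must be positive")
        if self.amplitude_range[0] <= 0:
            raise ConfigError("amplitude_range must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must be in [0, 1], got {self.rho}")
        lo, hi = self.position_range
        if lo < self.axis.start_cm1 - 1e-9 or hi > self.axis.stop_cm1 + 1e-9:
            raise ConfigError(
                f"position_range {self.position_range} exceeds axis "
                f"[{self.axis.start_cm1}, {self.axis.stop_cm1}]")
        if self.counts_scale <= 0:
            raise ConfigError("counts_scale must be > 0")
        if self.fwhm_distribution not in ("uniform", "log-uniform", "mixed"):
            raise ConfigError(
                f"fwhm_distribution must be 'uniform', 'log-uniform' or "
                f"'mixed', got {self.fwhm_distribution!r}")


@dataclass(frozen=True)
class SyntheticSpectrum:
    """A generated ground-truth spectrum: resolved peaks plus smooth baseline."""

    axis: SpectralAxis
    signal: np.ndarray
    baseline: np.ndarray
    peaks: tuple[PeakParams, ...]

    def __post_init__(self):
        if len(self.signal) != self.axis.n_points or len(self.baseline) != self.axis.n_points:
            raise ShapeError("signal/baseline length does not match axis")

    @property
    def clean(self) -> np.ndarray:
        """Signal + baseline — the noise-free spectrum."""
        return self.signal + self.baseline

    def scaled(self, factor: float) -> "SyntheticSpectrum":
        peaks = tuple(replace(p, amplitude=p.amplitude * factor) for p in self.peaks)
        return SyntheticSpectrum(self.axis, self.signal * factor,
                                 self.baseline * factor, peaks)


@dataclass(frozen=True)
class Spectrum:
    """A measured or composed spectrum: wavenumber grid + intensities.

    ``header`` carries free-form comment lines (without the leading '#')
    preserved by the text reader/writer.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    header: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.wavenumbers) != len(self.intensities):
            raise ShapeError("wavenumber and intensity lengths differ")

    def __len__(self) -> int:
        return len(self.intensities)

    @classmethod
    def from_axis(cls, axis: SpectralAxis, intensities: np.ndarray,
                  header: tuple[str, ...] = ()) -> "Spectrum":
        return cls(axis.grid, np.asarray(intensities, dtype=float), header)

    @property
    def axis(self) -> SpectralAxis:
        return SpectralAxis.from_grid(self.wavenumbers)


def _grid_of(axis) -> np.ndarray:
    if isinstance(axis, SpectralAxis):
        return axis.grid
    return np.asarray(axis, dtype=float)


def gaussian(axis, mu: float, w: float) -> np.ndarray:
    """Unit-area Gaussian parametrized by its FWHM ``w``."""
    if w <= 0:
        raise ParameterError(f"FWHM must be > 0, got {w}")
    x = _grid_of(axis)
    sigma = w / _FWHM_TO_SIGMA
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))


def lorentzian(axis, mu: float, w: float) -> np.ndarray:
    """Unit-area Lorentzian parametrized by its FWHM ``w``."""
    if w <= 0:
        raise ParameterError(f"FWHM must be > 0, got {w}")
    x = _grid_of(axis)
    half = w / 2.0
    return (half / np.pi) / ((x - mu) ** 2 + half**2)


def pseudo_voigt(axis, mu: float, w: float, rho: float = DEFAULT_RHO) -> np.ndarray:
    """Pseudo-Voigt profile: rho * Gaussian + (1 - rho) * Lorentzian.

    Both components share the FWHM ``w`` and integrate to one, so the profile
    is unit-area and symmetric about ``mu``.  ``rho`` is the Gaussian weight.
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError(f"rho must be in [0, 1], got {rho}")
    return rho * gaussian(axis, mu, w) + (1.0 - rho) * lorentzian(axis, mu, w)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_gt_spectrum(cfg: GeneratorConfig, rng=None) -> SyntheticSpectrum:
    """Draw one random ground-truth spectrum from the generator's sampling laws.

    The peak count is uniform over ``n_peaks_range``; positions and FWHMs are
    uniform over their ranges; amplitudes are log-uniform.  The baseline uses
    the same construction with its own (broad) ranges.  Fully reproducible
    given the same config and seed/generator.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    grid = cfg.axis.grid

    n_peaks = int(rng.integers(cfg.n_peaks_range[0], cfg.n_peaks_range[1] + 1))
    positions = rng.uniform(*cfg.position_range, size=n_peaks)
    # log-uniform widths oversample narrow peaks (useful for training data);
    # 'mixed' draws each width from either law with equal probability;
    # the default is uniform over the range
    if cfg.fwhm_distribution == "log-uniform":
        fwhms = _log_uniform(rng, *cfg.fwhm_range, n=n_peaks)
    elif cfg.fwhm_distribution == "mixed":
        uni = rng.uniform(*cfg.fwhm_range, size=n_peaks)
        logu = _log_uniform(rng, *cfg.fwhm_range, n=n_peaks)
        fwhms = np.where(rng.random(n_peaks) < 0.5, logu, uni)
    else:
        fwhms = rng.uniform(*cfg.fwhm_range, size=n_peaks)
    amplitudes = _log_uniform(rng, *cfg.amplitude_range, n=n_peaks) * cfg.counts_scale

    signal = np.zeros_like(grid)
    peaks = []
    for amp, mu, w in zip(amplitudes, positions, fwhms):
        signal += amp * pseudo_voigt(grid, mu, w, cfg.rho)
        peaks.append(PeakParams(float(amp), float(mu), float(w)))

    baseline = np.zeros_like(grid)
    if cfg.baseline_enabled:
        n_base = int(rng.integers(cfg.baseline_n_range[0], cfg.baseline_n_range[1] + 1))
        b_pos = rng.uniform(cfg.axis.start_cm1, cfg.axis.stop_cm1, size=n_base)
        b_fwhm = rng.uniform(*cfg.baseline_fwhm_range, size=n_base)
        b_amp = rng.uniform(0.0, cfg.baseline_amp_factor * amplitudes.max(), size=n_base)
        for amp, mu, w in zip(b_amp, b_pos, b_fwhm):
            baseline += amp * pseudo_voigt(grid, mu, w, cfg.rho)

    return SyntheticSpectrum(cfg.axis, signal, baseline, tuple(peaks))


def compose_noisy(gt: SyntheticSpectrum, noise: np.ndarray, scale: float = 1.0) -> Spectrum:
    """Add a noise vector to a ground-truth spectrum: clean + scale * noise.

    Pure addition — no clipping, negative counts are permitted.
    """
    noise = np.asarray(noise, dtype=float)
    if noise.shape != (gt.axis.n_points,):
        raise ShapeError(
            f"noise length {noise.shape} does not match axis ({gt.axis.n_points},)")
    if scale <= 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    return Spectrum.from_axis(gt.axis, gt.clean + scale * noise)


def snr_scale_for_noise(clean: np.ndarray, noise: np.ndarray, target_snr_db: float) -> float:
    """Factor for ``noise`` so that 10*log10(sum(clean^2)/sum((s*noise)^2)) hits the target."""
    p_sig = float(np.sum(np.square(clean)))
    p_noise = float(np.sum(np.square(noise)))
    if p_noise == 0:
        raise ParameterError("noise vector has zero power")
    return float(np.sqrt(p_sig / (p_noise * 10.0 ** (target_snr_db / 10.0))))


def snr_scale_for_signal(clean: np.ndarray, noise: np.ndarray, target_snr_db: float) -> float:
    """Factor for ``clean`` so the composed spectrum has the target SNR vs ``noise``."""
    p_sig = float(np.sum(np.square(clean)))
    p_noise = float(np.sum(np.square(noise)))
    if p_sig == 0:
        raise ParameterError("clean spectrum has zero power")
    return float(np.sqrt(p_noise * 10.0 ** (target_snr_db / 10.0) / p_sig))
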