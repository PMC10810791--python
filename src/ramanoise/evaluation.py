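"""Quantitative metrics and fits used throughout the pipeline.

Spectral metrics
    ``mse``       mean squared error, (1/m) * sum |y - x|^2.
    ``snr_db``    10*log10(sum x^2 / sum (y - x)^2) against a ground truth x;
                  powers are channel sums, so the ratio is identical whether
                  one sums or averages, as long as both are treated alike.

Image metrics
    ``psnr``      10*log10(1 / mean((Y - X)^2)) on images normalized to [0, 1]
                  by the joint maximum of the pair.
    ``ssim``      mean local structural similarity with Gaussian-weighted
                  local statistics (window 11, sigma 1.5, c1 = 0.01^2,
                  c2 = 0.03^2 for unit dynamic range); a 'global' mode uses a
                  single window covering the whole image.

Spatial-resolution analysis
    ``fit_edge_sigmoid``       logistic fit y = I2 + (I1 - I2)/(1 + e^(-a(x-b)))
                               to an edge profile; the FWHM of the first
                               derivative, 2*ln(3 + 2*sqrt(2))/|a|, estimates
                               the spatial resolution.
    ``resolution_over_lines``  mean +/- sd of per-line FWHM estimates.
    ``decay_slope``            ordinary least-squares line y = K*x + b for
                               intensity decay along the scan order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError, ShapeError

__all__ = [
    "mse", "snr_db", "snr_linear", "psnr", "ssim",
    "MetricReport", "ImageMetricReport", "evaluate_spectra", "evaluate_images",
    "SigmoidFit", "fit_edge_sigmoid", "resolution_over_lines",
    "DecayFit", "decay_slope", "LOGISTIC_FWHM_CONST",
]

#: FWHM of the derivative of a unit-rate logistic: 2*ln(3 + 2*sqrt(2)).
LOGISTIC_FWHM_CONST = 2.0 * np.log(3.0 + 2.0 * np.sqrt(2.0))


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x, y) -> float:
    """Mean squared error between a reference x and a test y."""
    x, y = _pair(x, y)
    return float(np.mean(np.square(y - x)))


def snr_linear(x, y) -> float:
    """Linear signal-to-noise ratio: sum(x^2) / sum((y - x)^2)."""
    x, y = _pair(x, y)
    resid = float(np.sum(np.square(y - x)))
    if resid == 0.0:
        warnings.warn("residual power is zero; SNR is infinite", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return float(np.sum(np.square(x))) / resid


def snr_db(x, y) -> float:
    """Signal-to-noise ratio in dB of y relative to the ground truth x."""
    lin = snr_linear(x, y)
    return float("inf") if np.isinf(lin) else 10.0 * float(np.log10(lin))


def psnr(X, Y, normalize: bool = True) -> float:
    """Peak SNR in dB; with ``normalize`` both images are divided by the
    joint maximum so the peak level is 1."""
    X, Y = _pair(X, Y)
    if normalize:
        peak = max(float(X.max()), float(Y.max()))
        if peak <= 0:
            raise ParameterError("images have no positive intensity to normalize by")
        X, Y = X / peak, Y / peak
    err = float(np.mean(np.square(Y - X)))
    if err == 0.0:
        warnings.warn("images are identical; PSNR is infinite", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return 10.0 * float(np.log10(1.0 / err))


def _local_stats(img: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    return gaussian_filter(img, sigma=sigma, truncate=truncate, mode="reflect")


def ssim(X, Y, window: str = "gaussian", win_size: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03, data_range: float | None = None) -> float:
    """Mean structural similarity between two equal-shape images.

    ``window='gaussian'`` (default) computes local means/variances/covariance
    with a Gaussian window (width ``win_size``, ``sigma``); ``window='global'``
    uses a single window spanning the whole image (plain sample statistics),
    which is the direct one-shot application of the SSIM formula.
    Local variances use the unbiased normalization.  ``data_range`` defaults
    to the joint intensity span of the pair (at least 1e-12).
    """
    X, Y = _pair(X, Y)
    if data_range is None:
        data_range = max(float(max(X.max(), Y.max()) - min(X.min(), Y.min())), 1e-12)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    if window == "global":
        n = X.size
        ux, uy = X.mean(), Y.mean()
        cov_norm = n / (n - 1.0)
        vx = cov_norm * (np.mean(X * X) - ux * ux)
        vy = cov_norm * (np.mean(Y * Y) - uy * uy)
        vxy = cov_norm * (np.mean(X * Y) - ux * uy)
        return float(((2 * ux * uy + c1) * (2 * vxy + c2))
                     / ((ux * ux + uy * uy + c1) * (vx + vy + c2)))
    if window != "gaussian":
        raise ParameterError(f"unknown window mode {window!r}")

    truncate = (win_size - 1) / 2.0 / sigma
    ux = _local_stats(X, sigma, truncate)
    uy = _local_stats(Y, sigma, truncate)
    uxx = _local_stats(X * X, sigma, truncate)
    uyy = _local_stats(Y * Y, sigma, truncate)
    uxy = _local_stats(X * Y, sigma, truncate)
    # unbiased normalization of the Gaussian-weighted (co)variances
    npix = win_size ** 2
    cov_norm = npix / (npix - 1.0)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    smap = ((2 * ux * uy + c1) * (2 * vxy + c2)) \
        / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    pad = (win_size - 1) // 2
    interior = smap[tuple(slice(pad, s - pad) for s in smap.shape)]
    return float(interior.mean())


@dataclass(frozen=True)
class MetricReport:
    """Per-spectrum MSE and SNR with their means and standard deviations."""

    mse_values: np.ndarray
    snr_db_values: np.ndarray

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mse_values))

    @property
    def sd_mse(self) -> float:
        return float(np.std(self.mse_values, ddof=1)) if len(self.mse_values) > 1 else 0.0

    @property
    def mean_snr_db(self) -> float:
        return float(np.mean(self.snr_db_values))

    @property
    def sd_snr_db(self) -> float:
        return float(np.std(self.snr_db_values, ddof=1)) if len(self.snr_db_values) > 1 else 0.0


def evaluate_spectra(reference: np.ndarray, test: np.ndarray) -> MetricReport:
    """Row-wise MSE and SNR of ``test`` against ``reference`` (shape (n, m))."""
    reference, test = _pair(np.atleast_2d(reference), np.atleast_2d(test))
    mses = np.mean(np.square(test - reference), axis=1)
    sig = np.sum(np.square(reference), axis=1)
    resid = np.sum(np.square(test - reference), axis=1)
    with np.errstate(divide="ignore"):
        snrs = 10.0 * np.log10(sig / resid)
    return MetricReport(mses, snrs)


@dataclass(frozen=True)
class ImageMetricReport:
    psnr_db: float
    ssim: float
    c1: float = 0.01 ** 2
    c2: float = 0.03 ** 2


def evaluate_images(reference: np.ndarray, test: np.ndarray) -> ImageMetricReport:
    return ImageMetricReport(psnr(reference, test), ssim(reference, test))


# -- spatial resolution ----------------------------------------------------

def _logistic(x, i1, i2, a, b):
    return i2 + (i1 - i2) / (1.0 + np.exp(-a * (x - b)))


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic edge fit; ``fwhm`` is the width of the derivative bell curve."""

    i1: float
    i2: float
    a: float
    b: float
    fwhm: float
    residual_rms: float
    success: bool = True
    residuals: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


def fit_edge_sigmoid(positions, intensities) -> SigmoidFit:
    """Fit a logistic step to an intensity profile across an edge.

    Initialization: plateau levels from the 10th/90th percentiles, inflection
    at the half-crossing, steepness from the central finite-difference slope.
    Rising and falling edges are both handled.  On failure the returned fit
    has ``success=False`` and carries the residual diagnostics.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("positions and intensities must be equal-length 1-D arrays")
    if len(x) < 6:
        raise ParameterError("need at least 6 points spanning the edge")
    order = np.argsort(x)
    x, y = x[order], y[order]

    lo, hi = np.percentile(y, 10.0), np.percentile(y, 90.0)
    mid = 0.5 * (lo + hi)
    j = int(np.argmin(np.abs(y - mid)))
    j = min(max(j, 1), len(x) - 2)
    slope = (y[j + 1] - y[j - 1]) / (x[j + 1] - x[j - 1])
    span = hi - lo if hi > lo else max(abs(y).max(), 1.0)
    a0 = float(np.clip(4.0 * slope / span, -1e3, 1e3))
    if a0 == 0.0:
        a0 = 1.0 / max(x[-1] - x[0], 1e-12)
    b0 = float(x[j])
    # I1 is the limit as a*(x-b) -> +inf
    i1_0, i2_0 = (hi, lo) if slope >= 0 else (lo, hi)

    try:
        popt, _ = curve_fit(_logistic, x, y, p0=[i1_0, i2_0, a0, b0], maxfev=20000)
    except (RuntimeError, ValueError):
        resid = y - _logistic(x, i1_0, i2_0, a0, b0)
        return SigmoidFit(i1_0, i2_0, a0, b0, float("nan"),
                          float(np.sqrt(np.mean(resid**2))), success=False,
                          residuals=resid)
    i1, i2, a, b = (float(v) for v in popt)
    if a == 0.0 or not np.isfinite(a):
        resid = y - _logistic(x, *popt)
        return SigmoidFit(i1, i2, a, b, float("nan"),
                          float(np.sqrt(np.mean(resid**2))), success=False,
                          residuals=resid)
    resid = y - _logistic(x, *popt)
    fwhm = LOGISTIC_FWHM_CONST / abs(a)
    return SigmoidFit(i1, i2, a, b, fwhm, float(np.sqrt(np.mean(resid**2))),
                      success=True, residuals=resid)


def resolution_over_lines(profiles) -> tuple[float, float, list[SigmoidFit]]:
    """Edge-resolution estimate averaged over parallel line profiles.

    ``profiles`` is a sequence of (positions, intensities) pairs.  Returns
    (mean FWHM, sample sd, per-line fits); lines whose fit fails are skipped,
    and an error is raised if every fit fails.
    """
    profiles = list(profiles)
    if len(profiles) < 1:
        raise ParameterError("need at least one line profile")
    fits = [fit_edge_sigmoid(xs, ys) for xs, ys in profiles]
    widths = [f.fwhm for f in fits if f.success]
    if not widths:
        raise FitError("all edge fits failed")
    mean = float(np.mean(widths))
    sd = float(np.std(widths, ddof=1)) if len(widths) > 1 else 0.0
    return mean, sd, fits


@dataclass(frozen=True)
class DecayFit:
    """First-order polynomial fit y = K*x + b (exact least squares)."""

    slope: float
    intercept: float
    residuals: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def decay_slope(intensities, positions=None) -> DecayFit:
    """Least-squares line through intensity vs scan position (or index)."""
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ParameterError("need at least 2 intensity points")
    x = np.arange(len(y), dtype=float) if positions is None \
        else np.asarray(positions, dtype=float)
    if x.shape != y.shape:
        raise ShapeError("positions and intensities must have equal length")
    if np.ptp(x) == 0:
        raise ParameterError("positions are degenerate (all equal)")
    k, b = np.polyfit(x, y, 1)
    return DecayFit(float(k), float(b), y - (k * x + b))
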