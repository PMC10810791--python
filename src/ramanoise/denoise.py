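"""Denoising front-end: apply a trained noise predictor, plus classical baselines.

The noise-learning pipeline for one spectrum is

    denoised = raw - IDCT( model( DCT(raw / s) ) ) * s,      s = max |raw|

i.e. the network predicts the noise coefficients of the amplitude-normalized
spectrum and the predicted noise is subtracted in the signal domain.  The
baseline is deliberately preserved (only noise is removed) and no
non-negativity clamping is applied: noise-subtracted counts may legitimately
go negative.

Hyperspectral cubes are denoised pixel by pixel with the same operation.

Two classical baselines are provided for comparison: Savitzky-Golay local
polynomial smoothing (default order 2, window 15) and multilevel wavelet
shrinkage with block James-Stein ("BlockJS") thresholding of the detail
coefficients (default sym4, level 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
import scipy.fft
from scipy.signal import savgol_filter

from .errors import ParameterError, ShapeError
from .synth import SpectralAxis, Spectrum

__all__ = [
    "HyperCube", "denoise_spectrum", "denoise_batch", "denoise_cube",
    "sg_denoise", "wavelet_denoise", "BLOCKJS_LAMBDA",
]

#: James-Stein block-thresholding constant (the standard lambda*).
BLOCKJS_LAMBDA = 4.50524


@dataclass(frozen=True)
class HyperCube:
    """(rows, cols, bands) intensity cube with a shared wavenumber axis."""

    data: np.ndarray
    axis: SpectralAxis
    pixel_size: float | None = None
    dwell_time: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ShapeError(f"cube must be 3-D (rows, cols, bands), got {d.ndim}-D")
        if d.shape[2] != self.axis.n_points:
            raise ShapeError(
                f"cube has {d.shape[2]} bands but axis has {self.axis.n_points}")
        if d.shape[0] < 1 or d.shape[1] < 1:
            raise ShapeError("cube must have at least one pixel")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _as_values(spectrum) -> tuple[np.ndarray, object]:
    """Return (values, template) where template rebuilds the output type."""
    if isinstance(spectrum, Spectrum):
        return spectrum.intensities, spectrum
    arr = np.asarray(spectrum, dtype=float)
    if arr.ndim != 1:
        raise ShapeError(f"expected a 1-D spectrum, got shape {arr.shape}")
    return arr, None


def _rebuild(template, values: np.ndarray):
    if template is None:
        return values
    return replace(template, intensities=values)


def denoise_batch(model, raw: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Denoise a (B, N) batch of spectra row-wise with a coefficient predictor."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ShapeError(f"expected (batch, N), got shape {raw.shape}")
    out = np.empty_like(raw)
    for i in range(0, len(raw), chunk):
        block = raw[i:i + chunk]
        scales = np.max(np.abs(block), axis=1)
        scales[scales == 0] = 1.0
        coeffs = scipy.fft.dct(block / scales[:, None], type=2, norm="ortho", axis=-1)
        pred = model.predict(coeffs)
        noise = scipy.fft.idct(pred, type=2, norm="ortho", axis=-1) * scales[:, None]
        out[i:i + chunk] = block - noise
    return out


def denoise_spectrum(model, raw):
    """Subtract the model-predicted instrumental noise from one spectrum.

    ``model`` is a TrainedModel or any object with a batched ``predict`` on
    DCT coefficients; ``raw`` is a Spectrum or 1-D array.  Output type
    matches the input.
    """
    values, template = _as_values(raw)
    out = denoise_batch(model, values[None])[0]
    return _rebuild(template, out)


def denoise_cube(model, cube: HyperCube, chunk: int = 64) -> HyperCube:
    """Pixel-wise denoising of a hyperspectral cube; metadata is preserved."""
    r, c, b = cube.shape
    flat = cube.data.reshape(r * c, b)
    out = denoise_batch(model, flat, chunk=chunk)
    return replace(cube, data=out.reshape(r, c, b))


def sg_denoise(raw, order: int = 2, window: int = 15):
    """Savitzky-Golay smoothing (least-squares local polynomial fit).

    Defaults follow common spectroscopy practice: polynomial order 2 with a
    15-channel window.  Edges are handled by mirror padding.
    """
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window <= order:
        raise ParameterError(f"window ({window}) must exceed order ({order})")
    values, template = _as_values(raw)
    if len(values) < window:
        raise ParameterError(f"spectrum shorter than the window ({window})")
    return _rebuild(template, savgol_filter(values, window, order, mode="mirror"))


def _blockjs_shrink(detail: np.ndarray, sigma: float, block_len: int,
                    lam: float) -> np.ndarray:
    """James-Stein shrinkage of one detail band in consecutive blocks."""
    out = detail.copy()
    n = len(detail)
    for start in range(0, n, block_len):
        block = detail[start:start + block_len]
        ell = len(block)
        s2 = float(np.sum(block * block))
        if s2 <= 0:
            out[start:start + block_len] = 0.0
            continue
        factor = max(0.0, 1.0 - lam * ell * sigma * sigma / s2)
        out[start:start + block_len] = factor * block
    return out


def wavelet_denoise(raw, level: int = 3, rule: str = "blockjs",
                    wavelet: str = "sym4", block_length: int | None = None,
                    lam: float = BLOCKJS_LAMBDA):
    """Multilevel wavelet shrinkage with block James-Stein thresholding.

    The spectrum is decomposed to ``level`` detail bands; each band is
    partitioned into consecutive blocks of length floor(log n) (n = spectrum
    length) and every block is shrunk by the James-Stein factor
    (1 - lam * L * sigma^2 / ||block||^2)_+ with the noise scale sigma
    estimated from the finest-level details via the median absolute
    deviation.  Approximation coefficients pass through untouched.
    """
    if rule.lower() != "blockjs":
        raise ParameterError(f"unknown thresholding rule {rule!r}")
    if level < 1:
        raise ParameterError(f"level must be >= 1, got {level}")
    values, template = _as_values(raw)
    n = len(values)
    if n < 2 ** level:
        raise ParameterError(f"spectrum of length {n} too short for level {level}")

    coeffs = pywt.wavedec(values, wavelet, level=level, mode="symmetric")
    sigma = float(np.median(np.abs(coeffs[-1])) / 0.6745)
    if sigma == 0.0:
        return _rebuild(template, values.copy())
    L = block_length if block_length is not None else max(1, int(math.log(n)))
    shrunk = [coeffs[0]] + [_blockjs_shrink(d, sigma, L, lam) for d in coeffs[1:]]
    rec = pywt.waverec(shrunk, wavelet, mode="symmetric")
    return _rebuild(template, rec[:n])
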