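"""Orthonormal 1-D discrete cosine transform (pixel-spatial frequency domain).

The denoiser learns in the DCT domain: spectra are transformed with the
type-II DCT, the network predicts noise coefficients, and the type-III
inverse maps them back.  The orthonormal convention is used so that the
forward/inverse pair is exactly self-consistent (IDCT(DCT(x)) = x) and
energy-preserving (Parseval).  Because the transform is linear, the additive
decomposition of a noisy spectrum carries over exactly:
DCT(clean + noise) = DCT(clean) + DCT(noise) — the algebraic fact the
noise-learning training target relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .errors import ParameterError, ShapeError

__all__ = ["DctCoeffs", "dct_forward", "dct_inverse"]

_NORM = "ortho"


@dataclass(frozen=True)
class DctCoeffs:
    """DCT coefficients with their normalization convention tag.

    ``values`` has the same trailing length as the source signal; leading
    dimensions (batches) are preserved.
    """

    values: np.ndarray
    norm: str = _NORM

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape[-1] < 1:
            raise ShapeError("empty coefficient vector")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[-1]


def _values_of(x) -> np.ndarray:
    if isinstance(x, DctCoeffs):
        if x.norm != _NORM:
            raise ParameterError(
                f"coefficient convention {x.norm!r} does not match {_NORM!r}")
        return x.values
    return np.asarray(x, dtype=float)


def dct_forward(x) -> DctCoeffs:
    """Orthonormal type-II DCT along the last axis.

    Accepts a single spectrum or a batch (..., N); N must be >= 2.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ShapeError(f"input length must be >= 2, got {x.shape[-1]}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("input contains non-finite values")
    return DctCoeffs(scipy.fft.dct(x, type=2, norm=_NORM, axis=-1))


def dct_inverse(coeffs) -> np.ndarray:
    """Exact inverse of ``dct_forward`` (orthonormal type-III DCT)."""
    y = _values_of(coeffs)
    if y.shape[-1] < 2:
        raise ShapeError(f"coefficient length must be >= 2, got {y.shape[-1]}")
    return scipy.fft.idct(y, type=2, norm=_NORM, axis=-1)
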