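"""Spectral pretreatments: Savitzky-Golay smoothing, Gaussian filtering, normalization.

Exactly one method is applied per model run (the pretreatments are compared
as alternatives, not chained). All filters use reflect padding (edge sample
not repeated) so the smoothers stay linear operators of fixed length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

from .io import Hypercube

VALID_METHODS = ("N", "GF", "SG", "none")
VALID_NORM_MODES = ("unit_vector", "minmax", "snv")


@dataclass(frozen=True)
class PreprocessSpec:
    method: str = "SG"
    sg_window: int = 11
    sg_polyorder: int = 2
    gf_sigma: float = 2.0
    norm_mode: str = "unit_vector"
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}, got {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window must be odd and > sg_polyorder "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})"
            )
        if self.gf_sigma <= 0:
            raise ValueError("gf_sigma must be > 0")
        if self.norm_mode not in VALID_NORM_MODES:
            raise ValueError(f"norm_mode must be one of {VALID_NORM_MODES}")
        if self.boundary != "reflect":
            raise ValueError("only reflect boundary handling is supported")

    @property
    def tag(self) -> str:
        """Short label used in tables, e.g. 'SG', 'GF', 'N', 'none'."""
        return self.method

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "gf_sigma": self.gf_sigma,
            "norm_mode": self.norm_mode,
            "boundary": self.boundary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(**d)


def _reflect_pad(x: np.ndarray, half: int) -> np.ndarray:
    # numpy 'reflect' mode: edge sample not repeated
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, half)], mode="reflect")


def savitzky_golay(spectrum: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Least-squares local polynomial smoothing over a centered window.

    Each point is replaced by the value at its position of the degree-
    ``polyorder`` polynomial fit to the surrounding ``window`` samples;
    boundaries are reflect-padded, so output length equals input length.
    Applies along the last axis for 2-D/3-D input.
    """
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if x.shape[-1] < window:
        raise ValueError(f"spectrum length {x.shape[-1]} < window {window}")
    half = window // 2
    # convolution kernel of the central-point SG estimate
    kernel = savgol_coeffs(window, polyorder, deriv=0)
    padded = _reflect_pad(x, half)
    # correlate along the last axis: out[i] = sum_k kernel[k] * padded[i + k]
    windows = np.lib.stride_tricks.sliding_window_view(padded, window, axis=-1)
    return windows @ kernel[::-1]


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian, truncated at ``truncate * sigma``, renormalized to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = max(1, int(truncate * sigma + 0.5))
    k = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-(k**2) / (2.0 * sigma**2))
    return kernel / kernel.sum()


def gaussian_filter(spectrum: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Convolve with a unit-sum Gaussian kernel, reflect boundaries."""
    x = np.asarray(spectrum, dtype=float)
    kernel = gaussian_kernel(sigma)
    half = len(kernel) // 2
    padded = _reflect_pad(x, half)
    windows = np.lib.stride_tricks.sliding_window_view(padded, len(kernel), axis=-1)
    return windows @ kernel[::-1]  # kernel symmetric; reversal kept for convolution semantics


def normalize(spectrum: np.ndarray, mode: str = "unit_vector") -> np.ndarray:
    """Per-spectrum normalization along the last axis.

    unit_vector: x / ||x||_2; minmax: (x - min)/(max - min); snv: (x - mean)/sd.
    Degenerate inputs (zero norm, constant spectrum) raise.
    """
    x = np.asarray(spectrum, dtype=float)
    if mode == "unit_vector":
        norm = np.linalg.norm(x, axis=-1, keepdims=True)
        if np.any(norm == 0):
            raise ValueError("cannot unit-vector normalize a zero spectrum")
        return x / norm
    if mode == "minmax":
        lo = x.min(axis=-1, keepdims=True)
        hi = x.max(axis=-1, keepdims=True)
        if np.any(hi == lo):
            raise ValueError("cannot min-max normalize a constant spectrum")
        return (x - lo) / (hi - lo)
    if mode == "snv":
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("cannot SNV normalize a constant spectrum")
        return (x - mu) / sd
    raise ValueError(f"unknown normalization mode {mode!r}")


def apply_chain(X, spec: PreprocessSpec):
    """Apply the selected pretreatment to each spectrum of a vector/matrix/cube.

    Accepts a 1-D spectrum, an (n, bands) matrix, a (rows, cols, bands) array,
    or a :class:`~hsichem.io.Hypercube`; returns the same shape/type.
    """
    if isinstance(X, Hypercube):
        return Hypercube(apply_chain(X.data, spec), X.wavelengths, kind=X.kind)
    x = np.asarray(X, dtype=float)
    if spec.method == "none":
        return x.copy()
    if spec.method == "SG":
        return savitzky_golay(x, spec.sg_window, spec.sg_polyorder)
    if spec.method == "GF":
        return gaussian_filter(x, spec.gf_sigma)
    if spec.method == "N":
        return normalize(x, spec.norm_mode)
    raise ValueError(f"unknown method {spec.method!r}")
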