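"""Continuous wavelet transform (CWT) features of reflectance curves.

Each spectrum is convolved with scaled copies of a Mexican-hat mother wavelet

    w_f(s, lambda) = sum_k r_k  (1/sqrt(a_s)) psi((k - lambda) / a_s)

over the discrete 1-nm grid, at the four decomposition scales s = 3, 4, 5, 6.
Two scale conventions are supported: ``dyadic`` (a_s = 2**s grid units, the
dominant convention in vegetation-spectroscopy CWT work; default) and
``linear`` (a_s = s).  Boundaries are handled by symmetric (half-sample)
reflection of the signal, so coefficients near 400 and 890 nm are defined but
depend on this extension.

One wavelet feature per wavelength (WF_400 .. WF_889) is then selected on a
training set: for each band the retained scale is the one whose coefficients
correlate most strongly (|Pearson r|) with the target chemistry, ties going
to the smaller scale.  Because the selection uses the target it must be
re-fit inside each cross-validation training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

from .errors import InputError, ScreeningError

DEFAULT_SCALES = (3, 4, 5, 6)


def mexican_hat(t: np.ndarray) -> np.ndarray:
    """Second derivative of a Gaussian, L2-normalized."""
    t = np.asarray(t, float)
    return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1.0 - t**2) * np.exp(-0.5 * t**2)


def scale_width(scale: int, mode: str = "dyadic") -> float:
    """Effective width a_s in grid units for a scale factor s."""
    if scale <= 0:
        raise InputError(f"scale must be positive, got {scale}")
    if mode == "dyadic":
        return float(2.0**scale)
    if mode == "linear":
        return float(scale)
    raise InputError(f"unknown scale mode {mode!r}")


def wavelet_filter(scale: int, mode: str = "dyadic") -> np.ndarray:
    """Sampled, scale-normalized filter psi(j / a) / sqrt(a), j = -J..J."""
    a = scale_width(scale, mode)
    half = int(np.ceil(6.0 * a))  # Mexican hat is negligible beyond ~5 widths
    j = np.arange(-half, half + 1)
    return mexican_hat(j / a) / np.sqrt(a)


@dataclass(frozen=True)
class WaveletCoefficients:
    """CWT coefficients of one spectrum: (n_scales, n_bands)."""

    scales: tuple[int, ...]
    matrix: np.ndarray


def cwt_transform(
    reflectance: np.ndarray,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    mode: str = "dyadic",
) -> WaveletCoefficients:
    """Transform one spectrum; symmetric-reflection boundary handling."""
    r = np.asarray(reflectance, float)
    if r.ndim != 1:
        raise InputError("expected a 1-D reflectance array")
    if not scales:
        raise InputError("scales must be non-empty")
    rows = np.stack([
        correlate1d(r, wavelet_filter(s, mode), mode="reflect") for s in scales
    ])
    return WaveletCoefficients(tuple(scales), rows)


def cwt_matrix(
    reflectance_rows: np.ndarray,
    scales: tuple[int, ...] = DEFAULT_SCALES,
    mode: str = "dyadic",
) -> np.ndarray:
    """CWT of every row: returns (n_samples, n_scales, n_bands)."""
    rows = np.asarray(reflectance_rows, float)
    if rows.ndim != 2:
        raise InputError("expected (n_samples, n_bands) reflectance matrix")
    out = np.empty((rows.shape[0], len(scales), rows.shape[1]))
    for si, s in enumerate(scales):
        out[:, si, :] = correlate1d(rows, wavelet_filter(s, mode), axis=1, mode="reflect")
    return out


@dataclass(frozen=True)
class WaveletFeatureDefinition:
    """Per-band selected scale: WF_lambda = w_f(s*(lambda), lambda)."""

    scales: tuple[int, ...]
    scale_index: np.ndarray  # (n_bands,) index into ``scales``

    @property
    def selected_scales(self) -> np.ndarray:
        return np.asarray(self.scales)[self.scale_index]


def select_wavelet_scales(
    coefficients: np.ndarray, target: np.ndarray, scales: tuple[int, ...] = DEFAULT_SCALES
) -> WaveletFeatureDefinition:
    """Pick, per band, the scale maximizing |Pearson r| with the target.

    *coefficients* is the (n_samples, n_scales, n_bands) training stack.
    Ties break toward the smaller scale (scales are assumed ascending).
    Bands whose coefficients are constant get correlation 0 at that scale.
    """
    c = np.asarray(coefficients, float)
    y = np.asarray(target, float)
    if c.ndim != 3 or c.shape[0] != y.size:
        raise InputError("coefficients must be (n_samples, n_scales, n_bands) matching target")
    if c.shape[0] < 3:
        raise InputError("need at least 3 training samples to select scales")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise ScreeningError("target is constant; correlation undefined")
    cm = c - c.mean(axis=0, keepdims=True)
    num = np.einsum("nsb,n->sb", cm, yc)
    den = np.sqrt((cm**2).sum(axis=0)) * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    # argmax on |r| returns the first (smallest-scale) maximizer on ties
    idx = np.argmax(np.abs(r), axis=0)
    return WaveletFeatureDefinition(tuple(scales), idx)


def wavelet_features(coefficients: np.ndarray, definition: WaveletFeatureDefinition) -> np.ndarray:
    """Apply a scale map to a (n_samples, n_scales, n_bands) stack -> (n_samples, n_bands)."""
    c = np.asarray(coefficients, float)
    bands = np.arange(c.shape[2])
    return c[:, definition.scale_index, bands]


def select_wavelet_features(
    coefficients: np.ndarray, target: np.ndarray, scales: tuple[int, ...] = DEFAULT_SCALES
) -> tuple[WaveletFeatureDefinition, np.ndarray]:
    """Convenience: fit the scale map on *coefficients* and apply it to them."""
    definition = select_wavelet_scales(coefficients, target, scales)
    return definition, wavelet_features(coefficients, definition)


def wf_feature_names(wavelengths: np.ndarray) -> list[str]:
    """WF slot names by wavelength, e.g. WF_675."""
    return [f"WF_{int(w)}" for w in np.asarray(wavelengths)]
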