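"""Harmonic (Fourier-series) decomposition of reflectance curves.

A spectrum on the 490-band grid is treated as one period of a discrete
periodic signal r_k, k = 1..N, and expanded in the real trigonometric basis

    r_k = A0/2 + sum_{n=1..N/2} [ A_n cos(2 pi n k / N) + B_n sin(2 pi n k / N) ]

with coefficients

    A_n = (2/N) sum_k r_k cos(2 pi n k / N)      (cosine amplitude, CA)
    B_n = (2/N) sum_k r_k sin(2 pi n k / N)      (sine amplitude, SA)
    C_n = sqrt(A_n^2 + B_n^2)                    (resultant amplitude, A)
    phi_n = atan2(A_n, B_n)                      (phase, P)

The phase convention follows the resultant form C_n sin(2 pi n k / N + phi_n).
For even N the n = N/2 (Nyquist) cosine coefficient must be halved during
reconstruction, which makes the full-order reconstruction exact.  M = N/2
orders are emitted; on the standard grid that is 245 orders and a flattened
harmonic-feature (HF) block of 4 x 245 = 980 named scalars.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import InputError

HF_BLOCKS = ("CA", "SA", "A", "P")


@lru_cache(maxsize=8)
def _basis(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """(M, N) cosine and sine design matrices with the k = 1..N origin."""
    m = n_points // 2
    k = np.arange(1, n_points + 1)
    n = np.arange(1, m + 1)[:, None]
    arg = 2.0 * np.pi * n * k / n_points
    return np.cos(arg), np.sin(arg)


@dataclass(frozen=True)
class HarmonicDecomposition:
    n_points: int
    a0: float                # 2 x spectrum mean (series convention)
    ca: np.ndarray           # (M,) cosine amplitudes A_n
    sa: np.ndarray           # (M,) sine amplitudes B_n
    amplitude: np.ndarray    # (M,) resultant amplitudes C_n
    phase: np.ndarray        # (M,) phases phi_n in (-pi, pi]

    @property
    def n_orders(self) -> int:
        return self.ca.size


def harmonic_decompose(reflectance: np.ndarray) -> HarmonicDecomposition:
    """Decompose one spectrum into per-order CA / SA / A / P parameters."""
    r = np.asarray(reflectance, float)
    if r.ndim != 1:
        raise InputError("expected a 1-D reflectance array")
    if r.size < 2 or r.size % 2:
        raise InputError(f"number of spectral points must be even and >= 2, got {r.size}")
    a0, ca, sa = _decompose_rows(r[None, :])
    amp = np.hypot(ca, sa)
    phase = np.arctan2(ca, sa)
    return HarmonicDecomposition(r.size, float(a0[0]), ca[0], sa[0], amp[0], phase[0])


def _decompose_rows(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized coefficients for a (n_samples, N) matrix."""
    n_points = rows.shape[1]
    cos_b, sin_b = _basis(n_points)
    scale = 2.0 / n_points
    return scale * rows.sum(axis=1), scale * rows @ cos_b.T, scale * rows @ sin_b.T


def harmonic_reconstruct(decomp: HarmonicDecomposition, n_orders: int) -> np.ndarray:
    """Partial-sum reconstruction using the first *n_orders* harmonics.

    ``n_orders = 0`` returns the constant mean curve; ``n_orders = N/2``
    reproduces the input to numerical precision (Nyquist cosine halved).
    """
    m = decomp.n_orders
    if not 0 <= n_orders <= m:
        raise InputError(f"n_orders must lie in [0, {m}], got {n_orders}")
    cos_b, sin_b = _basis(decomp.n_points)
    ca = decomp.ca[:n_orders].copy()
    if n_orders == m:
        ca[-1] *= 0.5  # Nyquist term appears once, not twice, in the real basis
    return (
        decomp.a0 / 2.0
        + ca @ cos_b[:n_orders]
        + decomp.sa[:n_orders] @ sin_b[:n_orders]
    )


def hf_feature_names(n_orders: int) -> list[str]:
    """Stable HF slot names: CA_1..CA_M, SA_1.., A_1.., P_1.. in block order."""
    return [f"{block}_{n}" for block in HF_BLOCKS for n in range(1, n_orders + 1)]


def flatten_hf(decomp: HarmonicDecomposition) -> pd.Series:
    """Flatten a decomposition into the named HF feature vector (length 4M)."""
    values = np.concatenate([decomp.ca, decomp.sa, decomp.amplitude, decomp.phase])
    return pd.Series(values, index=hf_feature_names(decomp.n_orders))


def hf_matrix(reflectance_rows: np.ndarray) -> pd.DataFrame:
    """HF features for every row of an (n_samples, N) reflectance matrix."""
    rows = np.asarray(reflectance_rows, float)
    if rows.ndim != 2 or rows.shape[1] % 2:
        raise InputError("expected (n_samples, even N) reflectance matrix")
    _, ca, sa = _decompose_rows(rows)
    amp = np.hypot(ca, sa)
    phase = np.arctan2(ca, sa)
    values = np.concatenate([ca, sa, amp, phase], axis=1)
    return pd.DataFrame(values, columns=hf_feature_names(ca.shape[1]))
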