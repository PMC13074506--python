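"""The fused multi-domain feature pool.

On the standard grid the pool concatenates, in fixed order, 490 raw
reflectance bands (R_400..R_889), 980 harmonic features (CA_1..CA_245,
SA_1.., A_1.., P_1..) and 490 wavelet features (WF_400..WF_889) — 1960
uniquely named scalar features per sample.  The wavelet block depends on a
target-fitted scale map, so pools are assembled per training fold in the
leakage-safe pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .harmonics import hf_matrix
from .wavelets import wf_feature_names

DOMAINS = ("R", "HF", "WF")


def r_feature_names(wavelengths: np.ndarray) -> list[str]:
    return [f"R_{int(w)}" for w in np.asarray(wavelengths)]


@dataclass
class FeaturePool:
    """Named per-sample feature matrix with a domain tag per feature."""

    values: pd.DataFrame   # (n_samples, n_features)
    domains: pd.Series     # feature name -> "R" | "HF" | "WF"

    def __post_init__(self):
        if list(self.values.columns) != list(self.domains.index):
            raise InputError("feature names of values and domains disagree")
        if self.values.columns.duplicated().any():
            raise InputError("feature names must be unique")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def domain_counts(self) -> dict[str, int]:
        return {d: int((self.domains == d).sum()) for d in DOMAINS}


def build_feature_pool(
    reflectance: np.ndarray,
    wavelengths: np.ndarray,
    wf_values: np.ndarray,
) -> FeaturePool:
    """Assemble the R + HF + WF pool for an (n_samples, n_bands) matrix.

    *wf_values* is the (n_samples, n_bands) wavelet-feature matrix produced
    by applying a (training-fitted) scale map to the CWT coefficients.
    """
    refl = np.asarray(reflectance, float)
    wf = np.asarray(wf_values, float)
    wl = np.asarray(wavelengths)
    if refl.ndim != 2 or refl.shape[1] != wl.size:
        raise InputError("reflectance must be (n_samples, n_bands)")
    if wf.shape != refl.shape:
        raise InputError("wf_values must match the reflectance shape")

    r_frame = pd.DataFrame(refl, columns=r_feature_names(wl))
    hf_frame = hf_matrix(refl)
    wf_frame = pd.DataFrame(wf, columns=wf_feature_names(wl))
    values = pd.concat([r_frame, hf_frame, wf_frame], axis=1)
    domains = pd.Series(
        ["R"] * r_frame.shape[1] + ["HF"] * hf_frame.shape[1] + ["WF"] * wf_frame.shape[1],
        index=values.columns,
    )
    return FeaturePool(values, domains)
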