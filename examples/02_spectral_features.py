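"""Decompose one reflectance spectrum into harmonic and wavelet features.

The 490-band spectrum becomes 980 harmonic scalars (cosine/sine/resultant
amplitudes and phases of 245 Fourier orders) plus 490 wavelet features
(Mexican-hat CWT coefficients at the per-band best scale).
"""

import numpy as np

from teaspec import (
    SyntheticConfig,
    cwt_matrix,
    flatten_hf,
    generate_dataset,
    harmonic_decompose,
    harmonic_reconstruct,
    select_wavelet_features,
)

table = generate_dataset(SyntheticConfig(samples_per_season=20, seed=3))
fresh = table.select(season="spring", state="fresh")
spectrum = fresh.reflectance[0]

decomp = harmonic_decompose(spectrum)
hf = flatten_hf(decomp)
print(f"harmonic features: {len(hf)} (orders 1..{decomp.n_orders})")
print(f"  mean term A0/2 = {decomp.a0 / 2:.4f} (the spectrum's mean reflectance)")
print(f"  CA_1 = {hf['CA_1']:+.4f}, SA_1 = {hf['SA_1']:+.4f}, A_1 = {hf['A_1']:.4f}")

for m in (5, 30, 245):
    err = np.sqrt(((harmonic_reconstruct(decomp, m) - spectrum) ** 2).mean())
    print(f"  reconstruction RMSE with {m:3d} orders: {err:.2e}")

coeffs = cwt_matrix(fresh.reflectance)
definition, wf = select_wavelet_features(coeffs, fresh.chemistry("polyphenols"))
band_675 = 675 - 400
print(f"\nwavelet features: {wf.shape[1]} per sample; at 675 nm the selected "
      f"scale is s={definition.selected_scales[band_675]} "
      f"(dyadic width {2.0 ** definition.selected_scales[band_675]:.0f} nm)")
print("Low harmonic orders capture the overall curve; wavelet coefficients",
      "localize the chemistry-sensitive absorption features.")
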