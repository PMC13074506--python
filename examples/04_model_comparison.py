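"""Compare the three regressors on one condition under ten-fold CV.

Feature screening, wavelet-scale selection and all preprocessing are re-fit
inside each training fold, so the out-of-fold metrics are leakage-free.
The CNN here uses the narrow desk-scale architecture.
"""

from teaspec import CNNArchitectureConfig, CVConfig, SyntheticConfig, generate_dataset
from teaspec.pipeline import run_condition

table = generate_dataset(SyntheticConfig(samples_per_season=60, seed=11))
fresh_autumn = table.select(season="autumn", state="fresh")

cond = run_condition(
    fresh_autumn,
    "polyphenols",
    models=("xgb", "gpr", "cnn"),
    cv=CVConfig(10, seed=11),
    arch=CNNArchitectureConfig.micro(40),
)

print("autumn / fresh leaves / polyphenols (out-of-fold, n = 60):")
for model, report in cond.reports.items():
    m = report.metrics
    print(f"  {model:4s} R2 = {m.r2:.3f}   RMSE = {m.rmse:.3f} %   RE = {m.re:.2f} %")
print("R2 is the fraction of chemistry variance explained; RMSE/RE are the",
      "prediction errors in percent dry weight and percent relative terms.")
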