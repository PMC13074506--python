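"""Run the full config-driven pipeline on a small synthetic study.

Writes a run directory with the dataset CSV, per-condition screening tables,
out-of-fold predictions and a compiled JSON report including the
season/state pattern flags.
"""

import json
from pathlib import Path

from teaspec import CVConfig, SearchStrategy, SyntheticConfig
from teaspec.pipeline import RunConfig, ScreeningSettings, run_pipeline

config = RunConfig(
    synthetic=SyntheticConfig(samples_per_season=20, seed=13),
    seasons=("spring", "summer"),
    states=("fresh", "powder"),
    indicators=("polyphenols",),
    models=("xgb",),
    cv=CVConfig(5, 13),
    screening=ScreeningSettings(
        dual_strategy=SearchStrategy.strided(32),
        triple_strategy=SearchStrategy.strided(128),
    ),
    output_dir="scratch/example_run",
    seed=13,
)

out = run_pipeline(config)
report = json.loads((Path(out) / "report.json").read_text())
print(f"artifacts in {out}:")
for p in sorted(Path(out).rglob("*")):
    if p.is_file():
        print("  ", p.relative_to(out))
print("\nper-condition metrics:")
for row in report["metrics"]:
    print(f"  {row['season']:7s} {row['state']:7s} {row['model']:4s} "
          f"R2={row['r2']:.3f} RMSE={row['rmse']:.3f}%")
print("\nconfig hash:", report["manifest"]["config_hash"],
      "- rerunning the same config reproduces these numbers exactly.")
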