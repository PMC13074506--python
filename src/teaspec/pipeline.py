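"""Config-driven orchestration: generate -> features -> screen -> train -> report.

The central entry point is :func:`run_condition`, which executes the
leakage-safe modeling protocol for one (season, physical state, indicator)
cell: within each cross-validation training fold it re-fits the wavelet
scale map, re-screens the spectral indices on the fold's training rows only,
assembles that fold's 100-column input matrix and fits the requested models;
validation rows never influence any fitted statistic.  A ``global`` mode
performs one pre-modeling selection on all rows instead, for comparison.

:func:`run_pipeline` loops cells, writes all artifacts (dataset CSV,
screening tables, per-condition predictions, compiled JSON report) into a
run directory stamped with the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import SyntheticConfig, generate_dataset
from .errors import ConfigurationError
from .evaluation import compile_report, compute_metrics, save_report
from .grid import INDICATORS, SEASONS, STATES
from .harmonics import hf_matrix
from .indices import (
    IndexCandidate,
    SearchStrategy,
    build_model_inputs,
    screen_indices,
)
from .io import SampleTable, read_sample_table, write_sample_table
from .models import (
    CNNArchitectureConfig,
    CVConfig,
    ModelReport,
    _cnn_fold,
    _derive_seed,
    _gpr_fold,
    _xgb_fold,
)
from .pool import FeaturePool, r_feature_names
from .wavelets import (
    cwt_matrix,
    select_wavelet_scales,
    wavelet_features,
    wf_feature_names,
)

log = logging.getLogger("teaspec")


@dataclass(frozen=True)
class FeatureSettings:
    wavelet_scales: tuple[int, ...] = (3, 4, 5, 6)
    scale_mode: str = "dyadic"          # or "linear"


@dataclass(frozen=True)
class ScreeningSettings:
    """Search strategies sized for a single-CPU run; ``full`` is available."""

    top_k: int = 10
    dual_strategy: SearchStrategy = SearchStrategy.strided(8)
    triple_strategy: SearchStrategy = SearchStrategy.strided(32)

    def strategies(self) -> dict[int, SearchStrategy]:
        return {2: self.dual_strategy, 3: self.triple_strategy}


@dataclass
class RunConfig:
    synthetic: SyntheticConfig | None = None
    table_path: str | None = None       # alternative to synthetic generation
    seasons: tuple[str, ...] = SEASONS
    states: tuple[str, ...] = STATES
    indicators: tuple[str, ...] = INDICATORS
    models: tuple[str, ...] = ("xgb", "gpr", "cnn")
    cv: CVConfig = field(default_factory=CVConfig)
    arch: CNNArchitectureConfig = field(default_factory=CNNArchitectureConfig.desk_scale)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    screening: ScreeningSettings = field(default_factory=ScreeningSettings)
    selection_mode: str = "per_fold"    # or "global" (pre-modeling selection)
    importance_repeats: int = 0         # > 0 exports permutation importance
    output_dir: str = "runs/latest"
    seed: int = 0

    def __post_init__(self):
        if self.synthetic is None and self.table_path is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.selection_mode not in ("per_fold", "global"):
            raise ConfigurationError("selection_mode must be 'per_fold' or 'global'")
        unknown = set(self.models) - {"xgb", "gpr", "cnn"}
        if unknown:
            raise ConfigurationError(f"unknown models: {sorted(unknown)}")


@dataclass
class ConditionResult:
    season: str
    state: str
    indicator: str
    reports: dict[str, ModelReport]
    fold_candidates: list[list[IndexCandidate]]   # per fold, 100 candidates
    global_matrix: object = None                  # IndexMatrix in global mode


_FOLD_FITTERS = {
    "xgb": lambda xt, yt, xv, yv, seed, arch: _xgb_fold(xt, yt, seed, 1000, 0.05),
    "gpr": lambda xt, yt, xv, yv, seed, arch: _gpr_fold(xt, yt, seed, 0.95),
    "cnn": lambda xt, yt, xv, yv, seed, arch: _cnn_fold(xt, yt, xv, yv, seed, arch),
}


def run_condition(
    table: SampleTable,
    indicator: str,
    models: tuple[str, ...] = ("xgb", "gpr", "cnn"),
    cv: CVConfig = CVConfig(),
    arch: CNNArchitectureConfig | None = None,
    features: FeatureSettings = FeatureSettings(),
    screening: ScreeningSettings = ScreeningSettings(),
    selection_mode: str = "per_fold",
) -> ConditionResult:
    """Leakage-safe ten-fold modeling of one sample subset.

    *table* should already be restricted to one (season, state) cell; the
    rows define the samples entering cross-validation.
    """
    arch = arch or CNNArchitectureConfig.desk_scale()
    refl = table.reflectance
    wl = table.wavelengths
    y = table.chemistry(indicator)
    n = len(y)

    # target-independent blocks, computed once
    coeffs = cwt_matrix(refl, features.wavelet_scales, features.scale_mode)
    r_frame = pd.DataFrame(refl, columns=r_feature_names(wl))
    hf_frame = hf_matrix(refl)

    def pool_for(wf_values: np.ndarray) -> FeaturePool:
        wf_frame = pd.DataFrame(wf_values, columns=wf_feature_names(wl))
        values = pd.concat([r_frame, hf_frame, wf_frame], axis=1)
        domains = pd.Series(
            ["R"] * r_frame.shape[1] + ["HF"] * hf_frame.shape[1] + ["WF"] * wf_frame.shape[1],
            index=values.columns,
        )
        return FeaturePool(values, domains)

    folds = cv.folds(n)
    preds = {m: np.full(n, np.nan) for m in models}
    fold_of_sample = np.full(n, -1)
    fold_metrics = {m: [] for m in models}
    predictors = {m: [] for m in models}
    fold_candidates: list[list[IndexCandidate]] = []

    def fold_matrix(train_rows: np.ndarray):
        wf_def = select_wavelet_scales(
            coeffs[train_rows], y[train_rows], features.wavelet_scales
        )
        pool = pool_for(wavelet_features(coeffs, wf_def))
        ranked = screen_indices(
            pool.values.iloc[train_rows],
            y[train_rows],
            top_k=screening.top_k,
            strategy=screening.strategies(),
        )
        return build_model_inputs(
            ranked, pool, train_index=train_rows, expected_per_formula=screening.top_k
        )

    if selection_mode == "global":
        matrix = fold_matrix(np.arange(n))

    for fi, (train, val) in enumerate(folds):
        t0 = time.perf_counter()
        if selection_mode == "per_fold":
            matrix = fold_matrix(train)
        fold_candidates.append(matrix.candidates)
        x = matrix.values
        fold_of_sample[val] = fi
        for m in models:
            predictor = _FOLD_FITTERS[m](
                x[train], y[train], x[val], y[val], _derive_seed(cv.seed, fi), arch
            )
            p = predictor(x[val])
            preds[m][val] = p
            fold_metrics[m].append(compute_metrics(y[val], p))
            predictors[m].append(predictor)
        log.debug("fold %d done in %.1fs", fi, time.perf_counter() - t0)

    reports = {
        m: ModelReport(
            m,
            y,
            preds[m],
            fold_of_sample,
            compute_metrics(y, preds[m]),
            fold_metrics[m],
            seed=cv.seed,
            config={"selection_mode": selection_mode, "indicator": indicator},
            fold_predictors=predictors[m],
        )
        for m in models
    }
    season = table.frame["season"].iloc[0] if n else "?"
    state = table.frame["state"].iloc[0] if n else "?"
    return ConditionResult(
        season, state, indicator, reports, fold_candidates,
        global_matrix=matrix if selection_mode == "global" else None,
    )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    # dataclasses with non-serializable leaves become plain structures
    return json.loads(json.dumps(d, default=lambda o: getattr(o, "__dict__", str(o))))


def config_hash(config: RunConfig) -> str:
    """Hash of the study definition (the output location is excluded)."""
    d = _config_dict(config)
    d.pop("output_dir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def candidates_frame(candidates: list[IndexCandidate]) -> pd.DataFrame:
    """Ranked-candidate table mirroring the published screening summaries."""
    return pd.DataFrame(
        {
            "index": [c.formula for c in candidates],
            "combination": [", ".join(c.slots) for c in candidates],
            "r2": [c.r2 for c in candidates],
        }
    )


def _export_importance(cond: ConditionResult, config: RunConfig, path: Path) -> None:
    """Top-10 permutation-importance table for the reference model.

    Available for global-selection runs, where one index matrix is shared by
    all folds so importances attach to fixed candidate columns.
    """
    from .models import permutation_importance

    reference = "cnn" if "cnn" in config.models else config.models[0]
    report = cond.reports[reference]
    result = permutation_importance(
        report,
        cond.global_matrix.values,
        report.observed,
        CVConfig(config.cv.n_folds, report.seed),
        n_repeats=config.importance_repeats,
        seed=config.seed,
    )
    top = result.top(10)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "index": [cond.global_matrix.candidates[j].label for j in top],
            "importance": result.scores[top],
            "spread": result.spread[top],
        }
    ).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured study end to end; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "screening").mkdir(exist_ok=True)
    (out / "predictions").mkdir(exist_ok=True)
    started = time.time()

    if config.table_path is not None:
        table = read_sample_table(config.table_path)
        log.info("loaded %d rows from %s", len(table), config.table_path)
    else:
        table = generate_dataset(config.synthetic)
        write_sample_table(table, out / "dataset.csv")
        log.info("generated %d rows (seed %d)", len(table), config.synthetic.seed)

    results: dict[tuple, ModelReport] = {}
    for season in config.seasons:
        for state in config.states:
            subset = table.select(season=season, state=state)
            if len(subset) == 0:
                continue
            for indicator in config.indicators:
                t0 = time.perf_counter()
                cond = run_condition(
                    subset,
                    indicator,
                    models=config.models,
                    cv=CVConfig(config.cv.n_folds, _derive_seed(config.seed, 1)),
                    arch=config.arch,
                    features=config.features,
                    screening=config.screening,
                    selection_mode=config.selection_mode,
                )
                tag = f"{season}_{state}_{indicator}"
                candidates_frame(cond.fold_candidates[0]).to_csv(
                    out / "screening" / f"{tag}.csv", index=False
                )
                if config.importance_repeats > 0 and cond.global_matrix is not None:
                    _export_importance(cond, config, out / "importance" / f"{tag}.csv")
                pred_frame = pd.DataFrame(
                    {
                        "sample_id": subset.frame["sample_id"],
                        "observed": cond.reports[config.models[0]].observed,
                        "fold": cond.reports[config.models[0]].fold_of_sample,
                    }
                )
                for m, rep in cond.reports.items():
                    pred_frame[f"pred_{m}"] = rep.predictions
                    results[(season, state, indicator, m)] = rep
                pred_frame.to_csv(out / "predictions" / f"{tag}.csv", index=False)
                log.info("condition %s done in %.1fs", tag, time.perf_counter() - t0)

    reference = "cnn" if "cnn" in config.models else config.models[0]
    report = compile_report(results, reference_model=reference)
    report["manifest"] = {
        "config": _config_dict(config),
        "config_hash": config_hash(config),
        "master_seed": config.seed,
        "runtime_s": round(time.time() - started, 1),
    }
    save_report(report, out / "report.json")
    return out


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file of overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    simple = (
        "table_path", "seasons", "states", "indicators", "models",
        "selection_mode", "importance_repeats", "output_dir", "seed",
    )
    for key in simple:
        if key in raw:
            val = raw[key]
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    if "synthetic" in raw:
        kwargs["synthetic"] = SyntheticConfig(**raw["synthetic"])
    if "cv" in raw:
        kwargs["cv"] = CVConfig(**raw["cv"])
    if "arch" in raw:
        arch = dict(raw["arch"])
        for k in ("kernel_sizes", "channels", "strides"):
            if k in arch:
                arch[k] = tuple(arch[k])
        kwargs["arch"] = CNNArchitectureConfig(**arch)
    if "features" in raw:
        feats = dict(raw["features"])
        if "wavelet_scales" in feats:
            feats["wavelet_scales"] = tuple(feats["wavelet_scales"])
        kwargs["features"] = FeatureSettings(**feats)
    if "screening" in raw:
        sc = dict(raw["screening"])
        for k in ("dual_strategy", "triple_strategy"):
            if k in sc:
                sc[k] = SearchStrategy(**sc[k])
        kwargs["screening"] = ScreeningSettings(**sc)
    return RunConfig(**kwargs)
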