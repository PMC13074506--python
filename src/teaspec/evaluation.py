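"""Accuracy metrics, group-comparison statistics and spectral PCA.

Metrics follow the chemometric conventions used throughout the package:

    R^2   = 1 - SSE / SST
    RMSE  = sqrt( (1/n) sum (P_i - O_i)^2 )              [% units of the target]
    RE    = 100 * sqrt( (1/n) sum ((P_i - O_i)/O_i)^2 )  [%]

RE is the root-mean-square relative error; a ``literal_re`` flag computes the
plain mean of squared relative errors (x100) instead, for comparison with
sources that print the expression without the root.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError
from .grid import SEASONS, STATES


@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float
    re: float
    n: int


def compute_metrics(observed, predicted, literal_re: bool = False) -> MetricSet:
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if o.shape != p.shape or o.ndim != 1 or o.size < 2:
        raise InputError("observed/predicted must be equal-length 1-D arrays with n >= 2")
    if np.any(o == 0):
        raise InputError("observed value of 0 makes the relative error undefined")
    sst = float(((o - o.mean()) ** 2).sum())
    sse = float(((p - o) ** 2).sum())
    # R^2 is undefined for a constant observed vector; reported as NaN so
    # RMSE / RE stay available (they do not need observed variation)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(((p - o) ** 2).mean()))
    rel_sq = ((p - o) / o) ** 2
    re = 100.0 * (float(rel_sq.mean()) if literal_re else float(np.sqrt(rel_sq.mean())))
    return MetricSet(r2, rmse, re, o.size)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    labels: list[str]
    means: dict[str, float]
    f_statistic: float
    p_value: float
    tukey: list[dict]          # all pairs, with adjusted p and 0.05 verdict
    letters: dict[str, str]    # compact letter display, 'a' = highest mean


def _compact_letters(labels, means, significant) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups are processed in descending-mean order; each joins every letter
    column whose members it does not differ from significantly, opening a
    new column when none accepts it.
    """
    ordered = sorted(labels, key=lambda g: -means[g])
    columns: list[set] = []
    for g in ordered:
        placed = False
        for col in columns:
            if all(not significant.get(frozenset((g, other)), False) for other in col):
                col.add(g)
                placed = True
        if not placed:
            columns.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        g: "".join(alphabet[i] for i, col in enumerate(columns) if g in col)
        for g in labels
    }


def anova_tukey(values, groups, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD (Tukey-Kramer for unequal n)."""
    v = np.asarray(values, float)
    g = np.asarray([str(x) for x in groups])
    if v.size != g.size:
        raise InputError("values and group labels must have equal length")
    labels = list(dict.fromkeys(g))  # first-appearance order
    samples = [v[g == lab] for lab in labels]
    if len(labels) < 2:
        raise InputError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise InputError("every group needs at least 2 values")

    means = {lab: float(s.mean()) for lab, s in zip(labels, samples)}
    within_ss = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    between_ss = sum(len(s) * (means[lab] - v.mean()) ** 2 for lab, s in zip(labels, samples))

    if within_ss == 0:
        # degenerate: no within-group variation; any mean difference separates
        f_stat = 0.0 if between_ss == 0 else np.inf
        p_val = 1.0 if between_ss == 0 else 0.0
        pairs = [
            {
                "groups": (a, b),
                "p_adj": 1.0 if means[a] == means[b] else 0.0,
                "significant": means[a] != means[b],
            }
            for a, b in itertools.combinations(labels, 2)
        ]
    else:
        k, n = len(labels), v.size
        f_stat = max(between_ss / (k - 1), 0.0) / (within_ss / (n - k))
        p_val = float(stats.f.sf(f_stat, k - 1, n - k))
        hsd = pairwise_tukeyhsd(v, g, alpha=alpha)
        order = list(itertools.combinations(hsd.groupsunique, 2))
        pairs = [
            {"groups": (str(a), str(b)), "p_adj": float(p), "significant": bool(rej)}
            for (a, b), p, rej in zip(order, hsd.pvalues, hsd.reject)
        ]
    significant = {frozenset(p["groups"]): p["significant"] for p in pairs}
    letters = _compact_letters(labels, means, significant)
    return GroupComparison(labels, means, float(f_stat), float(p_val), pairs, letters)


# ---------------------------------------------------------------------------
# PCA of spectra
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray                    # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray                # (n_components, n_bands)


def pca_scores(reflectance, n_components: int | None = None) -> PCAResult:
    """Centered PCA of reflectance rows with a deterministic sign convention:
    each component's largest-magnitude loading is made positive."""
    x = np.asarray(getattr(reflectance, "reflectance", reflectance), float)
    if x.ndim != 2 or len(x) < 3:
        raise InputError("PCA needs a (n_samples >= 3, n_bands) matrix")
    n_components = n_components or min(len(x) - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    components = pca.components_.copy()
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    return PCAResult(scores, pca.explained_variance_ratio_, components)


# ---------------------------------------------------------------------------
# study-style summary report
# ---------------------------------------------------------------------------

def compile_report(results: dict, reference_model: str = "cnn", alpha: float = 0.05) -> dict:
    """Assemble one machine-readable summary of a full run.

    *results* maps ``(season, state, indicator, model)`` to a
    :class:`teaspec.models.ModelReport`.  The summary carries per-condition
    metrics, seasonal / physical-state ANOVAs on the reference model's
    predictions, and pattern flags: is the season effect significant within
    every state, is the state effect non-significant within every season,
    and do predicted seasonal means order summer > autumn > spring.
    """
    rows = []
    by_condition: dict[tuple, dict] = {}
    for (season, state, indicator, model), report in results.items():
        rows.append(
            {
                "season": season,
                "state": state,
                "indicator": indicator,
                "model": model,
                "r2": report.metrics.r2,
                "rmse": report.metrics.rmse,
                "re": report.metrics.re,
                "n": report.metrics.n,
            }
        )
        cond = by_condition.setdefault((season, state, indicator), {})
        if "observed" in cond and not np.array_equal(cond["observed"], report.observed):
            raise InputError(
                f"inconsistent observed values for condition {(season, state, indicator)}: "
                "reports do not come from one run"
            )
        cond["observed"] = report.observed
        cond[model] = report.predictions

    season_tests: dict[str, dict] = {}
    state_tests: dict[str, dict] = {}
    patterns: dict[str, dict] = {}
    indicators = sorted({k[2] for k in results})
    for indicator in indicators:
        season_tests[indicator] = {}
        state_tests[indicator] = {}
        season_ok, state_ok, order_ok = [], [], []
        for state in STATES:
            preds, labels = [], []
            for season in SEASONS:
                cond = by_condition.get((season, state, indicator), {})
                if reference_model in cond:
                    preds.append(cond[reference_model])
                    labels.append(np.repeat(season, len(cond[reference_model])))
            if len(preds) >= 2:
                comp = anova_tukey(np.concatenate(preds), np.concatenate(labels), alpha)
                season_tests[indicator][state] = {
                    "F": comp.f_statistic, "p": comp.p_value, "letters": comp.letters
                }
                season_ok.append(comp.p_value < alpha)
                if set(comp.means) == set(SEASONS):
                    order_ok.append(
                        comp.means["summer"] > comp.means["autumn"] > comp.means["spring"]
                    )
        for season in SEASONS:
            preds, labels = [], []
            for state in STATES:
                cond = by_condition.get((season, state, indicator), {})
                if reference_model in cond:
                    preds.append(cond[reference_model])
                    labels.append(np.repeat(state, len(cond[reference_model])))
            if len(preds) >= 2:
                comp = anova_tukey(np.concatenate(preds), np.concatenate(labels), alpha)
                state_tests[indicator][season] = {"F": comp.f_statistic, "p": comp.p_value}
                state_ok.append(comp.p_value >= alpha)
        patterns[indicator] = {
            "season_effect_in_every_state": bool(season_ok) and all(season_ok),
            "no_state_effect_in_any_season": bool(state_ok) and all(state_ok),
            "summer_gt_autumn_gt_spring": bool(order_ok) and all(order_ok),
        }

    return {
        "metrics": rows,
        "season_anova_on_predictions": season_tests,
        "state_anova_on_predictions": state_tests,
        "pattern_flags": patterns,
        "reference_model": reference_model,
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
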