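"""Spectral-index construction, exhaustive enumeration and screening.

Ten classical vegetation-index formulations are generalized here: any pool
feature (raw band, harmonic parameter or wavelet feature) may occupy any
slot.  Five are dual-feature (DVI, NDVI, RVI, SAVI, MSR) and five are
triple-feature (DCNI, MTCI, MNDI, MCARI2, MEVI); constants are fixed
(SAVI L = 0.5, DCNI offset 0.03, MCARI2 factor 0.2, MEVI 2.5/1.5/1).

Candidates are ranked per formulation by the R-squared of a univariate
linear fit (the squared Pearson correlation between index and target).
Candidates producing any non-finite value on the screening samples —
ratio denominators below 1e-12 in magnitude are treated as non-finite —
are discarded before ranking; ties break lexicographically by slot names.
Enumeration is over unordered pairs for the (anti)symmetric dual formulas
DVI and NDVI, and over ordered tuples for RVI, SAVI, MSR and all triples.

A search strategy (``full``, ``strided(k)``, ``subsample(m, seed)``)
deterministically restricts the pool before enumeration, because the full
ordered triple search over 1960 features is billions of evaluations.
The vectorized screener is oracle-checked against plain enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AssemblyError, ConfigurationError, InputError, ScreeningError
from .pool import FeaturePool

DENOMINATOR_EPS = 1e-12


def _safe_div(num, den):
    bad = np.abs(den) < DENOMINATOR_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / np.where(bad, 1.0, den)
    return np.where(bad, np.nan, out)


def _dvi(a, b):
    return a - b


def _ndvi(a, b):
    return _safe_div(a - b, a + b)


def _rvi(a, b):
    return _safe_div(a, b)


def _savi(a, b, L=0.5):
    return _safe_div((a - b) * (1.0 + L), a + b + L)


def _msr(a, b):
    ratio = _safe_div(a, b)
    arg = ratio + 1.0
    with np.errstate(invalid="ignore"):
        root = np.where(arg > 0, np.sqrt(np.where(arg > 0, arg, 1.0)), np.nan)
    return _safe_div(ratio - 1.0, root)


def _dcni(a, b, c):
    return _safe_div(_safe_div(a - b, b - c), a - c + 0.03)


def _mtci(a, b, c):
    return _safe_div(a - b, b - c)


def _mndi(a, b, c):
    return _safe_div(a - b, (a - b) - (b - c))


def _mcari2(a, b, c):
    return ((a - b) - 0.2 * (a - c)) * _safe_div(a, b)


def _mevi(a, b, c):
    return _safe_div(a - b, a + 2.5 * b - 1.5 * c + 1.0)


@dataclass(frozen=True)
class IndexFormula:
    name: str
    arity: int
    func: callable
    ordered: bool               # ordered slot tuples vs unordered pairs
    constants: dict | None = None


DUAL_FORMULAS = (
    IndexFormula("DVI", 2, _dvi, ordered=False),
    IndexFormula("NDVI", 2, _ndvi, ordered=False),
    IndexFormula("RVI", 2, _rvi, ordered=True),
    IndexFormula("SAVI", 2, _savi, ordered=True, constants={"L": 0.5}),
    IndexFormula("MSR", 2, _msr, ordered=True),
)
TRIPLE_FORMULAS = (
    IndexFormula("DCNI", 3, _dcni, ordered=True, constants={"offset": 0.03}),
    IndexFormula("MTCI", 3, _mtci, ordered=True),
    IndexFormula("MNDI", 3, _mndi, ordered=True),
    IndexFormula("MCARI2", 3, _mcari2, ordered=True, constants={"factor": 0.2}),
    IndexFormula("MEVI", 3, _mevi, ordered=True, constants={"c1": 2.5, "c2": 1.5, "c3": 1.0}),
)
ALL_FORMULAS = DUAL_FORMULAS + TRIPLE_FORMULAS
FORMULAS_BY_NAME = {f.name: f for f in ALL_FORMULAS}


def evaluate_index(formula: IndexFormula, values) -> np.ndarray:
    """Evaluate one formula on a tuple of feature values (scalars or arrays)."""
    if len(values) != formula.arity:
        raise InputError(
            f"{formula.name} takes {formula.arity} features, got {len(values)}"
        )
    return formula.func(*[np.asarray(v, float) for v in values])


# ---------------------------------------------------------------------------
# search strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchStrategy:
    """Deterministic restriction of the pool before enumeration."""

    kind: str = "full"
    stride: int | None = None
    m: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("full", "strided", "subsample"):
            raise ConfigurationError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "strided" and (self.stride is None or self.stride < 1):
            raise ConfigurationError("strided strategy needs stride >= 1")
        if self.kind == "subsample" and (self.m is None or self.m < 1 or self.seed is None):
            raise ConfigurationError("subsample strategy needs m >= 1 and a seed")

    @classmethod
    def full(cls):
        return cls("full")

    @classmethod
    def strided(cls, stride: int):
        return cls("strided", stride=stride)

    @classmethod
    def subsample(cls, m: int, seed: int):
        return cls("subsample", m=m, seed=seed)

    def restrict(self, feature_names: list[str]) -> list[str]:
        names = list(feature_names)
        if self.kind == "full":
            return names
        if self.kind == "strided":
            return names[:: self.stride]
        rng = np.random.default_rng(self.seed)
        if self.m >= len(names):
            return names
        keep = np.sort(rng.choice(len(names), size=self.m, replace=False))
        return [names[i] for i in keep]


def enumerate_candidates(
    feature_names,
    formulas=ALL_FORMULAS,
    strategy: SearchStrategy = SearchStrategy.full(),
):
    """Yield (formula, slot-name tuple) for every candidate the search visits."""
    names = strategy.restrict(list(feature_names))
    for formula in formulas:
        combo = itertools.permutations if formula.ordered else itertools.combinations
        for slots in combo(names, formula.arity):
            yield formula, slots


# ---------------------------------------------------------------------------
# vectorized screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexCandidate:
    formula: str
    slots: tuple[str, ...]
    r2: float

    @property
    def label(self) -> str:
        return f"{self.formula}({', '.join(self.slots)})"


def _r2_block(block: np.ndarray, yc: np.ndarray, ss_y: float) -> np.ndarray:
    """Screening R^2 for every column of *block* (samples on axis 0).

    Non-finite or constant columns score -inf so they never rank.
    """
    finite = np.isfinite(block).all(axis=0)
    safe = np.where(np.isfinite(block), block, 0.0)
    centered = safe - safe.mean(axis=0)
    cov = np.tensordot(yc, centered, axes=(0, 0))
    ss_i = (centered**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / (ss_i * ss_y)
    valid = finite & (ss_i > 0) & np.isfinite(r2)
    return np.where(valid, np.minimum(r2, 1.0), -np.inf)


def _rank(entries, names, formula, top_k):
    # R^2 quantized to 12 decimals so exact algebraic ties (e.g. the two
    # orderings of MTCI's last two slots, which are affinely related) resolve
    # by the lexicographic slot rule rather than by float round-off
    entries.sort(key=lambda e: (-round(e[0], 12), tuple(names[i] for i in e[1])))
    return [
        IndexCandidate(formula.name, tuple(names[i] for i in e[1]), float(e[0]))
        for e in entries[:top_k]
    ]


def _slab_keep(r2_slab: np.ndarray, top_k: int):
    """Indices of slab entries that could make the global top_k (ties kept)."""
    flat = r2_slab.ravel()
    valid = flat > -np.inf
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.empty(0, dtype=np.intp)
    if n_valid <= top_k:
        return np.nonzero(valid)[0]
    threshold = np.partition(flat, flat.size - top_k)[flat.size - top_k]
    return np.nonzero(flat >= max(threshold, -np.inf) if threshold > -np.inf else valid)[0]


def _screen_dual(X, names, yc, ss_y, formula, top_k, chunk_target=4_000_000):
    n, p = X.shape
    chunk = max(1, int(chunk_target / max(n * p, 1)))
    entries = []
    for start in range(0, p, chunk):
        stop = min(start + chunk, p)
        block = formula.func(X[:, start:stop, None], X[:, None, :])  # (n, ch, p)
        r2 = _r2_block(block, yc, ss_y)
        ii = np.arange(start, stop)[:, None]
        jj = np.arange(p)[None, :]
        invalid = ii == jj
        if not formula.ordered:
            invalid |= jj < ii  # unordered: keep j > i only
        r2 = np.where(invalid, -np.inf, r2)
        keep = _slab_keep(r2, top_k)
        for flat_idx in keep:
            a, b = divmod(int(flat_idx), p)
            entries.append((float(r2[a, b]), (start + a, b)))
    return _rank(entries, names, formula, top_k)


def _screen_triple(X, names, yc, ss_y, formula, top_k, chunk_target=4_000_000):
    n, p = X.shape
    chunk = max(1, int(chunk_target / max(n * p, 1)))
    jj = np.arange(p)
    entries = []
    for i in range(p):
        a_col = X[:, i][:, None, None]
        for start in range(0, p, chunk):
            stop = min(start + chunk, p)
            block = formula.func(a_col, X[:, start:stop, None], X[:, None, :])
            r2 = _r2_block(block, yc, ss_y)  # (ch, p)
            jr = jj[start:stop][:, None]
            kr = jj[None, :]
            invalid = (jr == kr) | (jr == i) | (kr == i)
            r2 = np.where(invalid, -np.inf, r2)
            keep = _slab_keep(r2, top_k)
            width = p
            for flat_idx in keep:
                a, b = divmod(int(flat_idx), width)
                entries.append((float(r2[a, b]), (i, start + a, b)))
    return _rank(entries, names, formula, top_k)


def screen_indices(
    pool: FeaturePool | pd.DataFrame,
    target: np.ndarray,
    formulas=ALL_FORMULAS,
    top_k: int = 10,
    strategy: SearchStrategy | dict = SearchStrategy.full(),
) -> dict[str, list[IndexCandidate]]:
    """Rank candidates per formulation by univariate screening R^2.

    *strategy* may be one :class:`SearchStrategy` for all formulas or a
    mapping ``{arity: strategy}``.  Returns ``{formula name: top-k list}``.
    """
    values = pool.values if isinstance(pool, FeaturePool) else pool
    y = np.asarray(target, float)
    if len(values) != y.size:
        raise InputError("target length must match the pool's sample count")
    if len(values) < 5:
        raise InputError("need at least 5 samples for screening")
    yc = y - y.mean()
    ss_y = float((yc**2).sum())
    if ss_y == 0:
        raise ScreeningError("target is constant; screening R^2 undefined")

    result: dict[str, list[IndexCandidate]] = {}
    for formula in formulas:
        strat = strategy[formula.arity] if isinstance(strategy, dict) else strategy
        names = strat.restrict(list(values.columns))
        X = values[names].to_numpy(float)
        if formula.arity == 2:
            result[formula.name] = _screen_dual(X, names, yc, ss_y, formula, top_k)
        else:
            result[formula.name] = _screen_triple(X, names, yc, ss_y, formula, top_k)
    return result


# ---------------------------------------------------------------------------
# model-input assembly
# ---------------------------------------------------------------------------

@dataclass
class IndexMatrix:
    """Samples x selected-index matrix with per-column candidate metadata."""

    values: np.ndarray
    candidates: list[IndexCandidate]

    @property
    def column_names(self) -> list[str]:
        return [c.label for c in self.candidates]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def build_model_inputs(
    ranked: dict[str, list[IndexCandidate]],
    pool: FeaturePool | pd.DataFrame,
    train_index: np.ndarray | None = None,
    expected_per_formula: int | None = None,
) -> IndexMatrix:
    """Evaluate the screened candidates on a sample set sharing the pool.

    Columns are ordered by formulation registry order (duals first), then by
    screening rank.  Entries that evaluate non-finite on some sample are
    filled with the mean of the column's finite *training* values (rows in
    *train_index*, or all rows when omitted); a column with no finite
    training value raises :class:`AssemblyError`.
    """
    values = pool.values if isinstance(pool, FeaturePool) else pool
    order = [f.name for f in ALL_FORMULAS if f.name in ranked]
    extra = set(ranked) - set(order)
    if extra:
        raise InputError(f"unknown formulations in ranked lists: {sorted(extra)}")

    candidates: list[IndexCandidate] = []
    for name in order:
        cands = ranked[name]
        if expected_per_formula is not None and len(cands) != expected_per_formula:
            raise AssemblyError(
                f"{name}: expected {expected_per_formula} candidates, got {len(cands)}"
            )
        candidates.extend(cands)
    seen = set()
    for c in candidates:
        key = (c.formula, c.slots)
        if key in seen:
            raise AssemblyError(f"duplicate candidate {c.label}")
        seen.add(key)

    n = len(values)
    rows = np.arange(n) if train_index is None else np.asarray(train_index)
    out = np.empty((n, len(candidates)))
    for j, cand in enumerate(candidates):
        formula = FORMULAS_BY_NAME[cand.formula]
        col = evaluate_index(formula, [values[s].to_numpy(float) for s in cand.slots])
        finite_train = col[rows][np.isfinite(col[rows])]
        if finite_train.size == 0:
            raise AssemblyError(f"column {cand.label} has no finite training values")
        out[:, j] = np.where(np.isfinite(col), col, finite_train.mean())
    return IndexMatrix(out, candidates)
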