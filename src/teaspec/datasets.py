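"""Seeded synthetic tea-sample generator.

The analysis in this package was designed around field campaigns in which the
same shoots are measured three times — as fresh canopy leaves, as oven-dried
leaves and as ground powder — in spring, summer and autumn, with polyphenol
and catechin contents assayed by wet chemistry.  No public dataset exists, so
this module emulates the statistical structure that the downstream stages
assume:

* season-specific chemistry drawn from a correlated, range-truncated
  bivariate normal whose means / SDs / ranges follow the study's reported
  seasonal statistics (summer > autumn > spring for both traits);
* one latent sample measured in all three physical states with *identical*
  chemistry and state-specific spectra;
* state-specific spectral continua (dark vegetation curve with a red edge
  for fresh leaves; brown, monotonically rising curve for dried leaves;
  bright, smooth curve for powder) with chemistry-coupled Gaussian
  absorption features — for fresh leaves the polyphenol coupling sits at
  675 nm and is negative (more polyphenols -> lower reflectance);
* a per-measurement multiplicative scatter factor (largest for field fresh
  leaves, smallest for the homogenized powder) plus additive sensor noise.

Everything is a pure function of the master seed: per-stream RNGs are derived
with ``np.random.SeedSequence([seed, stream, ...])`` so any subset of the
dataset can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, InputError
from .grid import SEASONS, STATES, default_grid
from .io import META_COLUMNS, SampleTable, reflectance_columns

# Pooled (across-season mixture) chemistry moments used to standardize
# chemistry before spectral coupling: mean and SD in % dry weight.
POLYPHENOL_REFERENCE = (23.28, 2.61)
CATECHIN_REFERENCE = (18.84, 2.12)


@dataclass(frozen=True)
class ChemistryParams:
    """Seasonal chemistry distribution: truncated bivariate normal margins."""

    season: str
    poly_mean: float
    poly_sd: float
    poly_min: float
    poly_max: float
    cat_mean: float
    cat_sd: float
    cat_min: float
    cat_max: float
    rho: float = 0.6  # polyphenol-catechin correlation (both track season)

    def __post_init__(self):
        for trait in ("poly", "cat"):
            lo = getattr(self, f"{trait}_min")
            hi = getattr(self, f"{trait}_max")
            mu = getattr(self, f"{trait}_mean")
            sd = getattr(self, f"{trait}_sd")
            if not (lo < mu < hi):
                raise ConfigurationError(
                    f"{self.season}/{trait}: need min < mean < max, got {lo}, {mu}, {hi}"
                )
            if sd <= 0:
                raise ConfigurationError(f"{self.season}/{trait}: sd must be > 0")
        if not abs(self.rho) < 1:
            raise ConfigurationError("|rho| must be < 1")


#: Reported seasonal statistics (% dry weight).  The autumn catechin range is
#: not tabulated in the source statistics; mean +/- 3 SD is used as a stand-in.
SEASON_CHEMISTRY: dict[str, ChemistryParams] = {
    "spring": ChemistryParams("spring", 21.54, 1.94, 17.09, 25.70, 17.43, 2.13, 13.27, 23.90),
    "summer": ChemistryParams("summer", 25.82, 1.97, 21.71, 29.03, 20.08, 1.42, 18.04, 24.50),
    "autumn": ChemistryParams("autumn", 22.48, 1.62, 19.41, 25.36, 19.00, 1.83, 13.51, 24.49),
}


@dataclass(frozen=True)
class AbsorptionFeature:
    """Gaussian absorption dip with chemistry-coupled depth.

    depth = base_depth + poly_coupling * z_poly + cat_coupling * z_cat,
    where z_* are chemistry values standardized against the pooled reference
    moments.  A positive coupling deepens the dip for richer samples, i.e.
    produces a *negative* chemistry-reflectance correlation at the center.
    """

    center_nm: float
    width_nm: float
    base_depth: float
    poly_coupling: float = 0.0
    cat_coupling: float = 0.0

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ConfigurationError("absorption width must be > 0")


@dataclass(frozen=True)
class SpectralStateModel:
    """Spectral forward model for one physical state."""

    state: str
    continuum_anchors: tuple[tuple[float, float], ...]
    features: tuple[AbsorptionFeature, ...]
    scatter_sd: float  # SD of log multiplicative scatter factor
    noise_sd: float    # additive per-band noise SD

    def __post_init__(self):
        if any(not (0.0 <= r <= 1.0) for _, r in self.continuum_anchors):
            raise ConfigurationError("continuum anchor reflectance must lie in [0, 1]")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ConfigurationError("noise/scatter SDs must be >= 0")

    def continuum(self, wavelengths: np.ndarray) -> np.ndarray:
        anchors = np.asarray(self.continuum_anchors, float)
        return PchipInterpolator(anchors[:, 0], anchors[:, 1])(wavelengths)


def _vegetation_anchors():
    return (
        (400, 0.060), (450, 0.055), (500, 0.070), (550, 0.140), (600, 0.110),
        (640, 0.115), (675, 0.120), (690, 0.140), (705, 0.190), (720, 0.300),
        (750, 0.460), (800, 0.480), (889, 0.480),
    )


def _dried_anchors():
    return (
        (400, 0.080), (500, 0.120), (550, 0.160), (600, 0.200), (637, 0.220),
        (675, 0.250), (720, 0.330), (780, 0.400), (889, 0.450),
    )


def _powder_anchors():
    return (
        (400, 0.220), (500, 0.320), (550, 0.400), (600, 0.460), (675, 0.500),
        (720, 0.560), (780, 0.620), (889, 0.660),
    )


#: Default forward models.  Coupling strength is ordered fresh > dried >
#: powder, matching the reported ordering of chemistry-reflectance
#: correlations across physical states; the dried-leaf couplings are
#: negative-signed (richer -> brighter), so the dried correlation is positive
#: with its extremum near 637 nm.
STATE_MODELS: dict[str, SpectralStateModel] = {
    "fresh": SpectralStateModel(
        "fresh",
        _vegetation_anchors(),
        (
            AbsorptionFeature(675.0, 22.0, 0.060, poly_coupling=0.016, cat_coupling=0.003),
            AbsorptionFeature(560.0, 30.0, 0.030, poly_coupling=0.002, cat_coupling=0.009),
        ),
        scatter_sd=0.12,
        noise_sd=0.010,
    ),
    "dried": SpectralStateModel(
        "dried",
        _dried_anchors(),
        (
            AbsorptionFeature(637.0, 28.0, 0.055, poly_coupling=-0.010, cat_coupling=-0.002),
            AbsorptionFeature(560.0, 32.0, 0.035, poly_coupling=-0.002, cat_coupling=-0.007),
        ),
        scatter_sd=0.08,
        noise_sd=0.008,
    ),
    "powder": SpectralStateModel(
        "powder",
        _powder_anchors(),
        (
            AbsorptionFeature(675.0, 25.0, 0.050, poly_coupling=0.004, cat_coupling=0.001),
            AbsorptionFeature(560.0, 30.0, 0.030, poly_coupling=0.001, cat_coupling=0.003),
        ),
        scatter_sd=0.04,
        noise_sd=0.006,
    ),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic study."""

    chemistry: dict[str, ChemistryParams] = field(default_factory=lambda: dict(SEASON_CHEMISTRY))
    states: dict[str, SpectralStateModel] = field(default_factory=lambda: dict(STATE_MODELS))
    samples_per_season: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.samples_per_season < 2:
            raise ConfigurationError("samples_per_season must be >= 2")
        if set(self.chemistry) != set(SEASONS):
            raise ConfigurationError(f"chemistry must cover seasons {SEASONS}")
        if set(self.states) != set(STATES):
            raise ConfigurationError(f"states must cover {STATES}")
        if int(self.seed) < 0:
            raise ConfigurationError("seed must be a non-negative integer")


def _stream_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stream RNG: SeedSequence([master, *key])."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


# Stream ids for the counter scheme (documented so subsets reproduce).
_CHEM_STREAM = 0
_SPEC_STREAM = 1


def sample_chemistry(params: ChemistryParams, n: int, seed) -> np.ndarray:
    """Draw *n* correlated (polyphenol, catechin) pairs, % dry weight.

    Pairs come from a bivariate normal with correlation ``params.rho``;
    draws falling outside either trait's [min, max] range are rejected and
    redrawn, so each margin is range-truncated.  Returns an (n, 2) array.
    """
    if n < 0:
        raise InputError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else _stream_rng(seed)
    mean = [params.poly_mean, params.cat_mean]
    cov = [
        [params.poly_sd**2, params.rho * params.poly_sd * params.cat_sd],
        [params.rho * params.poly_sd * params.cat_sd, params.cat_sd**2],
    ]
    out = np.empty((0, 2))
    while len(out) < n:
        draw = rng.multivariate_normal(mean, cov, size=max(2 * (n - len(out)), 16),
                                       method="cholesky")
        ok = (
            (draw[:, 0] >= params.poly_min) & (draw[:, 0] <= params.poly_max)
            & (draw[:, 1] >= params.cat_min) & (draw[:, 1] <= params.cat_max)
        )
        out = np.vstack([out, draw[ok]])
    return out[:n]


def generate_spectrum(
    chem: tuple[float, float],
    model: SpectralStateModel,
    seed,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate one reflectance curve for chemistry ``(polyphenols, catechins)``.

    reflectance = scatter_factor * (continuum - sum of chemistry-coupled
    Gaussian dips) + additive noise, clipped to [0, 1].  Deterministic given
    the seed / Generator.
    """
    poly, cat = float(chem[0]), float(chem[1])
    if not (0 < poly < 100 and 0 < cat < 100):
        raise InputError(f"chemistry out of range: ({poly}, {cat}) % dry weight")
    wl = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    rng = seed if isinstance(seed, np.random.Generator) else _stream_rng(seed)

    z_poly = (poly - POLYPHENOL_REFERENCE[0]) / POLYPHENOL_REFERENCE[1]
    z_cat = (cat - CATECHIN_REFERENCE[0]) / CATECHIN_REFERENCE[1]
    curve = model.continuum(wl)
    for feat in model.features:
        depth = feat.base_depth + feat.poly_coupling * z_poly + feat.cat_coupling * z_cat
        curve = curve - depth * np.exp(-0.5 * ((wl - feat.center_nm) / feat.width_nm) ** 2)
    scatter = np.exp(rng.normal(0.0, model.scatter_sd)) if model.scatter_sd else 1.0
    noise = rng.normal(0.0, model.noise_sd, size=wl.size) if model.noise_sd else 0.0
    return np.clip(scatter * curve + noise, 0.0, 1.0)


def generate_dataset(config: SyntheticConfig | None = None) -> SampleTable:
    """Generate the full synthetic study: seasons x samples x three states.

    Each latent sample appears once per physical state with identical
    chemistry; spectra differ by state.  Fully determined by the master seed.
    """
    config = config or SyntheticConfig()
    wl = default_grid()
    rows = []
    refl = []
    for si, season in enumerate(SEASONS):
        params = config.chemistry[season]
        chem = sample_chemistry(
            params, config.samples_per_season, _stream_rng(config.seed, _CHEM_STREAM, si)
        )
        for k in range(config.samples_per_season):
            sid = f"{season}-{k:04d}"
            for ti, state in enumerate(STATES):
                rng = _stream_rng(config.seed, _SPEC_STREAM, si, k, ti)
                spectrum = generate_spectrum(chem[k], config.states[state], rng, wl)
                rows.append((sid, season, state, chem[k, 0], chem[k, 1]))
                refl.append(spectrum)
    frame = pd.concat(
        [
            pd.DataFrame(rows, columns=META_COLUMNS),
            pd.DataFrame(np.asarray(refl), columns=reflectance_columns(wl)),
        ],
        axis=1,
    )
    return SampleTable(frame)
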