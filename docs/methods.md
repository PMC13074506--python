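# Methods

This note documents the models, numerical conventions and design choices
behind `teaspec`, and what the synthetic-data generator does and does not
emulate.

## The estimation problem

Tea polyphenols and catechins (% dry weight) are predicted from 400–890 nm
reflectance at 1-nm resolution (490 bands; the region above 890 nm is
excluded as noisy under field conditions). Samples exist in three physical
states — fresh canopy leaves, oven-dried leaves, ground powder — measured in
spring, summer and autumn; a separate model is fitted per (season, state,
indicator) cell. The pipeline is: multi-domain feature extraction →
exhaustive spectral-index construction and screening → regression under
ten-fold cross-validation → statistical consistency checks.

## Harmonic features

A spectrum is treated as one period of a discrete signal r_k, k = 1..N, and
expanded in the real trigonometric basis with coefficients
Aₙ = (2/N)Σ r_k cos(2πnk/N) and Bₙ likewise with sine. Conventions that
matter and their rationale:

- The **k = 1..N index origin** (not 0..N−1) fixes all phases; the FFT
  oracle in the tests applies the matching phase shift.
- The **phase** is atan2(Aₙ, Bₙ), the value consistent with the resultant
  form Cₙ sin(2πnk/N + φₙ): Cₙ sin φₙ = Aₙ and Cₙ cos φₙ = Bₙ.
- **Nyquist handling:** M = N/2 orders are emitted; in reconstruction the
  n = N/2 cosine coefficient is halved, which makes full-order
  reconstruction exact for even N (verified to ≤ 1e-8 max-abs; the Parseval
  identity Σ Cₙ²/2 with the Nyquist term counted once holds to ≤ 1e-8
  relative).

The flattened HF block is ordered [all CA | all SA | all A | all P]
(980 slots for N = 490); names CA_1..CA_245 etc. are part of the public API.

## Wavelet features

The CWT uses the Mexican-hat (second derivative of Gaussian) mother wavelet
— the standard choice in vegetation spectroscopy; the source description
does not name the wavelet, so it is configurable. Scale factors 3, 4, 5, 6
are interpreted **dyadically** (widths a_s = 2^s = 8..64 grid units), the
dominant convention in this literature; a linear mode (a_s = s) is available
because the convention is genuinely ambiguous. Filters are truncated at
±6 a_s, where the Mexican hat is far below double precision of its peak.
Boundaries use half-sample symmetric reflection; coefficients within one
filter half-width of 400/890 nm depend on this choice.

Per wavelength, the retained scale maximizes |Pearson r| between coefficient
and target over the *training* samples, ties to the smaller scale; bands
with constant coefficients score r = 0. Because this selection uses the
target it is target- and fold-specific: the pipeline re-fits the scale map
inside each CV training fold (a `global` pre-modeling mode exists for
comparison and is labelled as leaky). WF slots are named by wavelength
(WF_400..WF_889), consistent with the R_400..R_889 band names.

## Index engine

The 1960-feature pool is ordered [490 R | 980 HF | 490 WF]. Ten formulations
are searched (constants fixed: SAVI L = 0.5, DCNI offset 0.03, MCARI2 factor
0.2, MEVI 2.5/1.5/1). DVI and NDVI are enumerated over unordered pairs
(their sign flips under slot swap, leaving screening R² unchanged); RVI,
SAVI, MSR and all triples over ordered tuples. Screening R² is the squared
Pearson correlation with the target; candidates yielding any non-finite
value on the screening samples are discarded (denominators below 1e-12 in
magnitude count as non-finite). Ties are broken lexicographically by slot
names, with R² quantized to 12 decimals in the sort key so exact algebraic
ties (e.g. MTCI(a,c,b) = −1 − MTCI(a,b,c)) resolve by the rule rather than
by float round-off.

A full ordered triple search over 1960 features is ~10⁹ evaluations per
formulation and infeasible per fold on one CPU. The search strategy
(`full`, `strided(k)`, `subsample(m, seed)`) restricts the pool
deterministically before enumeration; the pipeline defaults are stride 8
for duals (245-feature subpool) and stride 32 for triples (62 features),
which keeps a per-fold screen at a few seconds while covering all three
domains evenly. The vectorized screener is verified against a plain
enumerate-and-rank oracle on small pools, so correctness is independent of
the strategy chosen. Selected candidates evaluated on new samples can in
principle go non-finite; such entries are filled with the training-column
mean (rare, and confined to ratio formulations).

## Models

All three regressors consume the 100-column index matrix per fold.

- **XGBoost:** 1000 CART trees, learning rate 0.05, squared-error loss;
  other hyperparameters are xgboost defaults (notably max_depth 6) — the
  reference protocol fixes only trees and η.
- **GPR:** per-fold z-scoring and PCA retaining 95 % cumulative variance,
  then an RBF × constant + white-noise kernel with hyperparameters from
  marginal-likelihood maximization. The target is standardized on the
  training fold and predictions are inverse-transformed, so outputs are in
  % dry weight.
- **CNN-BiLSTM-attention:** the 100 indices, z-scored per fold, form a
  single-channel sequence (dual block then triple block, each by
  formulation then screening rank; this ordering is frozen because
  convolution imposes a neighborhood on it). Five 1-D conv layers (kernels
  5,5,3,3,3) with BatchNorm, LeakyReLU, squeeze-and-excitation channel
  attention and residual shortcuts where shapes permit; three stacked
  BiLSTM layers; 8-head self-attention; mean-pooled dense head. Kaiming
  initialization for conv, Xavier for dense; Smooth-L1 loss, AdamW,
  cosine-annealed learning rate, dropout, early stopping with
  best-checkpoint restore, monitored on the fold's held-out loss (the
  reference protocol retains the best model per fold).

  The network runs on `teaspec.nn`, a minimal numpy reverse-mode autograd
  engine (broadcast arithmetic, batched matmul, conv1d via im2col, softmax,
  LSTM cells composed from primitives) whose gradients are verified against
  central finite differences. Channel widths, SE reduction, dropout, batch
  size, learning rate and patience are package defaults, marked as such in
  `CNNArchitectureConfig`; the reference settings pin kernels, 3 BiLSTM
  layers, hidden size 384, 8 heads and the ≤ 800-epoch budget. Two scaled
  presets — `desk_scale()` (hidden 32, 16 channels, ≤ 100 epochs) and
  `micro()` (hidden 16, 8 channels, ≤ 40 epochs) — keep single-CPU runs in
  minutes; they preserve the layer structure and are the problem sizes used
  by the tests, the examples and the acceptance script. Strides 2 in three
  conv layers shorten the sequence before the recurrent stack.

  Known limitation: with mutually *uncorrelated* input columns and a
  position-specific target the network memorizes the training fold without
  generalizing. Its inductive bias presumes the screened-index input
  distribution, where every column carries the latent chemistry signal;
  there it recovers the target with out-of-fold R² > 0.9 on the default
  synthetic study.

- **Permutation importance:** mean decrease in out-of-fold R² when one
  column of the held-out rows is permuted (seeded, averaged over folds and
  repeats). Held-out rather than training rows are used — standard practice
  where the protocol leaves it open. The pipeline exports top-10 importance
  tables per condition in global-selection runs (`importance_repeats` in the
  run config); in per-fold mode the 100 columns differ between folds, so
  importances have no fixed candidate identity to attach to.

Cross-validation uses ten mutually exclusive folds from a seeded
permutation; every sample validates exactly once and aggregated out-of-fold
predictions feed the headline metrics. Seeds derive from the master seed via
`SeedSequence` so every stage is reproducible in isolation.

## Metrics and statistics

RE is implemented as the *root*-mean-square relative error
(100·√(mean(((P−O)/O)²))); the plain mean-of-squares variant is available
behind `literal_re` for comparison with sources that print the expression
without the root, whose reported magnitudes are only consistent with the
rooted form. R² is reported as NaN for a constant observed vector (RMSE and
RE remain defined). One-way ANOVA uses explicit between/within sums with an
exact degenerate branch (zero within-group variance); Tukey HSD comes from
statsmodels (Tukey–Kramer under unequal n) with an insert-and-absorb
compact-letter display. PCA of spectra fixes signs by making each
component's largest-magnitude loading positive.

## Synthetic data: what it emulates, what it does not

The generator encodes the study conditions the analysis assumes:

- **Chemistry:** per season, a bivariate normal (ρ = 0.6 between
  polyphenols and catechins — not reported anywhere, chosen as a moderate
  positive default since both track season; configurable) truncated to the
  reported min–max ranges, with the reported means/SDs: polyphenols
  21.54 ± 1.94 / 25.82 ± 1.97 / 22.48 ± 1.62 and catechins 17.43 ± 2.13 /
  20.08 ± 1.42 / 19.00 ± 1.83 for spring/summer/autumn. The autumn catechin
  range is not tabulated; mean ± 3 SD stands in. Default size: 150
  samples/season.
- **States:** one latent sample appears in all three states with identical
  chemistry (the pattern a correct model must reproduce as a null state
  effect) and state-specific spectra: a PCHIP continuum through
  state-typical anchors (dark vegetation curve with green peak, chlorophyll
  trough and red edge for fresh; brown rising curve for dried; bright
  smooth curve for powder), minus Gaussian absorption dips whose depth is
  base + coupling × standardized chemistry. Couplings give a negative
  polyphenol–reflectance extremum at 675 nm for fresh leaves, a positive
  one at 637 nm for dried, and a markedly weakened coupling for powder —
  the qualitative correlation structure and ordering reported for the real
  measurements. Multiplicative log-normal scatter (SD 0.12/0.08/0.04 for
  fresh/dried/powder — field measurements noisiest, homogenized powder most
  stable) and additive noise (SD 0.010/0.008/0.006) are sized so raw-band
  chemistry correlations land in a plausible 0.6–0.9 band while ratio-type
  indices, which cancel the scatter, screen higher.
- **Seeding:** one master seed; per-purpose generators derive from
  `SeedSequence([seed, stream, season, sample, state])`, so any subset
  regenerates bit-identically.

Not emulated: radiative-transfer leaf optics (no PROSPECT-style physics),
instrument artifacts, water-band structure, assay dropout (the real study
has slightly different n per assay), or the real study's exact accuracy
tables — the synthetic signal is cleaner than field data, so absolute R²
values here exceed the real-data ones. Passing tests therefore demonstrate
that the *pipeline* is correct and leakage-free and that it preserves the
designed statistical structure, not that field accuracy would match.

## Problem sizes and numerical tolerances

Tests and the acceptance script run on one CPU: the parameter-recovery
check uses the full default study (150 samples/season) for one condition
with the desk-scale CNN; the nine-cell pattern check uses 50 samples/season
with the micro CNN and coarser search strides (16/64). Oracle tolerances:
harmonic-vs-FFT ≤ 1e-10, full reconstruction ≤ 1e-8, Parseval ≤ 1e-8
relative, CWT-vs-quadrature ≤ 1e-9 on 64-point signals, search-vs-brute
force exact on ≤ 15-feature pools. Screening treats |denominator| < 1e-12
as non-finite; BatchNorm uses ε = 1e-5; AdamW ε = 1e-8.

## Known limitations

- The triple-index search at its default stride explores a regular
  62-feature subpool per fold, not the full 1960³ space; the full mode
  exists but is not desk-feasible.
- The CNN's early stopping monitors the fold's held-out loss, following the
  reference protocol of retaining each fold's best model; this mildly
  optimistic model-selection step is inherent to that protocol.
- Compact-letter displays use the simple insert-and-absorb algorithm,
  sufficient for three groups but not guaranteed minimal in general.
- The YAML config covers the common knobs (sizes, seeds, folds, strategies,
  architecture); bespoke chemistry/spectral-model overrides are Python-API
  only.
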