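# Methods

`acclimet` re-implements, as a tested pipeline over synthetic data, a
developmental-temperature metabolomics analysis for *Drosophila
melanogaster*: flies are reared from egg to adult at 10 constant
temperatures spanning the permissible range (12, 15.5, 18, 20, 22, 25, 27,
29.5, 31, 32 °C), both sexes are profiled by 1D ¹H-NMR (five replicate
pools of 40 flies per sex × temperature, 100 spectra), and four functional
phenotypes are scored in parallel: critical thermal minimum and maximum
(CT_min, CT_max), egg-to-adult viability (20 vials of 40 eggs per
temperature), and developmental time.

The analysis asks which parts of the metabolome follow each of three
hypothesized reaction norms across the thermal gradient — no change, a
linear change, and a U-shaped (or bell-shaped) change that depends on the
deviation from benign intermediate temperatures rather than on temperature
itself — and how those groups relate to the functional phenotypes.

## Spectral preprocessing

Processed real-valued spectra (the pipeline does not model FID acquisition,
phasing, or baseline correction) are handled in a fixed, logged order:

1. **Referencing** — each spectrum is shifted by an integer number of grid
   bins so the maximum inside ±0.25 ppm lands on the grid point nearest the
   TSP resonance at −0.017 ppm. The peak must exceed the window median by a
   configurable number of window standard deviations (default 10).
2. **Alignment** — two-pass, median-referenced, per-segment integer-bin
   cross-correlation (the core of the icoshift algorithm). Default: one
   whole-window segment, maximum cumulative shift 0.02 ppm, gaps filled
   with the segment-edge value. The published study does not state its
   segment scheme; segments and the cap are exposed in the configuration
   and recorded in the processing log.
3. **Trimming** — the residual-water window [4.67, 4.85] ppm and everything
   outside [0.5, 9.5] ppm are removed (closed intervals on ppm values).
4. **Total-intensity normalization** — each spectrum is divided by its own
   total so rows sum to 1, suppressing sample-amount (dilution) variation.
5. **Pareto scaling** — per variable, optional mean-centering followed by
   division by the square root of the standard deviation (n−1 denominator);
   the compromise between unit-variance and no scaling that is standard in
   NMR chemometrics. All multivariate models run on Pareto-scaled data; the
   sex-difference PCA alone is scaled without centering.

Trimming precedes normalization, matching the stated order of the original
workflow. Steps may not be repeated or run out of order; the processing log
is serialized with every artifact.

## Multivariate models

**PCA with target rotation.** Per sex, a centered PCA (SVD) is fitted to
the scaled matrix and the plane of the first two components is rotated so
one axis is maximally Pearson-correlated with developmental temperature
(the *linear component*). The optimum is closed-form,
u ∝ Cov(S)⁻¹ cov(S, T), rather than a grid search; the in-plane direction
orthogonal to it, carrying the most remaining variance, is the *U-shape
component*. Signs are fixed deterministically: the linear component
correlates positively with temperature, and the U-shape component
correlates positively with the squared centered temperature, so a negative
metabolite correlation always means "lower at the extremes" (a bell-shaped
norm).

**OPLS.** The orthogonal-filtering formulation: the predictive weight is
the y-covariance direction w ∝ Xᵀy; each orthogonal component takes the
part of the current X-loading orthogonal to w, deflates it, and the single
predictive component is fitted last. Orthogonal scores are exactly
uncorrelated with y on training data. With zero orthogonal components the
model coincides with single-component NIPALS PLS (verified against
scikit-learn's PLS in the tests). Seven models mirror the study's
prediction table: linear prior (y = temperature) and U-shape prior (y =
two-state encoding: extreme {12, 15.5, 31, 32} = 1, intermediate
[18, 29.5] = 0) per sex, developmental time per sex, and viability with
sexes pooled (no sex-specific viability exists). Component counts are
configurable in the conventional "1 + n_orth" notation (defaults 1+2, 1+1,
1+2, 1+2).

**Cross-validated Q².** All samples of one sex × temperature condition are
left out at a time; Pareto scaling and centering are re-estimated inside
each training fold (stricter than the original description, recorded in
output metadata). Q² = 1 − PRESS / Σ(y_held − ȳ_train)², with the total sum
of squares pooled over folds against each fold's training mean — whether
the original software pooled fold-wise or globally is not recoverable, so
this convention is fixed and documented. Q² ≥ 0.5 is treated as the
significance rule for a model row.

**OPLS-DA and clustering.** A multi-response OPLS against the 20-class
sex × temperature indicator matrix: orthogonal components (uncorrelated
with every class indicator) are filtered first, then NIPALS PLS2 predictive
components are fitted (default 2). The number of orthogonal components is
selected by stratified cross-validated class accuracy over {0..3} unless
fixed in the configuration. Condition-mean predictive scores are clustered
with Ward's method on Euclidean distances (SciPy's Lance–Williams
implementation, verified against brute-force enumeration in the tests) and
exported as a Newick dendrogram with branch lengths equal to merge-height
differences.

## Metabolite-level screening

Thirty metabolites are catalogued with characteristic shifts and an
integration range each; a metabolite's intensity is the summed (normalized)
intensity over its closed integration range. Intensities are Pearson-
correlated with seven targets: the rotated linear and U-shape components,
the linear- and U-shape-prior OPLS scores, the developmental-time OPLS
scores (all per sex), the viability OPLS scores (sexes pooled), and PC1 of
the sex-difference matrix. Each correlation is *verified* by checking
±0.005 ppm windows around the metabolite's other characteristic shifts:
verification demands sign consistency of the individually significant shift
windows, not significance itself (the stricter reading is reported
separately from the primary flag, since the original description is
ambiguous).

Significance uses sequential Bonferroni (Holm) per target per sex family
with an **assumed family size of 100 metabolites**: the sorted p-values are
compared against α/(100), α/(99), … — starting from the assumed total, not
from the ~29 actually tested, so untested metabolites still consume
family-wise error budget. A metabolite is labelled linear (±) or U-shape
(±) in a sex when it is significant on the rotated-component *or* the prior
target of that shape; both shapes may co-occur.

One catalogue entry (nicotinamide ribotide, integration range 9.595–9.581
ppm) lies above the retained 9.5 ppm edge and is skipped with a warning
after trimming; the direct integration call errors instead, naming the
metabolite.

**Sex differences.** Per temperature, each female spectrum minus the
pointwise median male spectrum, and the median female spectrum minus each
male spectrum (10 rows per temperature under the default design). The
matrix is Pareto-scaled *without centering* and decomposed by uncentered
PCA, so score deviations from zero measure the dimorphism itself; PC1 is
regressed on temperature with linear + quadratic + cubic terms separately
per row tagging, and the total score length per temperature is
√Σ_k(mean score_k)². Scaling the uncentered matrix with Pareto is an
assumption (the source states only that intensities were not centered) and
is flagged in output metadata.

## Phenotype models

* **CT_min / CT_max** — OLS of trait on sex, temperature (°C, raw scale)
  and their interaction; sequential F-test reduction at α = 0.05, never
  dropping a main effect inside a retained interaction. α is the
  conventional reading of the reported kept/dropped pattern.
* **Viability** — binomial-logit regression of adults/eggs on standardized
  temperature and its square; overdispersion estimated as Pearson χ²/df and
  standard errors multiplied by its square root (quasi-binomial);
  influential extreme-temperature vials are retained by design. The
  temperature effect is tested by a dispersion-scaled deviance test (2 df).
* **Developmental time** — Poisson log-link GLMM with standardized
  temperature + square + sex fixed effects and a vial random intercept,
  fitted by Laplace-approximated maximum likelihood. Because intercepts are
  independent across vials the marginal likelihood factorizes into
  one-dimensional integrals; each conditional mode is found by a vectorized
  Newton iteration and the Laplace correction reduces to
  −½ log(σ² e^û A_v + 1), which degenerates smoothly to the plain Poisson
  GLM as σ → 0 (cross-checked against statsmodels in the tests). Fixed
  effects are tested by likelihood-ratio tests with the same
  halt-on-interaction rule (the sex × temperature pair, 2 df, first).

Quadratic terms use standardized (mean 0, SD 1) temperature. The original
report's parenthesized second-degree coefficients appear to use a different
(probably orthogonal-polynomial) coding that is not recoverable, so only
the sign and curve shape of the quadratic — not its numeric value — are
treated as reproducible.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:
the default design is exactly the layout above, and the default metabolite
panel plants 10 linear (9 decreasing with temperature, phosphocholine
increasing), 5 inverted-U (NAD⁺, NADP⁺, AMP, mannose, β-alanine — depleted
at the extremes), 5 sex-dimorphic (dimorphism peaking at benign
temperatures), and 10 null reaction norms on the catalogued chemical
shifts. Class assignment respects the catalogue's physical overlaps:
glutamate's integration window contains the methionine sulfoxide 2.32 ppm
resonance, so glutamate is planted linear-decreasing alongside it (the
source study likewise reports glutamate falling in males), and histidine —
whose window is overlap-free — takes its place among the nulls.

Peaks are Lorentzian singlets (default FWHM 0.002 ppm) of equal area at
each characteristic shift; multiplet fine structure is not modelled because
the analysis integrates ranges, not coupling patterns. β-alanine's planted
peaks include its integration-range midpoint (~2.54 ppm): the catalogue's
shift list (3.16, 3.54) does not cover the range it integrates, while real
β-alanine has a CH₂ triplet near 2.55 ppm. Reaction-norm modifiers are
multiplicative: linear classes scale area by 1 ± e·(T − T̄)/(T_max −
T_min) (default effect size e = 0.6, i.e. a 60 % swing across the range);
U-shape classes are two-state, 1 ± e at the four extreme temperatures —
deliberately the same structure the U-shape prior tests, not a smooth
parabola. Sex-dimorphic metabolites multiply female areas by 1 +
0.5·exp(−((T−22)/7)²).

Nuisance structure exercises exactly what the preprocessing must undo: a
log-normal per-sample dilution factor (SD 0.15) applied to everything
except the TSP reference (which sits in the buffer at fixed concentration);
a global per-sample ppm jitter, uniform on ±0.005 ppm and quantized to the
grid — jitter models the referencing offset that integer-bin shifting can
and must undo exactly, not sub-bin lineshape physics; additive Gaussian
baseline noise (SD 0.3 intensity units against peak heights of order 10²–10³)
clipped at zero; and, dominating the error of integrated intensities as it
does in real pooled-fly data, an independent log-normal area factor per
metabolite per sample (SD 0.10).

Real extract spectra contain far more resonances than a 30-entry catalogue,
and that unassigned majority is what makes total-intensity normalization
benign in practice: without it, the closed 30-peak system would leak every
planted effect into the null metabolites through the shared total
(compositional closure). The generator therefore adds 150 sharp unassigned
singlets (total area 300 versus ~34 for the catalogued panel) at
deterministic pseudo-random positions kept clear of all integration ranges
and characteristic shifts, each varying like any other metabolite. Broad
macromolecule humps are not modelled — the CPMG acquisition the pipeline
assumes attenuates them.

Phenotype truths take every printed coefficient that is interpretable at
face value — CT_min (−4.578 + 0.412·T, residual SD 0.55), CT_max (37.601 +
0.123·T, male offset −0.692, interaction 0.019, residual SD 0.5), the
developmental-time sex offset (0.03 on the log scale) — and anchor the two
quadratics to the published curve shapes instead of the uninterpretable
printed second-degree codings: viability ≈ 43 %/75 %/45 % at 12/22/32 °C on
the logit scale with beta-binomial overdispersion factor 2, and
developmental time falling from ~49 days at 12 °C to ~7.5 days at 29.5 °C
with a slight rise toward 32 °C, vial random-intercept SD 0.05. Residual
SDs are back-calculated from the printed standard errors at the reported
sample sizes.

Randomness uses one `numpy` SeedSequence stream per sample, keyed by
(dataset seed, sample index), so identical seeds reproduce byte-identical
datasets and single samples can be regenerated in isolation.

### What passing tests do and do not show

The generator plants exactly the effect structures the analysis is built to
detect, with Lorentzian singlets, grid-quantized shifts and log-normal
replicate noise. Recovery results therefore demonstrate the pipeline's
internal correctness — normalization, alignment, rotation, OPLS, Holm
screening and the phenotype models do what they claim on data with known
truth — but not robustness to what real spectra add: multiplet structure
and peak overlap beyond the catalogue's, pH- and temperature-dependent
per-metabolite shift drift, baseline distortion, and reaction norms that
are neither linear nor two-state. The replicate noise magnitudes are
conventions (the source reports none) and are exposed in the configuration.

## Numerical choices and degenerate inputs

* PCA signs: largest-magnitude loading element positive; rotated components
  use the temperature-anchored conventions above.
* Alignment lag ties break toward the smallest |lag|; the cumulative
  per-spectrum shift is capped at the configured maximum with a warning.
* Zero-variance columns: Pareto centering maps them to zero; uncentered
  scaling leaves them unscaled with a warning. Constant metabolite columns
  are excluded from correlation testing with a warning and no p-value.
* An all-zero sex-difference matrix returns zero scores with a warning
  instead of a degenerate PCA.
* Holm refuses an assumed family size smaller than the number tested.
* OPLS refuses n_orth ≥ min(n−1, p); saturated (zero-residual) OLS
  reductions treat a zero improvement as droppable (F = 0, p = 1).
* The GLMM bounds σ ≥ 10⁻⁶ inside the optimizer and reports the boundary
  value as 0-adjacent; fixed-effect SEs come from the numeric observed
  information.

## Problem sizes

Default runs use the full study design (100 spectra × ~8,800 retained grid
points, 200 vials, 8,000 developmental-time records, 400 flies per thermal
limit). The test suite's replicate studies use 100–200 simulated datasets
for the phenotype models, 20 datasets for reaction-norm recovery, and 50
permutations for the Q² null — sizes at which every Monte-Carlo check
resolves its target within the stated tolerance.

## Known limitations

* No FID-level simulation, J-coupling, phasing, or baseline correction; no
  JCAMP/Bruker ingestion — the pipeline starts from processed intensity
  tables.
* Alignment and referencing are integer-bin; sub-bin misalignment is out of
  contract.
* The OPLS-DA implements the discriminant, class-indicator form only; the
  bidirectional O2PLS X↔Y decomposition and VIP scores are not provided.
* Signal overlap within the catalogue is inherited from its integration
  ranges (noted in its source): overlapping windows measure sums of
  metabolites, not individual concentrations.
* Viability correlations are pooled over sexes by construction; sex-specific
  viability cannot be recovered from vial-level counts.
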