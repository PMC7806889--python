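# Methods

## The question and the quantities

Labiodental consonants ([f], [v], and the rarer [ʋ], [ɱ], [ⱱ]) are produced
with the lower lip against the upper teeth. The hypothesis under test is that
their use in speech tracks dentition: populations with heavy-wear diets
(traditional hunter-gatherers, "HG") tend toward edge-to-edge bites that make
labiodentals more effortful, while food-producing populations tend toward
overbite/overjet that makes them cheaper. `labiofreq` implements a
*usage-based* test: rather than asking whether a language has a labiodental
phoneme, it counts labiodental **tokens** in phonetically transcribed basic
word lists.

For a doculect (one documented language variety, the unit of analysis) with
`C` consonant tokens, `F` labiodental tokens, and `F_wi` word-initial
labiodental tokens across all word forms:

```
LR   = F / C          labiodental ratio
WILR = F_wi / C       word-initial labiodental ratio
```

Both denominators are the *total* consonant count, so `WILR ≤ LR` always; a
form's first segment is its word-initial position, and every transcription
variant of a concept is counted.

## Tokenization

Word lists are in an ASJP-style encoding: 7 vowel symbols (`i e E 3 a u o`),
34 consonant symbols (labiodentals coded `f`, `v`), and modifier symbols
(`~` binds the preceding two symbols into one sound, `$` the preceding
three). Because bound sequences such as prenasalized stops count as separate
consonants for this analysis, tokenization drops modifiers and keeps the
bound symbols (`"nd~o"` → `n d o`, two consonant tokens). Spacing and loan
markers are ignorable; any other symbol is an error that names the offending
character and its offset, since it usually signals an encoding-dialect
mismatch. The alphabet is a CSV resource (`symbol,class,subclass`), not
code, so dialect drift is fixable without touching the tokenizer. A second
packaged table supports IPA input for pre-tokenized text material, with
`{f, v, ʋ, ɱ, ⱱ}` as the labiodental class and diacritics treated as
modifiers (input is NFD-normalized first so precomposed characters work).

## Boundary-valued ratios

More than half of worldwide word lists contain no labiodental at all, so LR
is very often exactly 0 and a raw logit is undefined. The default transform
is the logit of the Smithson–Verkuilen compression

```
y = (x · (N − 1) + 1/2) / N
```

with `N` the number of doculects in the analysis set. The same compression
(on the probability scale) feeds the beta-likelihood model. `raw_logit` is
available and errors at the boundary by design.

## Models

All models contrast HG vs non-HG doculects with crossed random intercepts
for linguistic lineage (family or isolate) and geographic contact region —
the two components of Galton's problem (shared descent, areal diffusion).

**Linear mixed model** (`CrossedInterceptLMM`): transformed ratio response,
fixed effects `intercept + β·HG`, random intercepts for lineage and region,
residual noise. Fitted by full maximum likelihood (not REML) so that the
likelihood-ratio test against the identical model without the fixed effect
is valid (df = 1, statistic clipped at 0 for boundary fits). The likelihood
is profiled analytically over the fixed effects and the residual variance;
the remaining two-dimensional optimization over variance ratios runs through
the Woodbury identity in the random-effect space, so a fit at n ≈ 2700 with
250+ intercepts takes ~0.1 s. Variance components may legitimately hit zero
with many small lineages; such fits are reported with the component at zero
and flagged `singular`, not errored. Wald covariance is `σ̂²(XᵀV̂⁻¹X)⁻¹`.
The implementation agrees with statsmodels `MixedLM` (ML, variance
components) to ≈1e-4 on test fixtures.

**Binomial mixed model** (`CrossedInterceptLogisticGLMM`): models the binary
presence of any labiodental in the word list, same fixed/random structure,
logit link. The marginal likelihood uses the Laplace approximation (the
random-effect mode is found by damped Newton on the concave penalized
log-likelihood; a log-determinant curvature term corrects the plug-in
likelihood), the same approximation family lme4's `glmer` uses at one
quadrature point; agreement with `glmer` is ≈5e-3 on test fixtures. Complete
separation (no outcome variation within a subsistence cell) is detected
up-front and reported as a flag. Wald SEs condition on the estimated
variance parameters, the usual GLMM convention.

**Bayesian beta mixed model** (`BetaMixedModel`): `y ~ Beta(μφ, (1−μ)φ)`
with `logit μ = β₀ + β·HG + a_lineage + a_region` and shared precision φ.
Priors (defaults, overridable): `Normal(0, 2.5)` on location terms,
`HalfNormal(1)` on group SDs, `Exponential(0.01)` on φ. Sampling is a
blocked adaptive Metropolis-within-Gibbs scheme: since each observation
belongs to exactly one lineage (region), all intercepts of a block are
proposed and accepted coordinate-wise in one vectorized step; scalar
parameters use adaptive random walks; additional interweaving "shift" moves
translate a fixed effect against its intercept block (likelihood-invariant,
priors decide), which removes the location degeneracy that otherwise
cripples centered samplers. Scales adapt toward 0.44 acceptance during
warmup only, so the retained chain has a fixed kernel. Chains derive from
one integer seed via `SeedSequence`; effective sample size and split-Rhat
come from arviz, and a results object flags itself `unreliable` below
ESS 50 or above Rhat 1.1. The headline scalar is `Pr(β < 0)`, the posterior
probability of the predicted direction.

## Stratified resampling contrast

The model-free control for Galton's problem. Per iteration, separately
within each subsistence group: pick one doculect uniformly from every
lineage present in the group (stage 1), then, from that sample, one doculect
uniformly from every region represented *in the stage-1 sample* (stage 2) —
the literal two-stage order, family then region, with the stage-2 universe
given by the stage-1 draw. A lineage spanning several regions may therefore
contribute its row to any of them. The recorded disparity is
`mean(non-HG sample) − mean(HG sample)` of LR or WILR; positive values mean
more labiodental usage outside HG groups. Default 5000 iterations; each
iteration consumes its own deterministically spawned `SeedSequence`
substream (HG group drawn first, then non-HG, independently), so the
disparity vector is bit-reproducible from one integer seed. Summaries
(mean, median, central 95% interval, fraction positive) are recomputable
from the stored vector.

## Synthetic data generator

No redistributable accession exists for the real word lists, so the
generator emulates the structure the analysis assumes, and its defaults are
the study conditions used throughout the tests:

* 233 lineages in 24 regions, 2729 doculects (lineage sizes shifted-geometric,
  adjusted to the exact total), in the worldwide-scale preset;
* each lineage sits in one region (10% of doculects re-drawn across regions
  in the preset, to exercise the resampler's stage-2 logic) and is HG with
  probability 0.25 — roughly the lineage-level HG share in worldwide
  comparative samples;
* per-doculect labiodental probability
  `p = logit⁻¹(μ + β·HG + a_lineage + a_region)` with
  `a ~ Normal(0, σ²)`, σ_lineage = 0.9 and σ_region = 0.5 on the logit
  scale — together ≈1.0, the overdispersion needed for an LR SD comparable
  to its mean, as observed;
* 40 words per list of 1–3 CV syllables (mean two consonants per word, so
  about half of labiodental tokens are word-initial, matching the observed
  WILR/LR ratio ≈ 0.5); every consonant slot is labiodental (`f`/`v`
  equiprobable) with probability p, else a uniform non-labiodental
  consonant. The finite list is the only noise source — the binomial
  sampling of tokens supplies the residual the LMM absorbs;
* the preset solves μ and β by Gauss–Hermite inversion of the logit-normal
  mixture so that the *expected* group LR means equal 0.0218 (non-HG) and
  0.0079 (HG) exactly; realized group means wander by cluster-level
  Monte-Carlo error (≈±0.002) because lineage effects are shared;
* an AUTOTYP-style second taxonomy is emitted for a 21.6% subset
  (mirroring 590/2729), agreeing with the generating labels by default;
  a disagreement rate is available.

What the generator does **not** emulate: real phonotactics, word-length and
segment-frequency distributions, sound change, borrowing, non-independent
missingness, or disagreement between subsistence codings. Passing tests
therefore demonstrate that the *pipeline* recovers the structure it assumes
at realistic sizes and noise levels — not that the real-world effect is
confirmed; the published point estimates from the real ASJP/AUTOTYP data
(group means 0.0218/0.0079, LMM coefficients −0.144 …, disparity means
0.0045–0.0153) remain documentation examples that require the external
databases.

A counts-level fast path (`generate_profile_table`) draws the token counts
the word-list model implies without materializing strings; it is
statistically identical (tested) and makes 5000-dataset calibrations cheap.

## Numerical and design choices

* Chi-square tests are uncorrected Pearson (no Yates continuity
  correction): only the uncorrected statistic reproduces both published
  contingency values (127.2 and ≈8.18). Zero marginals are an error.
* Note that for the 2×2 lineage-presence table [[0,7],[18,12]] the
  uncorrected statistic is 8.179 with upper-tail p = 0.0042.
* Variance-ratio optimization uses multi-start L-BFGS-B on log ratios with
  a floor of e⁻¹⁴ (component treated as zero, `singular` flagged at e⁻¹²);
  a Nelder–Mead fallback guards rough likelihoods.
* Metadata joins match glottocode first, then ISO 639-3 (glottocodes are
  doculect-granular; ISO merges dialects); ambiguous keys are an error, and
  every dropped row is tallied by reason so the data funnel is auditable.
  Under the `large` taxonomy absence from the HG list means non-HG (the
  list-based coding); under `autotyp`, rows without an explicit assessment
  are dropped.
* Synonym variants are split and all counted; the alternative (first
  variant only) can be had by pre-filtering, but no exclusion rule is
  implied by the source material.
* Transformed columns are computed after filtering, with the admitted row
  count as the smoothing N, so the two taxonomies use their own N.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make their statistical
claims sharp while staying cheap: parameter-recovery fits use 300–1000
observations with 20–50 lineages; the LRT type-I-error study uses 200 null
datasets of 500 doculects (100 lineages, 10 regions); the resampling null
calibration uses 5000 independently generated datasets (50 lineages, 10
regions) with one controlled contrast each — the mean of the resulting
disparity distribution is exactly zero by label symmetry, which is what the
3-standard-error bound verifies; directional-recovery checks run the full
worldwide-scale preset ten times. The Bayesian model's coverage checks run
at reduced scale (n = 300, 20 lineages, 8 replicates) with 2 × 1200
retained draws.

## Known limitations

* The LMM is fitted to a transformed bounded ratio whose distribution is a
  point-mass-plus-continuum; the LRT is calibrated by simulation (type-I
  error 0.045 at nominal 0.05 under the test conditions) but the Gaussian
  residual model is, as in the original analysis, an approximation.
* Coefficients on the smoothed-logit scale depend on N through the
  compression and are not comparable across datasets of different size or
  zero-inflation; signs and LRTs are the stable quantities.
* The Laplace GLMM shares lme4's small-cluster bias; with very few lineages
  per group its variance components are noisy.
* The MCMC sampler is a random-walk scheme: adequate (ESS in the hundreds
  per thousand draws) at the scales used here, but slower-mixing than
  gradient-based samplers at much larger scales.
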