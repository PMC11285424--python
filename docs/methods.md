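# Methods

This note documents the statistical machinery, the synthetic-data model,
and the numerical and design choices behind `n400link`. It states no
empirical result that the test-suite or `scripts/acceptance.py` does not
itself compute.

## 1. Metrics

For a critical word *w* with preceding context *c* under an autoregressive
backend, the contextual probability is the product of the per-token
conditionals over *w*'s sub-word tokens (each conditioned on *c* plus the
word tokens already scored), and surprisal is its negative logarithm:
*S* = −log *p* = Σᵢ −log *p*(tᵢ | c, t₁…tᵢ₋₁). Only autoregressive models
are supported: masked-LM pseudo-probabilities do not yield well-defined
multi-token products.

The metric family is *P* = *p*, *S*ᵏ for finite *k*, and *e*^(*S*^0.6).
Every metric entering a regression is z-scored (sample SD, ddof = 1) within
(language model, metric, dataset) on the analyzed trial set. Two
consequences worth knowing:

* because (c·S)ᵏ = cᵏ·Sᵏ, z-scored powered surprisal is invariant to the
  logarithm base; *e*^(*S*^0.6) is **not**, so the base (natural by default,
  base-2 selectable) is recorded on every `WordScore`;
* *S* = 0 (*p* = 1) is a hard domain error for *k* ≤ 0 and for the
  exponentiated metric, surfacing degenerate stimuli instead of clipping
  them. Softmax backends cannot produce *p* = 1; only hand-built tables can.

Negative exponents (−1, −0.5, −0.1) are computed for the AIC surface but
excluded from the 0–2 estimation grid.

## 2. Regression recipes

Two preset recipes cover the conventions of the trial-level datasets this
pipeline targets:

* **`lab_random_subject`** — baselined amplitude ~ metric + lab (dummy
  coded), random intercept per subject. For multi-lab replication-style
  data.
* **`baseline_covariates`** — raw amplitude ~ baseline + concreteness +
  log frequency + OLD20 + sentence position + metric; random baseline
  slopes for subject and item, random intercepts for item (and, by default,
  subject).

All numeric variables, including the dependent variable by default, are
z-scored on the analyzed trials. A common affine transform of the DV shifts
every log-likelihood by the same *n*·log *b*, so ΔAIC and likelihood-ratio
statistics are unaffected (asserted in the tests); `zscore_dv=False` is
available when raw coefficients are wanted.

Design construction never drops a trial silently: rows with missing
required fields are removed with logged counts and reasons. A categorical
fixed term with a single level (e.g. single-lab data under the multi-lab
recipe) is a hard degenerate-design error.

### Random-structure choice for the covariate recipe

The stated structure — baseline slopes for subject and item plus an item
intercept — leaves open whether the subject term also carries an intercept
and whether slope and intercept correlate. We fit subject and item each
with intercept + slope as **independent** variance components. Crossed
factors force this: correlated slope/intercept pairs are only expressible
within a single grouping factor in the available ML machinery, and the
independent-components likelihood is what both of our fitting routes (see
§3) optimize. `subject_slope_only=True` gives the stricter slope-only
reading.

## 3. Mixed-model engine

All models are fitted by **maximum likelihood, never REML**: the pipeline's
entire purpose is comparing AIC and running LRTs across models that differ
in fixed effects, which is only valid under ML. `n_params` counts fixed
coefficients + variance components + the residual variance, making
AIC = 2·n_params − 2·logLik reproducible across engines.

Three routes, selected automatically:

1. **Single random intercept** — profiled ML: for a fixed variance ratio
   λ = σ²_b/σ²_e the GLS coefficients and residual variance are closed
   forms (Woodbury on the compound-symmetric blocks), leaving a 1-D bounded
   search over log λ (tolerance 1e-10) plus an explicit λ→0 (OLS) boundary
   check. Deterministic and ~2 ms at 1800 rows, which is what makes the
   23-exponent × 5-LM sweeps cheap.
2. **Crossed independent variance components** — same profiling idea with a
   q-dimensional inner matrix (q = total random-effect levels): given the
   per-component ratios, β and σ² are closed forms; L-BFGS-B optimizes the
   log-ratios from two fixed starts. Used for the covariate recipe.
3. **statsmodels `MixedLM`** — single-factor correlated slope+intercept
   structures, and as the independent cross-check of routes 1–2 in the
   tests (agreement to ~1e-3 in logLik where it converges; the profiled
   routes never trail it). A brute-force optimizer of the full-matrix
   marginal likelihood serves as a second, engine-independent oracle.

Singular fits (a variance ratio at the numerical floor) are flagged, not
rejected. Rank-deficient fixed designs are errors. LRT statistics are
clipped at zero with a warning if an optimizer leaves the augmented model
below its base.

The variance-partitioning battery fits all seven fixed-effect subsets of
{P, S, S^0.6} against the *identical* response and random structure, then
reports the eight "base + added" tests with df = number of added terms
(df = 2 only for S^0.6 + (S + P)).

**Recipe matters for calibration.** Tests of item-level predictors are
anti-conservative under the subject-intercept-only recipe whenever items
carry unmodelled variance, because trials of one item are then treated as
independent. The pipeline therefore runs the battery under the
`baseline_covariates` recipe (item intercepts + slopes) by default; with it
the null tests are near-nominal after BY correction (measured in the
acceptance tests).

Benjamini–Yekutieli step-up adjustment (valid under arbitrary dependence,
inflation factor c(m) = Σ 1/i) is applied once per pipeline invocation
across every p-value the run emits — contrast LRTs plus the full battery —
and the family membership is written to `fdr_family.json` so alternative
groupings can be audited.

## 4. Exponent estimation

For each LM and each grid exponent the recipe is refitted with z(*S*ᵏ) as
the metric (the design is built once; only the metric column is swapped, so
every cell sees the same response). Failed cells are recorded with reasons;
a surface with >10% failures is flagged unreliable.

The smoother is a cubic penalized B-spline (basis dimension 10,
second-order coefficient-difference penalty, smoothing parameter by GCV
over a 43-point log grid) with one unpenalized offset column per
non-reference LM — the fixed-effect limit of per-LM random offsets. Adding
a constant to one LM's AICs changes only that LM's offset, never the curve
shape (asserted exactly in the tests). The population-level prediction —
spline plus the mean offset, i.e. the expected curve for a new, unobserved
"dummy" LM — is evaluated on k ∈ {0, 0.1, …, 2.0} and its argmin is *k̂*;
estimates at 0 or 2 are flagged as boundary. Fit quality is the adjusted R²
with the effective degrees of freedom as model df. Pooled mode adds
per-dataset offset columns and estimates one global curve.

Metric contrasts regress AIC on metric with a per-LM random intercept
(route 1); in a balanced complete table the estimate equals the mean paired
AIC difference exactly, and |ΔAIC| ≥ 4 (minus a 1e-9 round-off guard) sets
the "substantial" flag. A companion LRT checks metric as a predictor of AIC
at all. With a single LM the contrast degenerates to the raw difference and
no LRT is attempted.

## 5. Correlation analyses

Contextual similarity is the cosine between the critical word's embedding
and the unweighted mean of its context-word embeddings. Context words are
all whitespace-separated words preceding the critical word, lowercased,
punctuation stripped; out-of-vocabulary words are skipped (at least one
embeddable word is required). Correlations with cloze use only items with
cloze **strictly** greater than 0.05 (low-cloze norming estimates are
unreliable) and require at least three survivors; the similarity target
applies no filter. All correlations are reported as |Pearson r| — the
metrics differ in sign convention, and only association strength is
compared.

## 6. Synthetic-data model

One bundle mirrors the generative assumptions of the fitted models:

| parameter | default | meaning |
|---|---|---|
| `n_subjects` × `n_items` | 30 × 60 | fully crossed design (1800 trials) |
| `surprisal_range` | 0.5–12 nats | item surprisal, log-uniform |
| `k_true` / `link` | 0.6 / powered surprisal | generating link |
| `beta_metric` | −3.0 µV/SD | amplitude effect of the z-scored link |
| `beta_baseline` | 0.3 µV/SD | baseline dependence |
| `sd_subject`, `sd_item`, `sd_residual` | 1.0, 0.25, 1.5 µV | variance components |
| `n_labs`, `lab_offset_sd` | 3, 0.4 µV | round-robin lab assignment |
| `n_mock_lms`, `lm_noise_sd` | 5, 0.1 | noisy models of the item log-probabilities |
| `cloze_noise_sd` | 0.6 | noise on the cloze link (logit scale) |
| `embedding_dim`, `similarity_rho` | 8, −0.5 | mock embeddings, target corr(similarity, S) |

Amplitude = β₀ + β_metric·z(link) + β_baseline·z(baseline) +
Σ β_cov·z(cov) + lab offset + subject effect + item effect + Gaussian
residual; z-scoring happens at the trial level, matching what the fitted
designs see. Each mock LM reports the true item surprisals plus Gaussian
log-scale noise (clipped at 0.05 nats so probabilities stay inside (0,1)).
Cloze is an inverse-logit of 2 − 1.2·S^0.6 plus noise — a noisy monotone
transform of the sub-logarithmic metric, clipped to [0,1]. Embeddings place
each item's context and critical vectors at a designed cosine; the designed
similarity sequence is constructed by Gram–Schmidt so its *sample*
correlation with true surprisal equals `similarity_rho` exactly.

**Why these defaults.** The design size is desk-scale: the real datasets
this pipeline targets have 10⁴–10⁵ trials and hundreds of items, where a
much weaker per-SD effect is resolvable. At 60 items, distinguishing
*S*^0.4 from *S*^0.5 hinges on a component of variance that shrinks with
the item count, so the generator compensates with a strong single-trial
effect (−3 µV/SD, at the upper end of plausible N400 condition effects) and
clean noise (residual 1.5 µV, item SD 0.25 µV). The calibration was chosen
by simulating the estimator's operating range before the acceptance
thresholds were frozen, and left alone afterwards. LM noise of 0.1 nats
keeps the five mock models distinct without letting error-in-variables bias
the exponent estimate upward (transform noise grows at the low-surprisal
end for k < 1, which is also why the null battery tests are run against the
recipe with item effects rather than by shrinking the noise).

What the generator does **not** emulate: EEG waveforms or topography,
artifact structure, item repetition, non-Gaussian single-trial noise,
participant attrition, and realistic LM disagreement (mock LMs share one
truth plus independent noise; real models disagree systematically). Passing
tests therefore demonstrate that the *pipeline* recovers known ground truth
under its own model class — not that any particular empirical dataset has a
sub-logarithmic link.

## 7. Numerical choices

* Optimizers: 1-D bounded search (xatol 1e-10) for route 1; L-BFGS-B
  (ftol 1e-12) from two fixed starts for route 2; everything deterministic
  given the data, so a fixed-seed run is byte-identical across invocations.
* z-scoring uses ddof = 1 throughout.
* LRT χ² clipped at 0; p = 1 reported at χ² = 0.
* The spline solve adds a 1e-9 relative ridge for safety; the GCV search
  grid spans λ ∈ [1e-6, 1e8].
* Problem sizes in the test-suite (20 seeds per recovery setting, 50-seed
  battery calibration, 2000-replicate LRT null, 30 oracle problems) are the
  package's validation design, chosen to give stable rates at desk scale.

## 8. Known limitations

* No pretrained transformer adapters are bundled; the backend contract and
  registry are the integration point.
* Correlated random slope/intercept pairs are only available for
  single-factor structures (via statsmodels); crossed structures use
  independent components.
* The exponent estimate is restricted to the 0–2 grid by design; a link
  genuinely outside that range is reported as a flagged boundary estimate.
* Cloze and similarity generators encode one particular dependency
  structure (monotone in S^0.6; linear-in-similarity with exact sample
  correlation); they are validation instruments, not models of norming
  behavior.
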