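# Methods

This note documents the models and procedures implemented in `binocsync`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Offsets, tolerance, and the nine-type typology

For a binocular fixation (a temporally overlapping left/right pair of
monocular fixations) the two measures are

* start-time offset = right-eye fixation start − left-eye fixation start,
* end-time offset = right-eye fixation end − left-eye fixation end,

both in milliseconds, signed. A 500 Hz tracker reports events on a 2 ms
lattice, so offsets of ±2 ms are indistinguishable from simultaneity;
the classifier treats |offset| ≤ tol (default tol = 2 ms, inclusive) as
synchronous. On the 2 ms lattice the synchronous band is therefore
{−2, 0, +2}, and "right eye early" means offset < −2, not merely < 2 —
the inclusive tolerance band takes precedence over a literal strict
inequality, which would contradict the simultaneity convention. The
tolerance is configurable for trackers at other rates.

Crossing the start axis {sync, right-early, left-early} with the end axis
{sync, left-late, right-late} gives the nine types:

|                    | end sync | left ends later | right ends later |
|--------------------|----------|-----------------|------------------|
| starts sync        | Syn      | T1              | T2               |
| right starts early | T3       | T4              | T5               |
| left starts early  | T6       | T7              | T8               |

Left-eye-priority types {T1, T6, T7}; right-eye-priority {T2, T3, T5};
T4 and T8 combine an early advantage for one eye with a late advantage for
the other and are excluded from the default model set. Swapping the two
eyes negates both offsets and induces the label involution
T1↔T2, T3↔T6, T4↔T8, T5↔T7 (Syn fixed), which is asserted as a property
test. Derived aggregates: end-synchronous = Syn+T3+T6, start-synchronous
= Syn+T1+T2, and the two priority sums.

## Pairing

The two monocular streams within a page are each strictly ordered and
non-overlapping, so a physiologically meaningful matching cannot cross in
time. Among non-crossing one-to-one matchings, the pairing maximizes
total temporal overlap, computed exactly by an O(|L|·|R|) dynamic program;
tests verify it against exhaustive enumeration on small instances.
Decisions baked into this definition:

* overlap must be strictly positive (a shared endpoint on the 2 ms grid is
  a saccade boundary, not co-fixation);
* no fixation is reused — one long fixation spanning two opposite-eye
  fixations yields one pair and one unpaired fixation;
* pairs never span a page boundary;
* ties in total overlap resolve toward the earlier right fixation.

Unpaired fixations are tallied per eye and surfaced in the run manifest.

## Spatial assignment

A pair's screen position is the right eye's mean coordinates during the
fixation (at these spatial scales the choice of eye is immaterial and is
made once, for determinism). Regions left/middle/right are assigned from
x only — the analysis concerns position along lines of text — with
boundaries defaulting to equal thirds of the screen width. The thirds
default is a choice, not a measurement: a text-extent split is supported
through `ScreenGeometry.region_bounds` and matters for orthographies with
ragged right margins. Hexagonal density summaries use a pointy-top axial
tessellation with nearest-center assignment (exact, via cube rounding);
the default 25 px radius is roughly one Chinese character width and is a
display parameter only.

## Poisson count models

The modeling unit is the count of fixation pairs in a cell
(participant × article × page × region), per asynchrony type. Counts get
a Poisson distribution with log link. Fixed effects use treatment coding
with **middle as the reference**, so `region[left]` and `region[right]`
are log rate ratios versus the middle of lines. Random intercepts
(independent, crossed) are available for participant, article, and page;
"page" is keyed by (article, page-order-within-article) by default,
matching the idea that successive pages of an article become more
predictable, with a global page key available by flag.

*GLM.* Iteratively reweighted least squares; the deviance trace is kept
and tested for monotone descent; SEs from the observed information.

*GLMM.* The marginal likelihood over the random effects is approximated
by Laplace's method. For variance parameters σ (one per factor, optimized
on the SD scale with a lower bound of 0) and fixed effects β:

* the inner Newton solve finds the random-effect mode b̂(β, σ) of the
  penalized conditional log-likelihood;
* the Laplace objective is ℓ_c(β, b̂) − ½ Σ b̂²/σ² − ½ log det(I + S Z′WZ S),
  with S = diag(σ) and W the Poisson weights at the mode;
* the outer optimizer (L-BFGS-B, fixed start values and tolerances, hence
  deterministic) moves **β and σ jointly** against this objective. This is
  the nAGQ = 1 convention: the determinant depends on β through W, so
  profiling β at the joint penalized mode instead would bias the
  intercept — we verified the joint-outer convention against exact
  adaptive quadrature ML and against `lme4::glmer` on a frozen fixture
  (log-likelihoods within 0.005, coefficients within 10⁻⁴).

Boundary solutions (σ̂ = 0) are legitimate and reported as zero variances
with a table footnote; at the boundary the fit collapses onto the GLM.
A factor observed at a single level is dropped with a warning. Wald SEs
for β come from the Schur complement of the joint (β, b) Hessian. All
fits use maximum likelihood (no REML-style correction), so nested models
are compared by likelihood-ratio χ², with degrees of freedom equal to the
difference in parameter count.

*Parameter count.* k = (#fixed coefficients) + (#requested variance
components), including components estimated at the boundary. AIC =
−2ℓ + 2k and BIC = −2ℓ + k·ln(n) are asserted as identities on every
result object. This counting convention reproduces the published
arithmetic the pipeline is modeled on (a three-factor null model has
k = 4, its region model k = 6).

## Synthetic generator

The generator emulates the structure of a binocular multi-line reading
experiment: a left-to-right fixation walk along each of up to five lines
per page with a return sweep between lines, lognormal fixation durations
(defaults: log-mean 5.3 ≈ 200 ms, log-sd 0.35), a 30 ms inter-fixation
gap, on a 1024 × 768 px screen. Each conceptual fixation spawns one
left-eye and one right-eye event.

The temporal asynchrony model is the planted ground truth. With
x̃ = 2x/width − 1 the normalized horizontal position, the signed offsets
are drawn from Laplace (two-sided exponential) distributions —

* start offset ~ Laplace(−start_bias_slope · x̃ + sweep · [line-initial], scale),
* end offset ~ Laplace(+end_bias_slope · x̃, scale),

so a positive start slope makes the right eye start earlier toward the
right of the screen, a positive end slope makes it end later there, and
the first fixation after a return sweep gives the left eye an extra start
advantage. The Laplace form is a modeling choice: the only constraint
taken from the phenomenon is a long-tailed distribution with single-digit-
millisecond typical magnitudes. Defaults (scale 1.5 ms, slopes 2.0 and
1.5 ms, sweep advantage 2 ms) were chosen once so the resulting typology
distribution resembles the descriptive pattern of real binocular reading
corpora — a majority of fully synchronous pairs, roughly four fifths of
pairs ending synchronously, T3/T6 the leading asynchronous types with
opposite spatial skews.

Numerical details that matter:

* All times are rounded half-away-from-zero to the 2 ms sampling grid,
  which creates the discrete offset lattice {…, −4, −2, 0, +2, +4, …}.
  The planted-scale invariant (median |offset| = scale·ln 2) is therefore
  checked with a fine quantum, where the lattice does not mask the scale.
* Offsets are clipped to half the inter-fixation gap so each eye's stream
  stays strictly ordered; the clipping is symmetric and far beyond the
  median, leaving the median invariant untouched and thinning only the
  extreme tail.
* Configs whose lag scale could plausibly consume a short fixation
  (tail probability above `degenerate_tol` at the 1st-percentile duration)
  are rejected as degenerate rather than silently truncated.
* One global seed; per-(participant, article, page) substreams are seeded
  as (seed, i, j, k), so any subset of the session regenerates
  identically.

The generator does **not** model pupil size, raw 500 Hz samples,
microsaccades/drift, vergence/spatial disparity between the eyes, lexical
content, or blink interruption. Passing tests therefore show that the
pipeline recovers structure *of the planted kind* — location-dependent,
long-tailed temporal lags and log-linear region effects on counts — not
that real data obey the Laplace form.

A second path, `simulate_count_table`, skips the event level entirely and
draws Poisson counts with planted region effects (log rate ratios) and
normal random intercepts of given SDs, for estimator-level tests.

## Verification harnesses and problem sizes

The test suite and `scripts/acceptance.py` run everything at sizes chosen
to make each check statistically meaningful on one CPU:

* typology: the full 121-point offset grid against an independently coded
  oracle, plus eye-swap symmetry (exhaustive);
* pairing: 200 random instances of ≤ 8 fixations per eye against
  exhaustive enumeration;
* pipeline gradient: ~10⁴ pairs (6 participants × 5 articles × 5 pages)
  with planted bias, one-sided binomial tests at α = 0.01 on the
  T1+T6 (left > right region) and T2+T3 (right > left) shares;
* LRT calibration: 300 null simulations (no region effect, grouping SDs
  0.2, 36 participants × 5 articles × 3 pages); the rejection rate at
  α = 0.05 must fall in the exact binomial 95% interval;
* recovery: 100 replicates of planted effects (+0.46 left, −0.13 right,
  participant SD 0.23; 36 participants × 100 pages); each fixed effect
  must lie within ±2 estimated SEs of its planted value in ≥ 90% of
  replicates. Coverage is asserted per coefficient: at ±2·SE the nominal
  per-coefficient coverage is 95.4%, whereas the joint event over both
  coefficients is nominally ~91% and would fail such a threshold by
  design even for a perfectly calibrated estimator.

## Known limitations

* The Laplace approximation is least accurate for very sparse counts with
  large variance components; the quadrature cross-check covers only the
  single-factor case (exact integration over crossed effects is
  exponential in the number of levels).
* The pairing rule is one defensible formalization of "temporally
  overlapping pairs"; alternatives (e.g. allowing one-to-many matches)
  would change unpaired tallies at stream edges.
* Region boundaries at screen thirds are a convention; analyses of
  orthographies with ragged margins may prefer text-extent bounds.
* No overdispersion handling (negative binomial) and no random slopes;
  counts that are overdispersed relative to Poisson will show
  anticonservative Wald p-values.
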