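# binocsync

Analysis pipeline for **small temporal asynchronies between the two eyes'
fixations in reading**.

When both eyes' fixation events are recorded (e.g. with a 500 Hz binocular
eye tracker), the left and right eye usually start and end each fixation
within a few milliseconds of one another — but not exactly together. These
small asynchronies are systematic: the eye nearer to the fixated part of
the text tends to arrive first and linger longer, a signature of *ocular
prevalence* (prioritizing one eye's input in the fused percept). This
package turns raw per-eye fixation streams into that analysis:

1. **Pairing** — match the two monocular streams into binocular fixations
   (temporally overlapping left/right pairs) by a dynamic program that
   finds the optimal non-crossing one-to-one matching by total overlap.
2. **Typology** — compute the start-time offset (right-eye start − left-eye
   start) and end-time offset, treat |offset| ≤ 2 ms as simultaneous
   (configurable), and classify each pair into nine types: the 3 × 3 cross
   of {synchronous, right eye early, left eye early} starts with
   {synchronous, left eye late, right eye late} ends — `Syn` and `T1`–`T8`.
   Left-eye-priority types are {T1, T6, T7}; right-eye-priority {T2, T3, T5}.
3. **Spatial distribution** — place each pair at the right eye's mean
   coordinates, bin into hexagons, and assign a left / middle / right
   screen region.
4. **Count models** — model the per-cell pair counts
   (participant × article × page × region) with Poisson regression:

   log E[count] = β₀ + β₁·[region = left] + β₂·[region = right]
                  + b_participant + b_article + b_page

   with middle as the reference region and independent (crossed) random
   intercepts. The GLM is fitted by IRLS; the mixed model by a Laplace
   approximation to the marginal likelihood (maximum likelihood, so nested
   models are compared by likelihood-ratio χ² as with `anova`). Results
   report Est/SE/z/p per coefficient, variance and SD per random factor,
   log-likelihood, AIC and BIC.

Because raw binocular reading corpora are rarely shareable, the package
includes a first-class synthetic generator (`binocsync.simulate`) that
emits 500 Hz-quantized binocular fixation streams over multi-line
1024 × 768 px pages, with long-tailed (Laplace) per-eye lags whose sign
bias depends on horizontal position — the structure the analysis is built
to detect — plus planted-ground-truth count tables for estimator tests.

## Worked example

```python
import binocsync as b

cfg = b.SimConfig(n_participants=4, n_articles=4, pages_per_article=3, seed=42)
session = b.simulate_reading_session(cfg)
pairs, unpaired = b.pair_streams(session.fixations)
pairs = b.classify_pairs(pairs)
pairs = b.assign_regions(pairs, cfg.screen)
dist = b.type_distribution(pairs)
print((100 * dist.proportions).round(1).to_string())

counts = b.count_table(pairs)
sub = counts[counts["type"] == "T6"]
null = b.PoissonCountModel(sub, region_effect=False, random_factors=("participant",)).fit()
full = b.PoissonCountModel(sub, region_effect=True, random_factors=("participant",)).fit()
print(full.summary())
lrt = b.lrt_compare(null, full)
print(f"LRT: chisq={lrt.chisq:.3f}, df={lrt.df}, p={lrt.p:.3g}")
```

prints (7,332 monocular fixations pair into 3,666 binocular fixations):

```
Syn    64.4
T1      7.4
T2      6.4
T3      6.5
T4      0.6
T5      0.9
T6     11.4
T7      1.8
T8      0.5
Poisson count model (Laplace GLMM)
==========================================================
term                   Est        SE        z          p
----------------------------------------------------------
intercept            0.773     0.105     7.38   1.63e-13
region[left]         1.049     0.120     8.76   1.99e-18
region[right]       -0.541     0.213    -2.54     0.0111
----------------------------------------------------------
random intercept          Variance          SD
participant (4)             0.0000      0.0000
All random intercepts were equal to zero.
----------------------------------------------------------
Observations 113   Log likelihood -196.512
AIC 401.025   BIC 411.934   k 4
LRT: chisq=147.796, df=2, p=8.06e-33
```

Most pairs are fully synchronous; among the asynchronous ones, T6 (left
eye starts first) dominates. The T6 fit shows what the region
coefficients mean: T6 counts are e^1.049 ≈ 2.9× higher at the left of
lines than in the middle, and e^−0.541 ≈ 0.6× lower at the right — the
left eye leads where the text is in left peripersonal space. The LRT
compares the region model against the intercept-only null.

A command line mirrors the stages:

```sh
binocsync simulate --seed 1 --out fx.csv
binocsync pair fx.csv --out pairs.csv
binocsync classify pairs.csv
binocsync counts pairs.csv --out counts.csv
binocsync fit counts.csv --type T6
binocsync all --out-dir run/          # full pipeline + manifest
```

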