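# Methods

## The problem

Tree-ensemble network inference (GENIE3 and relatives) scores a candidate
regulator→target edge by how well the regulator's expression profile predicts
the target's, treating every sample as an exchangeable observation.  On
time-series compendia this throws away two things at once: the *kinetic*
information in consecutive time points, and the fact that a transcript's
steady-state level confounds transcriptional input with mRNA stability.  A
slowly degraded target integrates its regulator's activity — its level is a
lagged, flattened echo that correlates poorly with the regulator — while its
*rate of change* remains tightly coupled to the regulator's current activity.
In multi-tissue or multi-subject compendia the problem is compounded by
between-series baseline offsets that dominate total variance.

This package implements a feature-engineering remedy: replace (or augment)
expression levels with the per-gene significance of each expression rate
change, then let the same tree-ensemble engine consume the new features.

## Rate-change significance (RANGES) and its expression-weighted form

For gene *g* with expression X sampled at times T₁…T_N within a series, the
slope of each consecutive step is

    C_g(t) = (X_g(T_{t+1}) − X_g(T_t)) / (T_{t+1} − T_t),

attached to the step's *from*-sample.  Slopes are only computed within a
series; a cyclic series (e.g. a circadian course covering whole periods)
additionally wraps from its last sample back to its first, using the series'
median sampling interval as the (positive, forward) wrap interval.  The
non-cyclic case drops the final sample's column instead.

All of a gene's slopes, pooled across series, form its null ("background")
for rate changes: the distribution of steps this gene takes anywhere in the
compendium.  Optionally the background is a bootstrap resample of the pooled
slopes (default 10,000 draws, one seeded substream per gene); the bootstrap
converges to the pooled empirical distribution, so the package's *direct*
mode (use the pooled multiset itself) is the exactly-reproducible default in
the test suite, while bootstrap mode reproduces the published procedure.

Each observed slope is then scored by its empirical tail probability with
add-one smoothing,

    p = (min(#{b ≤ C}, #{b ≥ C}) + 1) / (B + 1),

i.e. the smaller tail of the background ECDF, so that extreme rises and
extreme falls are both significant and p is never 0 (keeping −log₁₀ p
finite).  A published formulation folds the one-sided ECDF onto [0.5, 1]
("if P < 0.5 then P = 1 − P"), which caps −log₁₀ p at ~0.301 and erases the
significance signal; that variant is kept behind `tail="literal"` for
comparison, but the smaller-tail form is the default because it is the only
reading under which the feature does what it is described to do — emphasize
the expression level preceding a major change.

The signed significance and its expression-weighted form are

    R_g(t) = −log₁₀(p) · sign(C_g(t)),        E_g(t) = R_g(t) · X_g(T_t),

with sign(0) = 0 so flat steps give exactly R = 0.  Because each gene is
ranked against its own slope background, R is invariant to per-gene positive
rescaling of expression and to global rescaling of the time axis; E scales
linearly with per-gene expression.  These invariances, the step-count law
Σ(N_s − 1 + cyclic_s), and exact agreement of the tail p-value with
brute-force counting are enforced by property tests.

## Edge scoring

For every candidate target, a random-forest regression of the target's
feature row on all regulators' feature rows (the target excluded from its
own predictors) yields one importance per regulator.  The default importance
is the out-of-bag mean decrease in accuracy: for each tree, mean squared
error on the samples the tree did not see, before vs after permuting one
regulator's values, averaged over trees and scaled by the target's variance.
Out-of-bag evaluation keeps noise regulators near zero importance;
training-set permutation would reward memorisation.  Impurity-based variance
reduction — the canonical GENIE3 importance — is available as a cross-check
(`importance="variance"`).

Defaults follow common practice: 2,000 trees per target (drop to ~100 for
large target sets; analyses in this repository use 100), `sqrt` regulators
per split, and per-gene standardisation of feature rows.  Per-target
normalisation of importances to sum 1 (the canonical GENIE3 pooling) is
available but off by default: out-of-bag accuracy drops are already on a
comparable scale across targets, whereas sum-normalisation awards a full
unit of score even to targets whose forests explain nothing, promoting
noise edges in the global ranking.  Observation
columns are sorted into a canonical order before fitting, which makes scores
exactly invariant to observation permutations; each target draws its own
seed substream, so results are independent of parallelism and evaluation
order.  Ties in edge rankings break lexically by (regulator, target) so
downstream metrics are reproducible.

The engine is feature-agnostic: EXPRESSION runs use sample columns,
RANGES/ExRANGES runs use step columns; feature types are never mixed within
a run.

## Evaluation

Per-regulator ROC AUC equals the Mann–Whitney statistic (ties count ½; an
all-tied ranking scores exactly 0.5), checked against a brute-force pairwise
oracle.  Precision–recall curves use step-wise average precision.  Predicted
target sets are profiled by coefficient of variation (SD/mean, n−1
denominator) and by a within/between-series decomposition (within = mean over
series of the per-series SD; between = SD of per-series means).  Functional
cohesion of a target set is the sum over annotation categories represented in
the set of −log₁₀ hypergeometric upper-tail p-values (no multiple-testing
correction in the score by design; a Benjamini–Hochberg variant and a
significance-filtered variant are provided but non-default).  The enrichment
universe defaults to the genes scored in the inference run.  Recall-at-top-
fraction reports the share of gold pairs among the top ⌈fraction·edges⌉ of
the global ranking.

## The synthetic compendium

No public benchmark exercises the stability/offset confound with known
ground truth at desk scale, so the package ships a mechanistic generator.

**Study design.** Six series ("tissues") sampled every 2 h for 48 h
(24 samples each, cyclic with a 24 h period); 5 regulators, 20 targets each,
100 decoy genes.  Uneven designs draw per-series jittered time grids.

**Regulators.** Each regulator's latent activity is a random smooth periodic
waveform — a Fourier series over 4 harmonics of the period with 1/k^1.5
amplitude decay, RMS amplitude 5 expression units against a mean baseline of
10 (a 3–4 fold swing, as core clock genes show).  Fundamental peak phases
tile the cycle, and every series expresses the waveform with its own phase
shift (SD 2 h), amplitude factor (±30%) and a series-specific waveform
component (relative RMS 1.2) — the tissue-specific rhythms seen in real
multi-tissue data.  These ingredients are not cosmetic: a set of same-period,
shared-phase sinusoids is mutually collinear, and any lagged target then
matches some phase-shifted competitor as well as its true regulator, making
the planted truth unidentifiable *for every method*.  Waveform diversity and
per-series variation are what make causal attribution possible at all.
Aperiodic mode replaces waveforms with independent smoothed random walks per
series.

**Targets.** Each target integrates its regulator's activity through

    dY/dt = k·f(A(t)) − δ·Y,     f(A) = (A/K)^h / (1 + (A/K)^h),

explicit Euler with automatic sub-stepping (step ≤ 0.1/δ and ≤ ¼ of the
smallest sampling gap), initialised at the first time point's quasi-steady
state.  Defaults: strength k ≈ 1 (U(0.8, 1.2)), slow degradation
δ ~ U(0.05, 0.15) h⁻¹ (half-lives ≈ 5–14 h against a 24 h rhythm), Hill
coefficient h = 4, threshold K within the regulator's traversed range
(U(0.7, 1.4) × median activity).  Cooperativity makes targets switch when
the regulator crosses its threshold — coordinated regulator/target changes,
the regime rate-weighted features are designed for; a threshold far outside
the observed range would plant an edge no method could detect.  A repression
variant (f ↦ 1 − f) exercises negative rate signs.  A target with k = 0 has
no planted edge; it falls back to independent basal smooth dynamics so it
stays statistically exchangeable with decoys (otherwise a zero-production
gene would be flat and trivially distinguishable, biasing null evaluations).

**Measurement layer.** Every gene receives a baseline (U(0.8, 1.2) × 10),
a per-gene-per-series offset N(0, 3²) — dominating the targets' ~1-unit
within-series signal, as tissue baselines dominate daily variation — and
i.i.d. observation noise N(0, 0.2²); values are floored at 0.  Offsets are
deliberately *not* part of the activity driving targets: they model
measurement-scale tissue baselines, which is exactly the confound that
defeats level-based inference while leaving slopes untouched.  All
randomness flows from one root seed through named substreams (regulators /
targets / decoys / noise+offsets).

**What the generator does not emulate.** Count noise (negative-binomial
sampling), stochastic kinetics, combinatorial regulation of one target by
several TFs, regulator–regulator coupling, and probe-level artifacts.
Passing tests on this generator therefore show that the transform recovers
mechanistically planted, identifiable edges under the stability/offset
confound — not that it attains any particular accuracy on real compendia.

## Numerical and design choices

- Slope step attached to the *from*-sample; the expression factor in E uses
  the same sample ("the level preceding the change").
- Add-one smoothing bounds |R| by log₁₀(B+1); with the default bootstrap
  (B = 10⁴) that is 4.
- Background pooled across series per gene; pooling respects the design
  (e.g. 12 series × 24 cyclic steps → 288 slopes per gene).
- Permutation importances can be negative; normalisation clips at 0.  When a
  target's importances are all ≤ 0 the normalised vector is all zeros.
- Constant targets return all-zero importances rather than erroring.
- Self-edges are NaN and excluded from rankings; a regulator scored as a
  target must still have ≥ 2 other regulators as predictors.
- Degenerate inputs rejected with named coordinates: series with < 2
  samples, duplicate times within a series, non-numeric cells, duplicate
  ids, design/matrix sample mismatches.

## Problem sizes used in the shipped analyses

The acceptance analyses run the default compendium (205 genes × 144 samples,
five seeds, 100 trees per target, direct-ECDF backgrounds), a 38-gene null
compendium with zero regulation over 10–20 seeds, and 1,000-instance oracle
sweeps for the tail p-value and ROC computations.  These sizes were chosen so
a complete desk run finishes in minutes while keeping the per-seed AUC
estimates stable to a few hundredths.

## Known limitations

- With few regulators (the default study has 5), `sqrt` feature sampling
  gives 2 candidates per split; importance still leaks between correlated
  regulators, which bounds attainable AUC below 1 even at low noise.
- The rate features assume the sampling interval resolves the dynamics;
  harmonics near the Nyquist limit of the design decohere secant slopes from
  instantaneous rates.
- The enrichment score inherits the biases of annotation size and overlap;
  it is a cohesion summary, not a calibrated test statistic.
- `GoldStandard` treats unlisted pairs as negatives, as ROC evaluation
  against ChIP-style data conventionally does; incomplete gold standards
  deflate absolute AUCs without necessarily changing method rankings.
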