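# Methods

`cohsel` implements a complete pipeline for discriminating two patient
groups from resting-state EEG: band-coherence feature extraction, wrapper
feature selection by an ant colony (with GA and binary-PSO baselines),
SVM classification, and nested cross-validation. Because no clinical EEG
for this problem is publicly deposited, the package ships a synthetic
cohort generator with a closed-form coherence oracle, so every stage can
be validated quantitatively. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Synthetic cohort generator

Each recording is a sum over the analysis bands (delta 0.5–4 Hz, theta
4–8 Hz, alpha 8–13 Hz) of band-limited white noise, independent per
channel, plus band-limited *shared* sources: an optional background
source common to all channels, and one source per planted effect
injected with unit gain into both electrodes of its pair. Band limiting
uses an ideal FFT brickwall filter, so source and noise have identical
spectral shape inside a band and the magnitude-squared coherence (MSC)
of a pair is constant across the band with the closed form

    msc = (gx·gy·s)² / ((gx²·s + nx)(gy²·s + ny)),

where `s` is the shared-source variance and `nx`, `ny` the channel noise
variances. Source variances are solved from this expression so the
expected band MSC equals the class target; the same expression serves as
the independent oracle in the tests.

Defaults emulate a clinical-scale recording campaign: 46 + 55 subjects
(labels BD/MDD), 19-channel 10/20 montage, 250 Hz, 180 s eyes-closed
rest, and five planted pair–band effects with MSC 0.6 in one class
versus 0.2 in the other — `F3-C3` and `P4-T6` in alpha, `C3-C4` and
`P3-T5` in theta, `F3-F4` in delta. Within each band the planted pairs
share no electrode, so no effect leaks into another planted feature.
Background coherence defaults to 0 and per-band channel noise to unit
standard deviation.

What the generator does **not** emulate: 1/f spectra, artifacts (blinks,
muscle), volume-conduction structure, and between-subject variability of
the coherence targets. Every subject of a class has the same expected
band MSC, so with 180-s recordings the planted features are nearly
noise-free and the two classes are close to separable. The planted
benchmark is therefore a *correctness and recovery* check — does the
pipeline find the informative features and classify from them, and does
it fall to chance under label permutation — not a statement about
attainable accuracy on clinical EEG.

Two estimator-level caveats, both visible in the tests: (i) the Welch
MSC of independent channels is biased upward by about `1/L` for `L`
averaged segments (the bias floor); (ii) with 650-ms Hann windows the
spectral resolution is ~1.5 Hz, so Welch bins at a band edge mix in
noise from the neighboring band. The theta band, bounded by delta below
and alpha above, realizes band MSC roughly 0.08–0.10 below its target,
while alpha and delta land within ~0.02. The class contrast is preserved
in all bands; oracle-versus-target assertions use the alpha band.

## Coherence features

Per subject: zero-phase Butterworth band-pass 0.15–30 Hz (order 4,
forward–backward); segmentation into 650-ms windows with 50% overlap
(window length `floor(0.65·fs)` = 162 samples at 250 Hz, hop 81, the
trailing remainder discarded); per-window mean removal, Hann taper and
FFT; Welch-averaged auto- and cross-spectral densities; MSC
`|Pxy|²/(Pxx·Pyy)` clipped to [0,1]; arithmetic mean over the bins of
each band; Fisher-Z stabilization `z = atanh(√msc)` (the convention for
magnitude-squared quantities; `atanh(msc)` is available via
configuration). Windows are mean-detrended before tapering because the
0.15-Hz band-pass edge lies far below the resolution of a 650-ms window.
Single-segment MSC is identically 1 and is rejected (at least two
segments required).

The montage contributes 16 pairs — six left-intrahemispheric
(F3–C3, F3–P3, F3–T5, C3–P3, C3–T5, P3–T5), six right
(F4–C4, F4–P4, F4–T6, C4–P4, C4–T6, P4–T6) and four interhemispheric
(F3–F4, C3–C4, P3–P4, T7–T8) — times three bands = 48 features, ordered
pair-major then band. The interhemispheric temporal pair is kept as
T7–T8 (central-temporal) even though the intrahemispheric list uses the
classic posterior-temporal labels T5/T6; both label sets are present in
the 19-electrode montage used here. Band aggregation averages MSC before
the Fisher-Z transform; transforming first is a near-equivalent
alternative for narrow bands.

## Feature search

**Fitness.** Every search method maximizes
`f(A) = m·J(A) + n/|A|` with `m = 0.92`, `n = 0.78`, where `J(A)` is the
wrapper accuracy of an SVM trained on subset `A`. The size term makes
smaller subsets win accuracy ties.

**ACO.** One pheromone level per feature, initialized to 1 and clamped
to [0.1, 5] (max–min style, to delay stagnation). An ant draws a target
size `k` uniformly from (10, 35) — bracketing the subset sizes a wrapper
on 48 coherence features typically settles on — then picks `k` distinct
features by sequential roulette with probability ∝ `τ_j^σ · η_j^v` over
the not-yet-chosen features. The heuristic `η_j` is the per-feature
Fisher discriminant ratio `(μ₁−μ₂)²/(s₁²+s₂²+ε)` rescaled to (0, 1]; it
plays the role the inverse distance plays in routing applications of the
algorithm. After each iteration `τ_j ← (1−ρ)·τ_j + Σ_r δ·f(A_r)` over
the ants `r` whose subsets contain `j` (good subsets deposit more;
δ = 1, ρ = 0.2), then clamping. Runs stop at `n_iter` (default 50)
or after 10 iterations without best-fitness improvement. Repeated
subsets are served from a cache, so evaluation counts are distinct
classifier trainings.

**IACO.** The improved variant varies the heuristic parameters during
the run — the concrete schedule is this package's design choice, since
only the goal (less premature stagnation, faster convergence) is
standard: σ is interpolated linearly 1 → 2 and v 2 → 0.5 across the run
(early: trust the filter heuristic, explore; late: trust the learned
pheromone, exploit), and the evaporation rate is doubled (capped at 1)
while the best fitness has stagnated for 5 iterations, which flattens
the pheromone landscape and re-opens the search.

**GA baseline.** Binary chromosomes over features; tournament selection
(size 2), two-point crossover with probability 0.8, per-chromosome
mutation 0.2 flipping one uniformly chosen bit, one elite, all-zero
chromosomes repaired by setting a random bit. Per-bit mutation at 0.2
would randomize ~10 bits per child and destroy convergence, so the
per-chromosome reading is used. Fitness defaults to the same `f(A)` as
the colony for comparability; raw accuracy is available via
configuration.

**Binary PSO.** Real-valued velocities with sigmoid transfer
(bit j set with probability `1/(1+e^{−v_j})`), inertia 0.9 → 0.4
linearly, c₁ = c₂ = 2, velocities clamped to ±4.

## SVM

Soft-margin SVM with linear, polynomial and RBF kernels. The dual is
solved by scikit-learn's SMO backend to KKT tolerance 1e-4; support
vectors, their coefficients `α_i q_i` and the bias are extracted, and
decision values are recomputed as `f(p) = Σ α_i q_i K(p_i, p) + b` with
this package's own kernel code (cross-checked against the backend in the
tests). Defaults: penalty `C = 10` and
RBF width such that `γ = 1/(2σ²) = 0.2`. Features are standardized with
training-fold mean and SD before the SVM, since Fisher-Z coherences have
heterogeneous scales and the RBF kernel is scale-sensitive. Ties at the
decision threshold predict the positive class.

## Nested cross-validation

Six stratified outer folds; per outer cycle, five stratified inner
splits of the training portion. On each inner split the search method
runs with an evaluator that trains on the four inner-training folds and
scores accuracy on the verification fold. The five inner winners are
ranked by fitness (so smaller subsets break ties), the top subset is
refit on the entire outer training set, and evaluated once on the outer
test fold, which never participates in selection or training (a
row-hash leakage guard asserts this). Standardization parameters are
always computed on the training side of whatever split is current.
Reported metrics are the arithmetic mean of the six per-fold values —
accuracy and sensitivity at the zero-decision threshold and the
Mann–Whitney AUC (ties counted ½) — with the "globally best" fold model
retained for inspection. Fold sizes differ by at most one subject
(101 subjects → five folds of 17 and one of 16); the per-class chunk
rotation that achieves this is implemented directly rather than with a
library splitter, whose largest-first allocation yields 18/17/17/17/16/16.

The comparison table (one row per selection method) reports the median
subset size over outer folds, mean sensitivity, mean accuracy in
percent, the fitness of that (accuracy, size) operating point, and mean
AUC.

## Problem sizes used in the tests

The planted-cohort checks run the full pipeline at 20 ants × 30
iterations (20 seeded runs for recovery, 10 label-permuted runs for the
null); the structural comparison across all five methods uses 8
searchers × 10 iterations. These sizes were chosen so the whole suite
runs comfortably on a laptop while leaving the recovery and null results
far from their thresholds; the search budget is a configuration knob,
not a tuned constant.

## Known limitations

- The IACO schedule is one defensible realization of "dynamic heuristic
  parameters"; other schedules (e.g. rank-based deposits, restarts) may
  behave differently on harder landscapes.
- The synthetic benchmark is nearly separable by construction, so
  accuracy-based comparisons between selection methods are uninformative
  there; only feature recovery, chance behavior under permutation,
  convergence speed and subset-size structure are meaningful.
- Wrapper accuracy inside the inner loop is estimated on one
  verification fold per split; with ~14 verification subjects its
  resolution is coarse (~0.07), which the size term of the fitness
  partially compensates.
- Subset construction with a target-size draw controls subset size well
  but cannot return subsets outside (k_min, k_max); the bounds are
  configurable where a wider search is wanted.
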