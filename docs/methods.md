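# Methods

This note documents the models, algorithms and numerical choices behind
`sitmotif`, the synthetic cohort that exercises them, and what the test
suite does and does not establish about real chair data.

## Centre of pressure and presence

Four load cells sit under the seat corners: A1 front-left, A2 back-left,
A3 front-right, A4 back-right, each in kg after linear calibration
(`A ← gain·(raw − zero)`, negatives clipped and counted).  The COP is the
corner-weighted sum divided by four:

    x = (−A1 − A2 + A3 + A4) / 4,     y = (A1 − A2 + A3 − A4) / 4.

The coordinate deliberately scales with body weight: the segmentation
works on correlation structure (a Markov random field per state), which is
invariant to overall scale, and the unnormalised form keeps the map linear
and exactly invertible.  A load-normalised variant (divide by ΣAᵢ) is
available behind a flag for users who prefer weight-free coordinates.

Recordings are reduced to 1 Hz by keeping the first sample of each
one-second bin anchored at the series' first timestamp; dropout seconds
and seconds with total load under 5 kg become explicit absent samples.
Sitting time is the count of present seconds.  Windows for the
segmentation are built only inside contiguous present runs, so absences
split the series rather than contaminating windows.

## State model (TICC)

Each sitting state is a zero-lag-and-short-lag Gaussian dependency
structure over a window of w = 5 consecutive COP samples (n = 2 axes,
nw = 10).  The state's precision matrix Θ is constrained block Toeplitz —
sub-block (i, j) equals A(j−i) — so within-window dependencies are
time-invariant; A(0) carries the instantaneous partial correlation between
the two axes, A(k) the lag-k terms.  Unlike the common zero-mean variant,
each cluster also carries a window mean, since COP is not centred.

Fitting minimises, over assignments P and precisions Θ,

    Σ_i [ ‖λ∘Θ_i‖₁ + Σ_{X_t ∈ P_i} ( −ll(X_t, Θ_i) + β·1{X_{t−1} ∉ P_i} ) ]

by EM-style alternation:

* **Assignment** is solved exactly by a switching-penalised Viterbi pass
  (numba-compiled).  Ties stay with the previous state, then take the
  lower state id.
* **Precision update** per cluster is a block-Toeplitz-constrained
  graphical lasso solved by ADMM.  The proximal step for the ℓ1 term plus
  the Toeplitz constraint is exact: entries of Θ tied to one A-parameter
  form an orthogonal group, so the prox is "average the group, then
  soft-threshold".  λ = 0.001 is a scalar broadcast over the off-diagonal
  (the diagonal is unpenalised).  ADMM uses ρ = 1 with the standard
  residual-balancing adaptation, tolerances 1e-5/1e-4, at most 1000
  iterations; the returned Θ is the structure-exact iterate, with a
  diagonal bump (≤ 1e-8 above the most negative eigenvalue) if needed for
  positive definiteness.  A precision refit is kept only if it improves
  its cluster's penalised likelihood, so the objective trace is
  non-increasing by construction.

Initialisation uses a Gaussian mixture on per-window summary features
(window mean, log standard deviation per axis, within-window
cross-correlation; 10 restarts, seeded).  A mixture on the raw stacked
windows reliably collapses states that differ mainly in covariance scale —
the defining situation here — whereas the log-scale features separate
them.  Empty clusters are re-seeded from the worst-fit windows (logged).
Convergence: < 0.1 % of assignments change, or 100 iterations.

Defaults follow the study settings: w = 5 samples, β = 50, λ = 0.001.
Model order is chosen by BIC = −2 ln L + k ln n with L the maximised
assigned-window likelihood and k counted as the unique A-block entries
with magnitude above 1e-5 plus the nw mean parameters, per cluster.

**Known limitation.**  At short series lengths (T ≈ 2000) with skewed
state occupancy, the exact optimum of the objective occasionally prefers
splitting a heavily occupied state over separating two lightly occupied
ones (we verified the alternative labelling scores worse on such draws).
This is an identifiability property of the fitted objective at that data size,
not a solver failure; recovery tests therefore assert the median over
several simulated days.

## Motif model (MASA)

Motifs live on the run-length-compressed state sequence (adjacent repeats
merged).  A motif m must have |m| > 2 with adjacent entries distinct, and
must recur more than L times with non-overlapping instances; an instance
realises each motif state over ≥ 1 consecutive measurements.  The
motif-aware objective augments the state model with a per-measurement
reward: measurements outside every instance are charged log γ (γ = 0.9 by
default; lower is harsher), and motif strength enters as Ψ(M).

* **Candidate enumeration** collects all contiguous subsequences of the
  compressed sequence(s) up to length 6 and counts non-overlapping
  occurrences greedily left-to-right (multi-day data pools candidates
  across days; occurrences never span a day boundary).
* **Closed-pattern pruning.**  A candidate is dropped when a strict
  contiguous sub-motif recurs more often — its extensions are incidental
  context — and a sub-motif is absorbed when some super-pattern recurs
  exactly as often (it never occurs on its own).  Without this rule,
  one-sided extensions of a frequent core (core + whatever state tends to
  follow) regularly out-score the core.
* **Scoring.**  Ψ(m, q) = |q| · Σᵢ −log f(mᵢ), with f the empirical
  compressed-state frequencies: instance count times the motif's total
  surprisal under an independent-draws null.  The exact form is recorded
  in the model output.
* **Decoding** maximises the first three objective terms exactly by a
  Viterbi pass over an expanded graph: one node per ordinary state plus
  one node per position of each candidate motif (top 10 by score).
  Instances must complete (a motif can only be exited from its last
  position); back-to-back instances are allowed, including splitting one
  run of the shared boundary state.  With γ = 1 the decoder provably
  reduces to the plain assignment (ties prefer ordinary nodes).
* **Iteration** alternates enumeration → decoding → per-state precision
  refits, accepting a step only if the objective improves, so the trace is
  non-decreasing; it stops otherwise (≤ 5 iterations).

The top-scored motif is the "common motif"; the headline feature is its
instance count per 30 sitting minutes.  The phase of an alternation is not
identifiable from counts — (1,2,1) and (2,1,2) describe the same
behaviour — so recovery is always judged on the motif's state set.

## Classifier (weighted PNN) and tuning (SSA)

The per-class density is a Parzen sum over that class's training
exemplars with a shared smoothing σ and per-feature weights ω that make
the kernel elliptical (a larger ωⱼ shrinks the kernel along feature j,
increasing its influence; ωⱼ = 0 removes the feature, and the ω = 1 case
is the textbook Parzen estimate — an exact algebraic identity the tests
check to 1e-12).  Densities are evaluated in log space with log-sum-exp;
features are standardised on the training split; classification takes the
prior-weighted argmax (uniform priors by default; ties go to the lowest
class index).

Tuning minimises the mean categorical cross-entropy over 5 stratified
inner folds of the training split — one (σ, ω) applied to all five inner
models — plus a soft barrier 10·(0.1 − σ)/0.1 when σ < 0.1, where small
kernels memorise the training set.  The optimiser is the social spider
algorithm: spiders propagate fitness "vibrations" I = log(1/(f − C) + 1)
attenuated as exp(−d/(σ̄ r_a)) over Manhattan distance d, follow the
strongest perceived vibration with a dimension mask refreshed with
probability 1 − p_c^(inactivity) (bits set with probability p_m), and add
an inertia term; positions clamp to the box.  Defaults: population 20,
10 iterations, r_a = 1, p_c = 0.7, p_m = 0.1, σ ∈ [0.01, 10],
ωⱼ ∈ [0, 5].  The best-so-far trace is monotone (elitist bookkeeping);
non-finite objective values trigger a resample (logged).

Evaluation is nested: 6 stratified outer folds, tuning strictly inside the
outer-training split, one evaluation on the untouched outer fold; metrics
are accuracy and support-weighted precision/recall/F1, optionally repeated
with re-randomised folds (mean ± sd).  When the rarest class has fewer
samples than outer folds the fold count is capped at that size (logged);
classes with fewer than two samples are an error.  Chance level comes
from label-permuted (surrogate) runs of the identical procedure.  The
model handed to the attribution step uses the fold-median (σ, ω):
hyperparameters that exploit a fold-specific accident — e.g. a spurious
sex/category association in a small cohort — are unstable across folds,
and the median damps them.

## Attribution and group statistics

Shapley values are computed exactly: all 2⁵ coalitions, with f_S the
interventional expectation over a background sample (absent features
replaced by background rows, prediction averaged).  Efficiency
(Σφ = f(x) − E f) and the null-player axiom therefore hold to numerical
tolerance on every row, and additive models recover their closed form;
these are the correctness anchors.  Feature importance is the mean |φ|
over evaluation rows, summed across the three class outputs.

Motif rates across the three LBP-change groups are compared with the
Kruskal–Wallis H (tie-corrected, χ² reference) followed by Dunn's pairwise
z tests on pooled mid-ranks, unadjusted by default with Holm adjustment
behind a flag (the omnibus level is 0.05).

## The synthetic cohort

The generator emulates an office cohort at the observed study scale:
22 participants × 4 recorded days, 8 h days at 1 Hz, sex balanced,
weight ≈ N(65, 10²) kg.  Its moving parts:

* **States.**  Four canonical states with 2×2 precisions at realistic COP
  scales — stable sit (SD 0.08, weakly coupled axes), slight sway (SD 0.4,
  +0.6 partial correlation), big sway (SD 1.5, −0.5), off-chair (absent
  samples).  A 4-state *seated* variant for segmentation benchmarks swaps
  off-chair for a strongly anisotropic directional rock (SD 1.2 × 0.15).
* **Dynamics.**  Semi-Markov: geometric run lengths (means 320/110/45/190 s)
  and a label-based switching kernel calibrated so that the
  stable↔slight alternation is the dominant recurring pattern, the
  background alternation rate is ≈ 0.6 per 30 sitting minutes, and
  presence is ≈ 70 % of the day (≈ 5.6 sitting hours).  Segmentation
  benchmarks use uniform switching (balanced occupancy) instead.
* **Planted motif.**  Instances of the stable/slight alternation — each
  state 1–60 s, instance < 3 min — are spliced into seated spans at a
  Poisson rate per 30 sitting minutes.  Day categories (exacerbated /
  no change / improved, probabilities 40/43/7 over 90) set that rate to
  base_rate + effect_size·δ with δ = (−0.25, 0, +1).  The defaults
  base_rate 2.4 and effect_size 2.7 are calibrated so that the *measured*
  group rates — after the ≈ 0.6 chance baseline and the ≈ 0.6 decode
  attenuation (β = 50 smooths away planted runs shorter than ~8 s, and
  near-saturated days merge instances) — land near 1.6/2.1/3.7 per 30 min
  with an overall mean ≈ 2.0, the regime the method is meant to operate
  in.
* **Questionnaires.**  LBP slot scores are built backwards from the day's
  category (evening minus morning has the matching sign, intermediate
  slots interpolate with noise).  Sleepiness and fullness are participant
  traits (baselines ≈ N(6.6, 1.6²) and N(4.3, 3.0²)) plus small day-level
  category shifts (≤ 0.7 points) and day noise; category-conditional
  marginals then arise mostly through participant composition, and the
  day-level symptom signal stays below the motif-rate signal.
* **Sensors.**  The COP→load-cell inverse A = W/4 + corner·(x, y) is exact
  (out-of-hull COP is clipped and counted); additive Gaussian sensor noise
  of 0.05 kg per channel; off-chair emits zero load.

All randomness flows through explicit seeds; identical specs reproduce
datasets byte for byte.

**What the generator does not emulate:** biomechanics (spinal load, muscle
activity), sensor saturation or drift, diurnal non-stationarity of
postural dynamics, missing questionnaire slots, and participant-level
clustering of day categories (days are drawn independently).  Passing
tests therefore show the pipeline recovers structure *of the kind it
assumes*, with correct decoding, honest cross-validation and exact
attribution — not that real sitting data satisfies those assumptions.

## Problem sizes used in tests and the acceptance script

Chosen to keep a full run on one core in minutes: segmentation and BIC
checks use T = 2000 single days (5 and 20 seeds; BIC sweeps K = 2..6);
motif-recovery checks use 4 h single days (20 seeds); classifier and
attribution checks use study-scale cohorts (88 participant-days), with one
cohort for the surrogate comparison (20 permutations) and ten cohorts,
without permutation re-runs, for the attribution ranking; repeated CV in
the acceptance script uses 3 repetitions.  The sphere benchmark for the
optimiser runs 20 seeds at 500 iterations.
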