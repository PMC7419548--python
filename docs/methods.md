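# Methods

`endomod` implements a two-stage penalized logistic pipeline for asking
whether endogenous (pre-stimulus) neural activity modulates trial-by-trial
visual category decoding in intracranial EEG, and whether the same aspect of
that activity predicts behaviour. Because no public iEEG dataset with this
task structure exists, the pipeline ships with, and is validated on, a
synthetic session generator with known ground truth; real data in the same
on-disk contract (HDF5 traces + CSV trial/electrode tables) can be dropped
in unchanged.

## The model

For one electrode, let `X_evk` (trials x 440) hold the post-stimulus
features — 400 samples of the 0.2–115 Hz band-passed single-trial potential
(stP) and 40 samples of single-trial broadband high-frequency activity
(stBHA, mean baseline-z-scored 40–100 Hz spectral power at 100 Hz) from the
[100, 500) ms window — and `X_pre` (trials x 560) the same two feature kinds
from the [−500, −100) ms window plus 60 pre-stimulus DFT phases encoded as
(sin θ, cos θ) pairs. `y ∈ {0,1}` marks trials of the electrode's preferred
category (one-vs-rest).

Stage 1 (elastic net, α = 0.95):

    β*_evk = argmin  ℓ(β) + λ₁ [ (1−α)/2 ‖β‖₂² + α ‖β‖₁ ]

with ℓ the logistic cross-entropy. Stage 2 freezes the stage-1 linear
predictor as an offset and fits the pre-stimulus features with a *group*
elastic net in which each phase's (sin, cos) pair is penalized by √2 times
its Euclidean norm, making the penalty invariant to phase direction:

    β*_pre = argmin  ℓ(offset; β) + λ₂ [ (1−α)/2 ‖β‖₂² + α‖β_stP‖₁
                                          + α‖β_stBHA‖₁ + α√2 Σ_k ‖β_phase_k‖₂ ]

The per-trial **modulation index** MI = X_pre β*_pre (intercepts excluded)
is the signed shift of the classification boundary attributable to
pre-stimulus activity. Both λ's are chosen by nested cross-validation: a
stratified outer 5-fold loop yields held-out decision values and MI for
every trial; an inner 10-fold loop on each outer training set picks λ by
minimum mean held-out deviance along a geometric path of `n_lambda` points
from λ_max (the KKT bound at the zero solution) down to 0.01 λ_max.
Sensitivity is summarized as d′ = Z(TPR) − Z(FPR) from pooled held-out
decisions, with rates clipped to [1/(2n), 1 − 1/(2n)]; the headline quantity
is Δd′ = d′(post+pre) − d′(post only).

### Solver

Both stages are solved by penalized iteratively-reweighted least squares
with (block) coordinate descent: closed-form soft-thresholding for single
columns, a majorized group-soft-thresholding step for (sin, cos) pairs,
warm starts along the λ path, sequential strong-rule screening verified
against the full KKT conditions after each solve (screening can therefore
never change the solution), and an objective backtracking safeguard that
halves the IRLS step until the penalized objective is non-increasing.
Convergence is declared when the largest coefficient change falls below
`tol` (default 1e-7 on the standardized scale; capped at 1e5 coordinate
sweeps, with non-convergence flagged on the result, never silent). Fits
used only to *rank* λ values inside the inner CV run at a relaxed
`inner_tol` (default 1e-3): the held-out deviance curve is flat on that
scale and the selected λ is unchanged, at roughly a tenth of the cost. All
final coefficients come from full-tolerance solves. The suite verifies both
stages against an independent accelerated proximal-gradient (FISTA) solver
on the identical objective.

### Design choices in the CV procedure

Two places in the nested CV admit more than one reading; we chose the
leakage-free one in both and note the consequences.

* **d′ threshold.** The model's printed form carries no intercept, where
  thresholding decisions at zero is a prior-balanced rule. We keep an
  unpenalized intercept (necessary for a sane deviance under the 1:5
  one-vs-rest imbalance) and instead threshold held-out decisions at the
  empirical prior log-odds. Thresholding at raw probability 0.5 with the
  intercept in place predicts the positive class almost never (TPR pinned
  to its clipping floor), which reduces d′ — and any Δd′ — to an artifact
  of the clipping rule.
* **Cross-fitted stage-2 offsets.** During λ₂ selection and the stage-2
  refit, each training trial's offset X_evk β*_evk is computed from the
  inner-fold stage-1 model (at the selected λ₁) that never saw that trial.
  Using one stage-1 fit of the whole training set would hand stage 2
  in-sample, overconfident offsets; the inner deviance then underrates the
  pre-stimulus features and λ₂ collapses to λ_max, so the model learns
  nothing. Held-out test offsets are out-of-sample either way.

Standardization: stP and stBHA columns are standardized per training fold
(statistics frozen and applied to the held-out fold); phase (sin, cos)
columns are left on their natural, unit-norm scale so the group penalty's
rotation invariance is preserved end to end (a fixed phase offset at any
frequency provably leaves held-out decisions, MI and d′ unchanged; the
suite checks this).

## Electrode selection

A ridge-regularized 6-way multinomial classifier (scikit-learn, fixed
C = 0.01; the 440-column design against ~384 training trials is ill-posed
without it) is scored by stratified 5-fold CV; pooled held-out predictions
give one-vs-rest TPR/FPR and d′ per category. An electrode is
category-selective when its maximum d′ exceeds 0.5 and the winning category
also has the largest mean post-stimulus response — mean |stP| (polarity is
reference-dependent) or mean stBHA; requiring *either* to agree is the
default, *both* is a flag. A label-permutation utility can recalibrate the
threshold. Note the bare d′ > 0.5 cut is not a 5% test at this design size:
the max over six categories of the null d′ (sampling SD ≈ 0.1 at 480
trials) exceeds 0.5 in roughly a fifth of permutations; the false-selection
control comes from the threshold *and* the mean-response constraint
together (kept ≤ ~5% empirically).

## Downstream statistics

* **MI–RT correlations** (Spearman) over repeat trials with a recorded RT,
  separately for the electrode's preferred and non-preferred categories.
* **Quartile contrasts**: mean over the top ⌈N/4⌉ trials by MI minus mean
  over the bottom ⌈N/4⌉ (ties broken by trial position), applied to RT and
  to pre-stimulus stBHA mean/SD and |stP| mean/SD.
* **Random-projection permutation null** for those contrasts: each
  surrogate draws a random support of the same size as β*_pre's support,
  fills it with N(0,1) weights, recomputes MI = X_pre β and the statistic;
  two-sided add-one p-values. With per-fold coefficient vectors from the
  nested CV, the representative β_pre is their across-fold mean and the
  support size the median per-fold support.
* **Cross-electrode MI correlation**: Spearman ρ across trials for every
  electrode pair more than 2 cm apart, averaged separately over
  same-selectivity and different-selectivity pairs. The null permutes each
  electrode's MI series across trials independently, destroying the
  cross-electrode pairing the statistic measures; the original analysis
  reran the whole pipeline under shuffled category conditions, which is not
  tractable per permutation at desk scale and is approximated by this
  pairing-shuffle without refits.
* **MI autocorrelation** r_k for lags 1–20 with the printed estimator
  (numerator truncated at T − k, denominator over all T) and the
  approximate 95% bound 2/√T on lag 1.
* **Post-stimulus control**: the Spearman correlation between the held-out
  stage-1 loadings X_evk β*_evk and RT on preferred repeats, to check the
  MI–RT link is not a generic decision-value–behaviour relation.

## The synthetic session generator

One session is 6 categories × 30 images × 2 presentations = 360 base
presentations in random balanced order, with an exact repeat of the
preceding image inserted after a deterministically realized third of them:
480 trials, 120 with a reaction time. (The source design is described both
as "1/3 of the time" and as "20% of trials"; we fix the repeat count at 120
because 480 total trials is the stated number, and expose the fraction in
the config.) Epochs span [−900, 900) ms at 1000 Hz in microvolts; four 3 s
inter-run baseline segments per electrode support stBHA z-scoring.

Latent state: each category network c carries an AR(1) series G_{c,t}
(coefficient ρ_trial, default 0; stationary variance 1), and electrode e in
network c(e) has g_{e,t} = w·G_{c(e),t} + √(1−w²)·η with loading w = 0.8 —
so same-network electrodes share state (corr ≈ w²) and different networks
are independent.

Traces are a sum of: 1/f² background (0.5–200 Hz, 12 µV RMS; the spectral
slope keeps sample-to-sample steps far below the 25 µV artifact criterion,
as in clean recordings); 10 Hz (6 µV) and 15 Hz (5 µV) oscillations with
per-trial uniform phase, the 15 Hz phase at onset recorded as ground truth;
band-limited 40–100 Hz noise (4 µV) whose pre-stimulus variance is scaled
by (1 + c_g·g_t), c_g = 1.0 — the read-out channel from state to stBHA; and
a post-stimulus evoked response. Evoked templates s_c(t) are damped
sinusoids (latencies 110–310 ms, frequencies 3–8 Hz, τ = 130 ms) normalized
to a common analysis-window RMS of 3.5 µV and weighted by (5.5/f)^0.8 so
that templates riding on the 1/f² background are comparably discriminable;
an electrode responds at full amplitude to its network's category and at
0.25 to the others, which is what makes it category-selective. At default
noise the 6-way classifier lands at d′ ≈ 1.5–2 for the preferred category
and the one-vs-rest two-stage model at d′_evk ≈ 0.6–1.2, bracketing the
regime the method is meant for.

The latent state reaches the evoked response through three mechanisms, all
zeroed in a null session:

1. **Gain** (γ = 0.3): the evoked template is multiplied by
   (1 − γ·g_t) — a high endogenous state weakens single-trial tuning. This
   is the mechanism that fixes the *sign* of the fitted MI (+g in every
   network). A purely additive category-independent drift cannot do that:
   for near-orthogonal templates, the overlap of any fixed waveform with
   the six one-vs-rest discriminant directions sums to exactly zero, so
   additive coupling would give some categories MI ∝ +g and others
   MI ∝ −g.
2. **Circuit-specific drift** (κ = 3 µV per unit g): every trial's evoked
   window receives κ·g_t·u_e(t) with u_e the negated unit-RMS template of
   the electrode's own network category — stimulus-independent suppression
   of activity along the circuit's response pattern. Because the classifier
   must read exactly that pattern, this common-mode fluctuation cannot be
   evaded by feature selection; it is the decision-value noise that stage 2
   measurably removes (the source of Δd′ > 0). A drift built from a mixture
   of all templates fails here too: the sparse stage-1 fit simply selects a
   combination of features in whose span the drift cancels.
3. **Phase gate** (c_φ = 0.6): the evoked template is additionally scaled
   by (1 + c_φ·cos(θ₁₅ − θ₀)), coupling the 15 Hz phase at onset to evoked
   amplitude; the phase is exactly readable from the pre-window DFT.

Reaction times exist only on repeat trials: RT = 665 + 40·G_{c,t} + N(0,
90²) ms, driven by the *network* latent of the trial's own category — so an
electrode's MI predicts RT for its preferred category only, by
construction. The RT slope is chosen so the per-electrode MI–RT Spearman ρ
(~0.1–0.4 at ~20 preferred repeats) is detectable across a 20-seed batch;
the implied top-vs-bottom-quartile RT difference (tens of ms) is larger
than the ~19 ms the motivating study reports, a deliberate desk-scale
power choice, not a fitted quantity.

All randomness flows from one root `SeedSequence` through named spawns
(trial order, latents, RT noise, one stream per electrode), so components
are independently reproducible and sessions are bit-identical given a seed.

### What the generator does not emulate

Volume conduction and anatomical geometry; spike-level dynamics; epoch-to-
epoch continuity of the background (epochs are independent draws);
session-level nonstationarity beyond the AR(1) latent; eye movements,
epileptiform artifacts, or any structured artifact beyond what the
amplitude/jump criteria target; and real categorical structure in images
(templates are abstract waveforms). Passing the recovery suite therefore
shows the *pipeline* is correct and well-calibrated under the stated
generative assumptions, not that any particular real dataset satisfies
those assumptions.

## Numerical and procedural details

* Filters: 4th-order Butterworth, applied forward–backward (zero-phase), so
  stP inherits no phase distortion; the 55–65 Hz stop-band removes line
  noise before anything else. The 0.2 Hz band edge implies multi-second
  transients; analysis windows sit far from epoch edges.
* stBHA: Hann-tapered 200 ms segments centred every 10 ms, zero-padded to a
  2 Hz bin grid (2–100 Hz); raw power z-scored bin-wise by inter-run
  baseline mean/variance (log-power behind a flag); mean over 40–100 Hz.
* Phase: DFT of the 400-sample pre-window; the 60 features are bins
  2.5–150 Hz (DC carries no phase). Phases are taken after line-noise
  removal only (a flag restores literally-raw input).
* Artifact rejection: a trial is dropped when its max |amplitude| exceeds
  the mean + 5 SD of the per-trial max-amplitude distribution (the
  reference distribution is the per-trial maxima; the source text leaves
  this implicit) or when any consecutive-sample step exceeds 25 µV. Both
  thresholds are config values.
* Quartile size ⌈N/4⌉; ties in MI broken by trial position. Two-sided
  add-one permutation p-values throughout. Group-level summaries use
  ordinary paired t-tests.
* The pipeline (`simulate → features → select → fit → stats → report`)
  hashes its full configuration; a stage re-runs only when its outputs or
  the hash are stale, and a downstream stage refuses upstream outputs
  produced under a different hash. Integer sub-seeds (session, CV,
  selection, permutation) derive from the root seed via `SeedSequence` and
  stay below 2³¹.

## Problem sizes in the shipped suite

The test suite exercises the full nested-CV model on sessions of 2–4
electrodes with the complete 480-trial design, a 10-point λ path, and
20-seed batches for the calibration and recovery claims; permutation
calibrations use 200 replicates at 199 permutations. These sizes are the
package's validation defaults; the pipeline's own defaults (12 electrodes,
100-point path, 1000 permutations) match the study-scale configuration and
run in minutes per electrode on one core.

## Known limitations

λ selection minimizes inner-CV deviance with no 1-SE rule, so the stage-2
support size fluctuates across folds; the representative β_pre used by the
random-projection null is the across-fold mean. The cross-electrode null
does not refit the GLM per permutation (see above). d′ from thresholded
rates is granular at 480 trials (steps of ~0.01–0.05); Δd′ claims are
therefore made over seed batches, never single sessions. The multinomial
selection step delegates to scikit-learn rather than the in-package solver;
the two-stage model itself never does.
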