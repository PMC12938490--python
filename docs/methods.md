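# Methods

`embaudit` audits embedding-based regression: the practice of converting text
prompts into fixed-length vectors with a language encoder and regressing a
behavioral target on those vectors with an L2 (ridge) penalty. The package
asks one question of such pipelines — *does apparent predictive success
survive when evaluation requires extrapolating beyond the training target
distribution?* — and provides the machinery to answer it: synthetic study
generators with known ground truth, a synthetic encoder with the local
similarity structure the method exploits, the regression itself, a taxonomy
of hold-out regimes, and diagnostics (the SD score and ordinal-adequacy
tests) that make extrapolation failure visible.

## The evaluation protocol

For a dataset of *n* prompts with embeddings `X` (n x d) and target `y`:

1. **Split** the rows into train/test by one of three strategies:
   * `random` — a seeded random test fraction. Test targets span the training
     distribution, so evaluation is exercisable by interpolation
     (out-of-sample, in-distribution).
   * `quantile` — the test side is the lowest, middle, or top fraction of the
     *target values*, rank-ordered with stable ties. `top`/`lowest` force
     extrapolation outside the training range; `middle` carves an interior
     band the model must bridge. The middle band is centered on the median by
     rank (rank-based bands remain well defined under ties and skew); the
     test size is `round(fraction * n)` with halves rounded away from zero.
   * `condition` — all rows with the named condition labels form the test
     side (out-of-domain/condition hold-out).
2. **Fit** ridge (continuous y) or logistic ridge (binary y) on the training
   embeddings. Coordinates are standardized before penalization and the
   intercept is unpenalized. The penalty is selected by seeded k-fold
   cross-validation over a grid (squared error / binomial deviance), using
   the one-standard-error rule by default: the most regularized penalty whose
   CV loss is within one standard error of the minimum. With d >> n the
   loss-minimizing penalty often lets an in-sample fit interpolate the target
   exactly, which would make the SD denominator (below) meaningless; the 1se
   rule is the standard guard. `selection_rule="min"` is available.
3. **Predict** the test side with the trained model.
4. **Exchange**: fit a second model *with the identical configuration* on the
   test side itself and take its in-sample fitted values as the reference —
   the best account of the test data that this model family, fitted on this
   data, gives.
5. **Diagnose**:
   * Pearson r (continuous) or accuracy at a 0.5 threshold with ties
     predicted positive, plus a deviance-based determination coefficient
     (binary). An undefined correlation (zero variance) is reported as NaN,
     never silently 0.
   * **SD score** = (summed distances of transferred predictions from the
     test targets) / (summed distances of the fit-on-test reference from the
     same targets). Distances sum absolute deviations by default (`l1`); the
     Euclidean norm (`l2`) is available. A score of 1 means the transferred
     weights describe the test side exactly as well as weights estimated on
     it (model integrity); scores well above 1 signal extrapolation
     breakdown; below 1 warrants inspection. The ratio is scale-free. Across
     repeated well-specified splits, log(SD) should center on 0; the summary
     flags consistency when the mean log score is within a configurable band
     (default ±0.2). A denominator below 1e-10 relative to the target scale
     raises an explicit degenerate-denominator error with both raw sums
     attached: a perfect reference fit means the diagnostic is undefined,
     not that integrity failed.
   * **Ordinal adequacy**: cluster means of an a-priori expected ordering are
     compared between the observed data and the model's account of it. The
     default clustering bins *all* rows into rank bins of the observed target
     (6 by default) and uses in-sample fitted values on the training side and
     transferred predictions on the test side, asserting the observed
     increasing order of bin means. A *reversal* is an assertion that holds
     in the observed means whose strict inverse holds in the model's means —
     e.g. extrapolated predictions for the top target bin falling below the
     fitted values of adjacent training bins. Binning across the whole range
     was chosen over test-side-only bins because the prediction-vs-fit
     contrast across the train/test boundary is the stable signature of
     extrapolation collapse; within a carved-out band the predictions are
     dominated by extrapolation noise and any within-band contrast is
     jitter-limited.

Every stage is seeded; a master seed fans out to per-stage seeds by
stage-name hashing, so adding a regime never perturbs another's randomness,
and an emitted effective configuration replays bit-for-bit.

## The synthetic encoder

Real final-layer embeddings have one property this whole method depends on:
prompts carrying nearby concept values ("This is number 37" / "This is
number 38") produce nearby vectors, with similarity falling off as the
concepts separate. `SyntheticEncoder` reproduces exactly that property with
no pretrained weights. Each signal coordinate is a sum of Gaussian bumps of
width `length_scale` at several (`n_centers`, default 8) seeded random
locations over the concept range. Consequences:

* rows co-activate strongly when concepts are within ~1 `length_scale`, and
  only weakly — through accidentally shared centers — at long range;
* every coordinate varies over *any* concept subset, as real embedding
  coordinates do. This matters: a basis with coordinates that are flat on
  the training side (e.g. one bump per coordinate) explodes under the
  regression's standardization when those coordinates wake up on held-out
  concepts, and a basis with global components (e.g. unconstrained random
  Fourier draws, whose frequency distribution puts mass near zero) hands the
  model genuine long-range trends to extrapolate, which real number-prompt
  embeddings do not provide.

A configurable fraction of coordinates (default 0.25) are concept-independent
distractors, derived deterministically from a hash of the prompt text, and
i.i.d. Gaussian noise (default sd 0.05) is added per entry. Identical
prompts therefore produce identical noiseless rows, and identical seeds
reproduce the matrix bit-for-bit. A real transformer adapter slot exists
(mean pooling over final-layer token states, a pinned choice); it raises an
explicit capability error when its optional dependency is absent.

Because extrapolated predictions beyond the training concept range are sums
of weights fitted to flank data times pseudo-random basis activations, they
wander around the training mean — which is the realistic behaviour: what an
embedding regression predicts for prompts outside its training manifold is
unconstrained by the data it saw.

## Synthetic studies and their parameters

**Number-prompt study (`usecase1-*` presets).** Prompts "This is number n",
n = 0..100 step 1, each replicated 30 times with independent Gaussian rating
noise (sd 0.5) around the linear target y = n. Replication emulates the
aggregated-ratings reliability structure of severity-rating studies (many
ratings mapping onto the same stimulus) and is load-bearing twice: it is why
random out-of-sample validation reduces to predicting a stimulus from its
own replicates (the data-reliability reading of OOS success), and it anchors
the fit-on-test reference at the within-stimulus noise floor, which keeps
the SD score's denominator meaningful. The V-shaped variant folds the same
target about its median — `a + b*|y - pivot|`, rescaled onto the original
min/max range — which destroys linear recoverability of the concept while
preserving interpolability; the fold's pivot and scaling are this package's
choice since any symmetric, range-preserving V plays the same role. Encoder:
dim 256, length scale 0.5 (adjacent numbers co-activate modestly, numbers a
few units apart essentially not at all), distractor fraction 0.25, noise
0.05.

Because predictions inside a carved-out band wander, single-study statistics
there fluctuate across seeds (the band holds only ~33 distinct concepts);
the battery therefore reports medians over 7 replicate studies, exactly as
the trial-series battery aggregates over participants.

**Condition study (`sleep-study`).** Three ordered conditions with means
(90, 70, 50), within-condition sd 5, 20 participants each, every participant
carrying an individual prompt (a shuffled stimulus-order token). The concept
scalar is the condition index. Holding out the middle condition is an
interpolable hold-out; holding out an extreme one is not.

**Trial series (`trial-prompt`).** A stationary AR(1) series (150 trials,
coefficient 0.8, innovation sd 1) prompted "This is trial t". AR(1) is the
minimal process with trial-index-predictable autocorrelation, standing in
for repeatedly measured neural activity. The paired feedback-prompt variant
replaces the prompts with texts stating only which option was rewarded (an
i.i.d. reward amount as the concept), so the prompts carry no trial-index
information — isolating what the prompt template alone contributes. Encoder
length scale 1 trial.

**Horizon task (`horizon`).** Two horizon conditions (1 and 6 choices per
game), 500 games each; a game in horizon h contributes h choice rows with
remaining-trials labels h..1. The probability of choosing the
better-prior-mean option is `base_p_best + exploit_growth * (choices made)`
plus `first_choice_explore_gap` for the short horizon, with defaults 0.3,
0.1, 0.15: early long-horizon choices sit below chance (directed exploration
of the lesser-known option), exploitation crosses chance mid-horizon, and
the short horizon's only choice is more exploitative than the long horizon's
first by exactly the gap. The below-chance early regime is deliberate — if
every condition's P(best) sat on one side of 0.5, predicting the majority
class would already be Bayes-optimal and no classifier could demonstrate
anything beyond the base rate. Prompts encode both options' prior samples
and the remaining-trials count (the concept scalar); condition labels
`h{horizon}-r{remaining}` expose both factors, and the preset's hold-out
withholds all remaining-trials 1-3 prompts, so the model must extrapolate
below the remaining-trials range it trained on.

## What passing these batteries does and does not show

The generators reproduce the *statistical structure* each scenario needs —
concept-graded similarity, reliability through replication, autocorrelation,
ordinal condition effects — and nothing else. They do not emulate natural
language variability, fMRI noise spectra, disease-description semantics, or
individual differences. A battery that passes shows that the audit
machinery detects interpolation success and extrapolation failure where
those are present by construction; it says nothing about any particular real
encoder or dataset, which is the point: the diagnostics, not the synthetic
data, are the deliverable.

## Numerical choices and degenerate inputs

* Ridge is solved by one SVD of the standardized training matrix per fit
  (the whole penalty path reuses the factorization); at penalty 0 it
  degenerates to the minimum-norm least-squares solution with an rcond
  cutoff of 1e-10 on singular values. Logistic ridge delegates to
  scikit-learn's solver with `C = 1/lambda`.
* The automatic continuous penalty grid is `n * logspace(-5, 3, 15)` —
  after standardization the Gram diagonal is ~n, so lambda/n indexes the
  effective-degrees-of-freedom range. The binary grid is
  `logspace(-1, 4, 6)`. Fold count defaults to 10 (5 in the horizon preset,
  where fits are costlier).
* Constant embedding columns pass through standardization with scale 1.
  Predicted probabilities are clipped to (1e-12, 1 - 1e-12).
* Constant binary targets, all-equal quantile targets, empty ordinal
  clusters, exhaustive condition hold-outs, and malformed prompt templates
  raise typed errors rather than producing silent defaults.
* Quantile ties are broken by stable row order; the middle band gives the
  extra row to the low flank when the remainder is odd.

## Problem sizes

The bundled batteries run at the sizes stated above: 3030 rows for the
number-prompt study (7 replicate studies, plus 100 repeated random splits
for the log-SD consistency check), 30 simulated participants of 150 trials,
and 3500 horizon choice rows. These sizes put every reported median well
inside its sampling band while keeping a full battery run in the
low minutes on one CPU.

## Known limitations

* The synthetic encoder models similarity as a function of a scalar concept
  only; multi-factor prompts are represented only through condition labels.
* The SD score inherits a mild upward bias when the exchanged test side is
  much smaller than the training side (its reference concept-mean estimates
  pool fewer replicates); at the bundled study sizes the bias is ~0.15 on
  the log scale and is part of what the consistency band absorbs.
* The transformer adapter is a convenience, not a validated replication
  path: pooling and layer choice are pinned but real-encoder behaviour is
  outside the test surface.
* `quantile` hold-outs are defined on the behavioral target, not on prompt
  features; prompt-space out-of-domain designs are expressed through
  condition labels constructed by the caller.
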