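# Methods

This note documents the models implemented in `infoval`, the assumptions of
the synthetic-data generator, and the numerical and design choices made
where the procedure was genuinely open.

## The task being modeled

Each trial offers a choice between two four-outcome reward lotteries
("offers"). Every offer carries:

* a reward distribution: four magnitudes, each delivered with probability
  1/4 if that offer is chosen. Distribution families: *safe* (four equal
  bars), *50/50* (two bars d below the mean, two bars d above), *25/50/25*
  (one bar d below, two at the mean, one d above), and *25/75* (one bar 1.5 d
  from the mean, three balancing bars on the other side). All magnitudes are
  discretized to multiples of R_step in [0, R_max] (e.g. 0.02-ml steps up to
  0.6 ml gives 31 possible amounts, or integer coins for the human variant).
* an informativeness flag: informative offers reveal the eventual outcome
  with an early cue; non-informative offers present a matched but
  uninformative cue. The information is non-instrumental — it cannot change
  the outcome.
* in the timing ("clock") task version, a pair of event times: the cue at
  t_cue ∈ [0.4, 5.8] s and the reveal at t_rev ∈ [1.2, 6.7] s after choice,
  both multiples of 0.1 s with t_rev − t_cue ≥ 0.8 s, drawn uniformly from
  the enumerated valid set; reward arrives 1.1 s after the reveal
  (t_out = t_rev + 1.1). The fixed-timing version pins t_cue = 0.5 s,
  t_rev = 4.0 s, t_out = 4.5 s.

75% of trials draw each offer's features independently and uniformly; the
remaining 25% present the same lottery (and timing) with opposite
informativeness, the trials most diagnostic of information preference.
Optionally, offer 2's expected reward is constrained to a window around
offer 1's — the task's device for avoiding trivial decisions; it also
concentrates statistical power on the non-E[r] attributes.

## Behavioral model

Binary choices are fitted with a binomial GLM with logistic link and no
intercept, on attribute *differences* (offer 2 minus offer 1); the model is
therefore antisymmetric under relabeling the offers. Uncertainty is
operationalized as one of

    SD[r]      = ( Σ_r p(r) (r − E[r])² )^½
    Range[r]   = max(r) − min(r)
    Entropy[r] = −Σ_r p(r) log₂ p(r)   over *distinct* magnitudes

Entropy aggregates equal bars before forming probabilities; otherwise every
four-bar lottery would score 2 bits and the 25/50/25 (1.5 bits) vs 50/50
(1 bit) contrast — the only design feature that dissociates entropy — would
vanish. Informativeness is coded {0, 1}, so interaction weights read as "the
effect of information", and a main-effect weight is the value of information
for a certain (safe) offer.

Non-convergent fits (separation: runaway weights or standard errors) are
flagged and excluded rather than reported, mirroring the exclusion of
individuals whose behavior is too deterministic to constrain the model.
Significance is two-tailed Wald at α = 0.05 with no multiplicity adjustment
throughout.

**Shuffle-corrected log likelihood.** Models with different attribute counts
are compared by LL(fit) − mean over shuffles of LL(fit to choice-permuted
data); permuting choices across valid trials and refitting measures the
chance-level gain of each parameterization. Default 100 shuffles, seedable;
a cross-validated variant (both terms held-out likelihoods) is available but
the plain version is the default. Bootstrap CIs for between-model
differences resample per-trial log-likelihood contributions of the two real
fits (2,000 draws) and carry the model-level shuffle-correction constants;
refitting every shuffle inside every bootstrap draw would cost ~10⁵ fits for
no change in the interval at this scale.

**Willingness to pay.** On trials whose offers differ in informativeness,
choice of the informative offer is fit as a logistic function of
x = E[r]_info − E[r]_noinfo; WTP = −(indifference point), with SEs from 200
bootstrap resamples (over trials for individual fits; over individuals for
the population fit, which fits the across-individual mean curve by least
squares). Slope ≤ 0 or an indifference point outside the observed x-range is
flagged as extrapolated.

**Attribute selection.** Greedy forward selection on 5-fold cross-validated
log likelihood, stopping when the selected set reaches 99% of the full
candidate model's above-chance CV likelihood; one fold split is shared by
all candidate models, and ties break in candidate-list order.

**Stimulation model.** Offer-period microstimulation is modeled as
subtracting a fixed value s from the stimulated offer. The behavioral model
is fitted on no-stimulation trials only, its value estimates are then
evaluated on all trials, and choices are refit on three regressors:
(V2 − V1), Stim1, Stim2. The stimulated offer's stim attribute is coded −1
(a value-subtraction indicator: the difference design then carries +1 on
stim-1 trials for the Stim1 term and −1 on stim-2 trials for the Stim2
term), so a true subtraction of s is recovered as +s on *both* weights and a
positive weight always reads "reduced log odds of choosing the stimulated
offer".

## Neural model

Windowed firing rates (offer window 125–500 ms after offer onset; cue and
reveal windows 150–750 ms after their events) are z-scored against the
session-wide vector of rates in non-overlapping 500-ms bins; constant-rate
neurons are excluded. Offer 1 and offer 2 responses are fitted separately by
OLS with intercept on the same attribute vocabulary, and by a one-regressor
"value model" whose attribute is the behaviorally estimated subjective value
of that offer.

**Shuffle-corrected R².** R²(data) minus the mean R² over fits with the
attribute rows permuted against the responses (default 100 permutations),
removing the chance-level variance a larger model absorbs. Internally each
permutation is evaluated by projecting the permuted response onto a QR basis
of the fixed design — algebraically identical to refitting, at a fraction of
the cost.

**Value coding index** = clamp₀¹( R²_cor(value model) / R²_cor(attribute
model) ), computed only for neurons with strong attribute effects: some
attribute significant at p < 0.05 in either offer fit *and* attribute-model
R²_cor ≥ 0.1. Below the gate the index is undefined, never zero. The two
offers' R²_cor values are averaged before the ratio (the analysis fits
offers separately but reports one index per neuron; averaging is the
symmetric combination). The clamp handles small shuffle fluctuations that
push the ratio just outside [0, 1]. The neuron's value sign is the sign of
the summed per-offer value-model weights. Because the neuron's "Value"
regressor is an *estimate* from behavior, a noiseless value-coding neuron
scores exactly 1 only when the regressor is the same value signal the neuron
encodes; with weights re-estimated from a finite session it scores just
below 1.

**Cross-validated peristimulus effects.** Population timecourses of
Info×Uncertainty (uncertain = SD above the session's median offer SD),
Info×UncertaintyType (50/50 vs 25/50/25), or the pooled Info×Time effect are
sign-normalized and selection-corrected *across offers*: whether a neuron's
offer-k trace enters, and with what sign, is decided solely from its
offer-(3−k) main-window fit. Under the null of no true effect the selected,
sign-normalized traces average to zero — verified by simulation in the test
suite. Traces are expected as sliding-window rate matrices (200-ms windows
stepped 25 ms in the tests; the kernel is a parameter, not a commitment).

**Functional indexes.**

* *Choice-predictive index*: Spearman rank correlation between
  Δ_behavioral = choice − p̂(choice) and Δ_neural = NVS − predicted NVS,
  where the normalized value signal NVS is the z-scored rate sign-flipped by
  the neuron's value-coding sign and predicted by the attribute model on the
  same trials. Positive values mean neural fluctuations toward "this offer
  is valuable" precede choosing it, whatever the neuron's raw coding sign.
* *RPE index*: RPE = delivered reward − chosen offer's E[r]; trials are
  classed Info/Noinfo × positive/negative RPE (|RPE| > 0.1 ml excluded
  otherwise; the threshold is unit-bound and configurable for coin data).
  RPE_cue = ROC(InfoPos, InfoNeg) − ROC(NoinfoPos, NoinfoNeg) on post-cue
  rates; RPE_rev is the mirror image on post-reveal rates (information
  arrives at the cue only on informative trials and at the reveal only on
  non-informative ones). The index is their mean; significance by
  permutation (400 swaps of rates between Info and Noinfo within each RPE
  sign, add-one p estimator (k+1)/(n+1)), combined across windows by
  Fisher's method (χ², 4 df). ROC areas use half-credit ties, making
  identical samples score exactly 0.5 and roc(x,y) + roc(y,x) = 1.
* *Combined coding*: a neuron is combined-coding if value index > 0.6,
  choice-predictive p < 0.05, RPE p < 0.05, and the three signs agree, with
  all signs expressed on raw rates (value sign = sign of the value weight;
  choice sign = value sign × sign of the NVS-based index; RPE sign = sign of
  the RPE index). Above-chance overlap is tested by permutation (default
  200,000; each property's flag-and-sign pairs shuffled independently across
  neurons), and the same scheme tests between-population differences.

## Synthetic-data generator

The generator is first-class, tested code: it emulates the offer statistics
above, logistic choosers with stated weights, and neurons under four coding
hypotheses — *single attribute* (unit weight on one attribute), *random
mixture* (behavioral weights shuffled and sign-flipped), *partial
integration* (a random half of attributes value-consistent, the rest
mixture), *full integration* (the behavioral weights themselves). A neuron's
offer response is baseline + sign·gain·(w·x) + noise; RPE responses carry
sign·rpe_gain·RPE in the window where information arrives. Choice coupling
injects a shared trial-level value noise into both the chooser and the
neuron's offer-epoch residual with correlation c (per offer if desired),
implementing the premise that behavioral and neural residuals share a common
value-noise source; without it the choice-predictive index has nothing to
recover (default 0). The outcome of the unchosen offer is never drawn.
Stimulation subtracts a configured value from the stimulated offer before
the logistic draw. Ground truth (weights, schemes, noise, seed) is persisted
with every dataset, and every generator is bit-reproducible given a seed.

Default choosers (see `infoval/studies.py` and `pipeline.DEFAULT_BETAS`) are
chosen once per task version: humans weight E[r] ≈ 0.8 log-odds per coin,
are mildly risk averse, and value information at roughly a coin, more for
uncertain lotteries; monkeys weight E[r] ≈ 8–10 log-odds per ml, are risk
*seeking*, and their information value flows predominantly through the
Info×Unc[r] term, with temporal discounting and information-timing
preferences (positive Info×t_advance terms) in the clock task. The
uncertainty-form study fixes the dissociating design: both uncertain types
at matched ranges (deviations 0.08 and 0.12 ml), offer-2 E[r] within 0.08 ml
of offer 1's, 5,000 trials per session.

What the generator does **not** emulate: spike trains (window rates
suffice), reaction times, gaze, lapses, session-to-session drift, learning
(including the human color-reversal), or correlated noise across neurons
beyond the shared value-noise channel. Passing recovery tests therefore
demonstrates the estimators are consistent and calibrated under the model's
own assumptions — not that real recordings satisfy those assumptions.

## Numerical choices

* Logistic fits use statsmodels' Logit for reported results; shuffle and
  cross-validation inner loops use an internal Newton/IRLS solver (ridge
  1e-10, step cap, separation flagged) for speed. OLS uses statsmodels;
  permutation R² uses the QR identity above.
* Timing grids are validated on an integer decisecond lattice (tolerance
  1e-9) to avoid binary-float artifacts; reward grids are built in integer
  ticks of R_step.
* Permutation p-values use the add-one estimator, never exactly zero.
* Degenerate inputs fail loudly and specifically: rank-deficient designs
  name the collinear attributes; constant neurons, empty RPE cells, and
  constant residuals return undefined (skipped) results with logged reasons
  rather than zeros.
* Problem sizes in the test battery (e.g. 100 replicate 5,000-trial sessions
  for the uncertainty-form comparison, 200-neuron populations, 10,000
  permutations for overlap calibration with 200,000 available) are the
  package's chosen demonstration scales; all counts are parameters.

## Known limitations

* The value coding index inherits estimation noise from the behavioral fit;
  on short sessions this biases indexes of perfectly integrated neurons
  slightly below 1.
* The psychometric WTP assumes a common logistic in the E[r] difference;
  when information value varies strongly across trials the indifference
  point estimates the *average* value of information, and curvature effects
  enter at second order.
* The overlap permutation test conditions on the observed flag counts; for
  populations with very few flagged neurons its p-value is heavily discrete
  (a warning fires below 10 neurons).
* Offer position is carried as metadata only; no side-bias attribute is
  modeled.
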