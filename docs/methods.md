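# Methods

## Gait model and event definitions

A gait cycle of one leg runs heel-strike → toe-off → next heel-strike.
Stance is the heel-strike-to-toe-off interval (foot in contact with the
ground), swing the remainder, so stance + swing = cycle holds exactly by
construction in `GaitCycle`. Stride time is the interval between
successive ipsilateral heel-strikes; step time of leg L is the interval
from a contralateral heel-strike to the next leg-L heel-strike (the
attribution of a step to the leg that *ends* it is a convention — the
verbal definition "between successive contralateral heel-strikes" leaves
it open — and is applied consistently). Single-support time of leg L is
the contralateral swing time; %SST divides it by leg L's cycle time.

**Cadence.** Cadence is stored in steps/min throughout and converted to
steps/s only inside the gait stability ratio (GSR = cadence[steps/s] /
speed). It is computed as `(n_HS − 1) · 60 / (t_last_HS − t_first_HS)`
over both legs' heel-strikes: the first heel-strike starts the walk and
every later one is a step. A naive `count / trial_duration` miscounts by
one fencepost step (126 instead of 120 steps/min for 1 s cycles over a
10 s pass) and depends on where the recording window is cut; the
span-based rate is exact for periodic gait and stable under end-trimming.

**Per-trial values** are means over retained cycles. The first and last
complete cycle of each leg's pass are trimmed by default
(`trim_cycles=1`) to reduce acceleration/deceleration bias near the
walkway ends; trimming is a config knob because walkway protocols differ
in whether the timed region includes the ramp-up.

**Symmetry index.** SI is computed on left/right %stance exactly as
`(X_L − X_R)·100 / (0.5(X_L + X_R))`; its sign therefore encodes
left-vs-right, which is arbitrary with respect to the lesion. An
affected-minus-unaffected variant (`symmetry_index_affected`, positive =
affected leg spends the larger cycle fraction in stance) is reported
alongside; the left/right form is the one carried in the canonical
17-parameter list.

**The 17-parameter list.** Normalized step length, walk ratio, stride
time, step time, %stance, %swing and %SST per side (14), plus GSR, SI and
cadence (3). Walking speed is measured (distance/duration) and feeds the
spatial indices but is not itself a member.

## Event detection from FSR traces

Contact detection thresholds each channel at 20% of its dynamic range
above its minimum (`threshold_fraction=0.2`), bridges sub-threshold gaps
shorter than the 50 ms debounce window and discards shorter runs. Both
constants are exposed: FSR insoles differ in baseline drift and crosstalk,
and the right debounce scales with cadence. Heel-strike is the earliest
onset among the two heel channels of a footfall, toe-off the latest offset
among all three channels — the physically conservative bounds of foot
contact, robust to medial/lateral heel asymmetry. Footfalls missing heel
or toe contact are excluded with a warning rather than guessed.

## Synthetic cohort

The generator emulates the study geometry it is meant to exercise: a 10 m
straight walkway walked at self-selected speed, two legs as phase-shifted
periodic event trains (default offset 0.5 cycle), side-specific stance
fractions (hemiparetic gait holds the paretic side longer in stance), and
independent truncated-Gaussian jitter (±3 SD) on every event time.
Defaults: 1.0 s cycles, 60% stance, 1.0 m/s; the end-to-end demo uses
1.1 s cycles, 65/60% stance and 0.8 m/s — typical of chronic hemiparetic
walkers. FSR synthesis loads the heel channels over the first 60% of
stance and the toe channel from 30% of stance to toe-off, so event
recovery is exact to one sample on noise-free traces.

What the generator does **not** model: spatial foot placement (step
length is reconstructed from step time × speed, as with the real
instrument), kinematics and kinetics, within-pass speed drift, sensor
drift/saturation, or gait variability structure beyond white per-event
jitter. Passing tests therefore validate the computational chain, not the
instrument or the clinical effect sizes.

**E-field profiles.** The two montage profiles are constants chosen
inside published qualitative ranges: the dentate-targeting montage
reaches the dentate nuclei at 0.25 V/m and all lobules at 0.12 V/m; the
leg-area montage reaches lobules VIIb–IX and the dentate at 0.10 V/m and
other lobules at 0.05 V/m. Only inequalities are published (> 0.2, > 0.1,
> 0.08 V/m), so the constants are overridable. The 30 predictor labels
are 20 contra-/ipsi-lesional hemispheric lobules, 8 vermis subdivisions
and 2 dentate nuclei. Between-subject variability is not published at
all; the default SD is 0.05 V/m per lobule (a substantial, realistic
inter-individual spread for tDCS fields), truncated at zero.

**Planted association.** `random_planted_association` draws a sparse
coefficient matrix (default 4 active lobules, i.i.d. N(0, 100) rows in
%-change per V/m) acting on *centered* fields, so zero-noise planted data
are exactly recoverable by a centered linear model. The recovery study
uses 10 subjects × 2 montages = 20 observations, 30 lobules, 17
responses, and response noise at 10% of the per-column signal SD.

**End-to-end demo effects.** Post-stimulation trials shift the generator:
the dentate montage shortens the cycle and trims unaffected-side stance,
the leg montage does the reverse (directions follow the published
contrast). Magnitudes (±0.007 s cycle, ±0.004 stance fraction) put the
between-montage separation near one SD of a change score's session noise,
so montage differences straddle the detection threshold as they do in
real small crossover studies, instead of flagging every parameter.

## Change scores and the rank-sum test

Percent normalized change `(POST − PRE)·100/(POST + PRE)` is
antisymmetric, scale-invariant and bounded in (−100, 100) for positive
raw values (all 17 indices are positive); cells with POST + PRE = 0 are
flagged missing. Montages are compared per parameter with a two-sided
Wilcoxon rank-sum test. For combined n ≤ 20 without ties the p-value is
exact: the null distribution of the rank sum is built by dynamic
programming over ranks 1..N, and the two-sided p is twice the smaller
tail, capped at 1 — at 10 per montage the exact and asymptotic p can
differ in the third decimal, which matters when results sit near 0.05.
Ties or larger samples use the normal approximation with tie correction
and a 0.5 continuity correction. No multiplicity correction is applied
across the 17 parameters by default (each parameter is reported as its
own test); Benjamini–Hochberg is available behind `correction="bh"`.

## PLS regression

Regression-mode two-block PLS (PLS2) on centered, unscaled blocks —
centering only, because predictors share units (V/m) and responses share
units (% change); column standardization would reweight lobules by their
between-subject variance, which is part of the signal here. Per
component: the X-weight is the first left singular vector of the residual
cross-covariance X′Y (computed by direct SVD rather than NIPALS power
iteration — deterministic and exact to machine precision); the score is
t = Xw; X- and Y-loadings are regressions of each block on t; both blocks
are deflated by their t-projection. Coefficients are
B = W(P′W)⁻¹Q′. Because residuals stay orthogonal to all scores, the
cumulative % response variance explained equals 100·R² at full rank, an
identity the tests check numerically.

Numerical choices: weight signs fixed so each component's
largest-magnitude weight element is positive (SVD signs are otherwise
arbitrary and would make loadings irreproducible); extraction stops with
a warning when the residual cross-covariance's top singular value falls
below 1e-12 of its initial value or a score's squared norm underflows;
`n_components` defaults to 10 and is capped at min(rows − 1, predictors).
With more observations than predictors and full components, PLS
reproduces ordinary least squares (tested against the normal-equations
solution); with fewer observations than predictors (the 20 × 30 study
shape) the full-rank fit interpolates, so R² is only meaningful at a
truncated component count — the 10-component default.

Predictor importance for recovery checks is the L2 norm of each
predictor's coefficient-matrix row; "recovered" means all planted active
lobules rank in the top quartile of that importance. No cross-validated
inference (jackknife/bootstrap) is performed: the model is used as a
fixed-effect correlation-style description of one data set, and a
bootstrap would be the natural extension.

## Clinical MCID flags

Improvement flags use the standard minimal clinically important
differences: ten-meter walk speed +0.10 m/s, timed up-and-go −8 s, Berg
Balance Scale +12.5 points (scale 0–56). These are threshold flags, not
hypothesis tests.

## Problem sizes and determinism

Default problem sizes — 10-subject cohorts, ~9–12 cycles per 10 m pass,
500 Hz FSR synthesis, 100-replicate recovery studies, 500-replicate power
checks and a 2000-replicate type-I-error check — keep the whole suite in
a few seconds while leaving Monte-Carlo margins of several binomial SEs.
Every stochastic step takes an explicit integer seed and is bit-for-bit
reproducible; the pipeline records the seed and a config hash in every
report.

## Known limitations

* Step length is time-derived (step time × mean speed), as with the real
  shoe; no spatial measurement exists, so walk ratio and normalized step
  length inherit any speed-measurement bias.
* The exact rank-sum branch requires untied data; change scores are
  continuous so ties are rare, but heavily rounded inputs will silently
  shift to the approximate branch (the method used is always recorded).
* PLS loadings are descriptive; no salience inference is provided.
* The synthetic E-field profiles are qualitative stand-ins constrained
  only by published inequalities, not subject-specific field models.
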