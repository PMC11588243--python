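# Methods

This note documents the models, conventions and numerical choices behind
`ethostate`, and what its synthetic studies do and do not demonstrate.

## Sensor model and feature extraction

Input is a 10 Hz tri-axial acceleration stream (±2 g, 8-bit) plus a 1 Hz
analog immersion voltage, per deployment. Recordings are segmented into
gap-free *bursts* wherever consecutive samples are more than `max_gap`
(default 2 s) apart, because the HMM likelihood assumes one observation
per 30-s step; segments shorter than one window are logged and dropped.
The 1 Hz channel is aligned to whole seconds since burst start and
forward-filled across occasionally missing seconds — both sensors share
the device clock, and how the original hardware time-registers the two
streams is not published, so this alignment is a package choice.

Static (gravity) acceleration is a centred uniform moving average per
axis. The window is 91 s — the dominant stroke period of the study
species, taken as given — realized as 911 samples at 10 Hz (odd length
for symmetry); edges use the shrinking-window mean. "Uniform" is a
choice: the weighting of the original smoother is not published, and the
running-mean convention is standard in the dynamic-body-acceleration
literature. Dynamic acceleration is defined as `raw − static`, which
fixes the sign convention and makes the reconstruction identity
(`static + dynamic == raw`, per sample, to machine precision) the
invariant the tests enforce; ODBA is unaffected by the sign either way.

Pitch is `atan2(Sx, hypot(Sy, Sz))` in degrees, the diving-bird
convention; a zero static vector (free-fall artefact) yields pitch 0 with
a logged warning.

Window features (non-overlapping 30 s, aligned to burst start, trailing
partial windows dropped):

* `mean_odba_log10 = log10(max(mean ODBA, 1e-12))`
* `var_pitch_log10 = log10(max(var pitch, 1e-12))` — *sample* variance
  (n−1 denominator, the default of the statistical environments this
  workflow usually runs in; the alternative n-denominator changes the
  300-sample window variance by 0.3%, well below the state separation)
* `immersed` — strict majority of the window's seconds at or below the
  500 V threshold. The threshold comparator (≤ by default) and the
  majority rule are package choices; mean-voltage and any-sample rules
  would differ only for windows straddling a water entry/exit.
* a summary block (max / mean / IQR / variance of ODBA and pitch) is
  retained for export; only the three features above feed the model.

The 10⁻¹² floor keeps log features finite for motionless synthetic
windows whose quantized signal is exactly constant.

## The constrained HMM

Five states in fixed order — ActiveWater, ActiveLand, InactiveWater,
InactiveLand, Nesting — anchored by their starting values; no post-hoc
relabelling. Emissions are conditionally independent given the state:
Normal for each continuous feature, Bernoulli for immersion with
probability clamped to [10⁻¹², 1 − 10⁻¹²] (estimable by default; a switch
fixes them at their starting values).

Seven ordered transitions are structurally impossible within one 30-s
step: InactiveWater→{ActiveLand, InactiveLand, Nesting},
ActiveWater→{InactiveLand, Nesting}, Nesting→{ActiveWater,
InactiveWater}. A resting turtle in water can only stay or resume
swimming; hauling out, basking or nesting requires an active transit.
These are hard exclusions — no parameter exists for them — so decoded
paths can never contain them and the transition matrix has exact zeros.
Whether Nesting→InactiveWater was forbidden in the original analysis is
ambiguous ("transitions did not occur between" the two states reads as
bidirectional); the default set above is configurable.

Gravidity enters as state-space masking, not as a soft covariate: a
non-gravid individual's tracks are evaluated on the 4-state sub-chain
with the Nesting row/column removed and rows renormalised over the
retained, allowed cells. Because the rows are multinomial-logit with the
diagonal as reference, renormalisation is exactly the softmax over the
remaining cells, so a masked 5-state fit on non-gravid data is the same
function as an explicit 4-state model — the acceptance suite verifies the
fitted log-likelihoods agree to 10⁻⁶. Each individual has a free initial
simplex shared across its bursts (a per-individual intercept in the
initial distribution); a flag falls back to the stationary distribution
of the (masked) chain.

### Estimation

Direct maximisation of the exact scaled-forward log-likelihood with
L-BFGS-B on working parameters: means free, `log sd`, logit immersion,
multinomial-logit transition rows (forbidden cells absent), per-individual
initial logits (first allowed state as reference). The gradient is
analytic via one forward–backward pass per track (Fisher's identity: the
score equals the posterior-weighted complete-data score); it is validated
against finite differences in the unit tests. Working parameters are
box-bounded (logits ±30, log-SDs in [−10, 5]) so coordinates whose MLE is
at infinity — saturated immersion probabilities, never-observed
transition cells, corner initial distributions — go inactive at a bound
instead of drifting. Defaults: relative `ftol` 10⁻⁸, at most 1000
iterations, one start from the default starting values (multi-start via
`n_restarts` adds seeded jitter). Non-convergence is flagged on the
results object, never silently dropped, and the reported log-likelihood
is never below the starting value.

Two numerical refinements matter in practice. First, the per-step scaling
uses a row-max shift before exponentiation, and a window where every
state underflows returns −∞ rather than dividing by zero (line searches
do propose such points). Second, after L-BFGS-B terminates, a
deterministic *boundary polish* snaps each logit coordinate to its bound
whenever that strictly improves the likelihood and re-optimises (at most
two cycles). Quasi-Newton steps drain the exponential tails of
infinite-MLE coordinates extremely slowly; polishing removes the
path-dependent ~10⁻⁴ log-likelihood residue they leave, which is what
makes the masked/explicit equivalence reproducible at 10⁻⁶. For that
check the two fits are run at `tol=1e-12`, since the default 10⁻⁸
relative tolerance only resolves the objective to ~10⁻⁵ at these sample
sizes.

Viterbi decoding runs on the masked chain per track; ties break toward
the lower state index, so decoding is deterministic.

## Validation and budgets

The confusion report stores raw counts (manually-classified rows ×
model-inferred columns) because overall accuracy cannot be recovered from
percentages alone; the displayed percentages normalise within each
inferred column, the convention of the published tables this layout
follows, with a per-manual-row normalisation also available. Annotation
sampling is 50 windows per individual, uniform without replacement,
seeded. Interval annotations (video logs) map to windows by dominant
overlap duration; ties exclude the window with a log entry.

Bouts are maximal same-state runs within a burst (never across gaps), so
per individual the bout durations sum to 30 s × decoded windows exactly.
Daily budgets divide by the windows *observed* that local calendar day
(partial days kept; whether the original analysis assumed full 24-h
coverage is unstated, and observed-window denominators keep rows on the
simplex). Local days come from a configurable UTC offset, default −4 h
(Eastern daylight time, the study region's summer offset). The sex
comparison pools gravid and non-gravid females, tests each state's bout
durations with Shapiro-Wilk per group, then Wilcoxon rank-sum if either
group rejects normality at α = 0.05, else classical equal-variance
Student's *t* (Welch behind a flag). A state absent in one sex is
reported as skipped. Daily proportions are exported tidy
(individual, sex, date, state, proportion) for external mixed-effects
beta-regression; that model is deliberately not reimplemented here.

## The synthetic studies

Two generation levels share one state-sequence simulator (Markov chain on
30-s steps honouring the forbidden set; non-gravid chains run on the
masked sub-chain; an optional explicit-duration mode draws lognormal
dwells, deliberately misspecified relative to the plain HMM).

**True transition matrix.** Diagonals are set from field-scale mean bout
durations (water states ≈ 16 min, inactive-on-land ≈ 25 min, nesting ≈
17 min, active-on-land ≈ 3 min) and the off-diagonal mass is arranged so
the stationary distribution matches field-scale activity budgets:
roughly 46% active in water, 40% inactive in water, 3% active on land,
7% inactive on land, and ~5% nesting for gravid females.

**Feature level** (used for parameter recovery): windows drawn directly
from the emission model. True means sit at the default starting means;
true SDs keep the same relative pattern scaled by 0.3 — the starting SDs
are deliberately broad search windows, not state widths, and the
recovery study is meant to be well-separated. Window-level immersion is
near-deterministic (1 ∓ 10⁻⁴): a majority vote over 30 wet/dry seconds
essentially never flips. The default study is 8 individuals (5 F / 3 M,
3 gravid) × 2,000 windows (~16.7 h each). At these sizes the fitted
Normal means land within 3 σₖ/√nₖ of truth and Viterbi accuracy exceeds
99%.

**Signal level** (used end to end): each 30-s block emits 300
accelerometer samples — a gravity vector whose pitch ramps linearly
between two draws around the state's posture (drift SD 9° for active
states, 18° for digging, 0.05° at rest), plus state-specific oscillation
(sinusoidal gait for swimming/walking; for nesting a 0.15 Hz sawtooth in
8-s bursts separated by 4-s pauses, echoing rhythmic hind-leg digging),
plus white noise — clipped to ±2 g and quantized to 8 bits — and 30
voltage samples from well-separated wet (200 ± 30 V) and dry (800 ± 30 V)
bands. The drift and amplitude scales were calibrated once so each
state's realized feature centroid lands near the default starting
geometry; without that, starting-value label anchoring fails on
raw-pipeline features. The default signal study is reduced-scale (140–800
windows per individual, one mid-deployment battery dropout) to keep
end-to-end runs fast.

**What passing does and does not show.** The generator matches the
assumptions of the inference model (conditionally independent Normal /
Bernoulli emissions, geometric dwells unless the explicit-duration mode
is used), so recovery results demonstrate correctness of the
implementation, not robustness to real-sensor pathology: no drifting
attachment angles, no temperature effects, no brackish intermediate
immersion voltages, no behaviour intergrades. The separation-dial test
(shrinking the active/inactive contrast degrades accuracy monotonically)
probes sensitivity, not realism. Real-data accuracy must be established
with annotated field windows, as the validation module supports.

## Determinism and reproducibility

One master seed fixes a synthetic study byte-for-byte (per-individual
streams are spawned from a `SeedSequence`). Fits are deterministic given
data, starting values and seed; annotation sampling is seeded.
`scripts/acceptance.py --seed S --out f.json` regenerates every reported
quantity from scratch in about a minute on one CPU, at the study sizes
above.
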