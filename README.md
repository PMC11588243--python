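# ethostate

Unsupervised behavioural-state classification for semi-aquatic animals
carrying multi-sensor biologgers (tri-axial accelerometer + analog
immersion channel), built around a constrained hidden Markov model.

Freshwater turtles and similar cryptic, semi-aquatic species are nearly
impossible to observe continuously: they submerge for hours, bask out of
sight, and nest far from their wetlands. Animal-borne loggers record body
acceleration at 10 Hz and wet/dry state at 1 Hz around the clock; the
problem is turning tens of millions of raw samples into an interpretable
ethogram. `ethostate` implements that pipeline end to end for five broad
states — **active in water**, **active on land**, **inactive in water**,
**inactive on land**, and **nesting** (gravid females only) — for movement
ecologists working with AxyTrek-style CSV exports.

## The model

Raw acceleration is split into a gravity ("static") component, estimated by
a centred 91-s running mean per axis, and a body-motion ("dynamic")
residual:

```
S_i = running_mean_91s(raw_i),   D_i = raw_i − S_i        (i ∈ {x, y, z})
ODBA = |D_x| + |D_y| + |D_z|
pitch = atan2(S_x, √(S_y² + S_z²)) · 180/π
```

Per non-overlapping 30-s window the pipeline computes three features:
log₁₀ mean ODBA, log₁₀ variance-in-pitch, and a binary immersion flag
(analog voltage ≤ 500 V = in water, majority vote over the window's
seconds). These feed a 5-state HMM with state-dependent Normal emissions
for the two continuous features and a Bernoulli emission for immersion
(probabilities clamped to [10⁻¹², 1 − 10⁻¹²]). The transition matrix
carries **structural zeros** for ecologically impossible 30-s switches
(e.g. a turtle resting on the bottom cannot appear basking in the next
window), and the state space is **masked by gravidity**: gravid females
are fitted with the full 5-state chain, everyone else with the 4-state
sub-chain, sharing emission and transition parameters. Each individual
gets its own initial state distribution. Fitting maximises the exact
forward likelihood with L-BFGS-B on transformed working parameters using
the analytic score (forward–backward); states are decoded with the
Viterbi algorithm, then summarised into bouts, daily activity budgets and
a male/female comparison (Shapiro-Wilk, then Wilcoxon rank-sum or
Student's *t*).

## Worked example

No field data ships with the package; the synthetic module generates
deployments with known ground truth (8 individuals — 5 females of which 3
gravid, 3 males — 2,000 windows each by default):

```python
import ethostate as es

windows, truth = es.simulate_feature_study(seed=11)
res = es.BehaviourHMM.from_dataframe(windows).fit(seed=0, max_iter=2500)
print(res.summary())
```

```
Behavioural-state HMM results
========================================================================
windows: 16000    tracks: 8    individuals: 8
log-likelihood: -18271.165   (at start: -54410.841)
converged: True   iterations: 1139   [CONVERGENCE: RELATIVE REDUCTION OF F <= FACTR*EPSMCH]
------------------------------------------------------------------------
state-dependent emissions (log10 feature scale)
               varpitch_mean  varpitch_sd  odba_mean    odba_sd  immersion_prob
ActiveWater          -0.5017       0.8914    -0.9952     0.2399          1.0000
ActiveLand           -0.4998       0.6126    -0.4919     0.3023          0.0000
InactiveWater        -6.0067       0.8963    -2.0001     0.1479          1.0000
InactiveLand         -6.0105       0.5911    -2.0010     0.1518          0.0000
Nesting               0.1960       0.2910    -0.5022     0.0576          0.0000
```

The fitted emission table recovers the generator's truth (means −0.5/−1
for swimming, −6/−2 for resting, immersion saturated at the wet/dry
extremes). Decoding and downstream summaries:

```python
decoded = res.decode()                      # Viterbi state per window
merged = truth.merge(decoded[["burst_id", "window_index", "state"]],
                     on=["burst_id", "window_index"])
print(f"accuracy: {100 * (merged.true_state == merged.state).mean():.1f}%")

bouts = es.delineate_bouts(decoded)
budgets = es.daily_budget(decoded)
```

```
decoding accuracy vs ground truth: 100.0%
bouts: 562; mean ActiveWater bout: 974 s
mean deployment budget: {'ActiveWater': 0.501, 'ActiveLand': 0.03,
 'InactiveWater': 0.371, 'InactiveLand': 0.068, 'Nesting': 0.029}
```

A `100.0%` here means every one of the 16,000 windows was decoded to its
true state; bouts are maximal same-state runs (974 s ≈ 32 windows), and
the budget is the fraction of observed windows per state — turtles in
this configuration spend about half their time active in water, matching
the generator's stationary distribution.

The same pipeline runs from the shell on CSV exports:

```bash
ethostate simulate --out study --seed 3          # synthetic deployments
ethostate features --input study/SYN_001.csv --out feats.csv
ethostate fit      --features feats.csv --out model.json
ethostate decode   --model model.json --features feats.csv --out decoded.csv
ethostate budget   --decoded decoded.csv --out-bouts bouts.csv --out-budgets budgets.csv
```

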