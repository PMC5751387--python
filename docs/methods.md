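# Methods

## The adaptive re-referencing model

The filter treats each output sample of a target electrode as the raw
potential minus a weighted estimate of the interference common to its
neighborhood.  All adaptive quantities derive from two per-sample statistics:

* the **concordance correlation coefficient** (CCC) between the target's and
  each neighbor's trailing window of `Wf` samples,
  `ρc = 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²)`, with biased (1/n) moments.  CCC
  multiplies Pearson correlation (precision) by a factor penalizing mean and
  variance disagreement (accuracy), so `|ρc| ≤ |r|` always.  The window
  ending at sample `k` covers samples `[k−n+1, k]`, 0-based inclusive.
* the **amplitude spread** `Vstd = sqrt(Σ_j (V_j − V_i)² / (N−1))` over the
  candidate set at the current sample.

**Stage 1 — neighbor selection.**  Running extremes `m = min Vstd`,
`M = max Vstd` are tracked per target (session-running by default; the
maximum is capped at `cap_ratio·m` so one huge artifact cannot make the
threshold sticky, and `m` is floored at 1e-6 µV).  The adaptive threshold

```
TH(v) = 2m + (M*−m)(M*−v)/(M*−2m),    M* = min(M, cap_ratio·m)
```

is +∞ (accept all) while `M* ≤ 2m`.  A sample with `Vstd < TH` keeps every
neighbor; otherwise only neighbors with `ρc` above `ρc_M − D (− 0.05)` are
kept, where `ρc_M` is the neighbor-median CCC and `D` the median *absolute*
deviation (the signed median is ~0 for any near-symmetric set, which would
disable one branch).  If no neighbor passes, the single most concordant one
is kept so the output stays referenced and no division by zero occurs.

**Stage 2 — weights and amplitude correction.**  Selected neighbors are
weighted by normalized virtual distances `VD = exp(−w1·ρc)` — computed as a
shifted softmax of `−w1·ρc`, since `VD` reaches `e^{w1}` for anti-correlated
neighbors.  Low similarity ⇒ high weight: concordant neighbors carry the
target's own signal and must not dominate the subtraction.  When the spread
of the *selected* set (recomputed after selection, with its threshold
re-evaluated at that updated value) is still anomalous, each member is
re-centered by the median amplitude of its correlated subgroup: electrodes
with at least one partner at Pearson `r ≥ 0.85` over the current window use
the median over that subgroup (`Se`); electrodes with no such partner use the
median of the whole selected set.  This dispatch is the only reading in
which the two printed branches of the correction differ; a singleton set
receives no correction (subtracting its own median would null the signal).
Corrections act on the output only — they are not fed back into the CCC.
The final output is `(V_i − AC_i) − Σ_j g_ij (V_j − AC_j)`.

During warm-up (fewer than `Wf` samples) the filter applies classic
inverse-distance weights (configurable to passthrough), so early output is
still referenced.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `w1` | 5 | virtual-distance steepness (fitted operating point) |
| `window_ms` (`Wf`) | 100 ms | similarity window; also the settling time after artifacts |
| `cap_ratio` | 10 | cap of running `Vstd` max relative to min |
| `r_cut` | 0.85 | correlation defining the amplitude-correction subgroup |
| `ccc_tol` | 0.05 | slack subtracted from the CCC threshold when neighbor CCCs agree |

A grid-search harness (`spectral.grid_search_filter_params`) scores
`(Wf, cap_ratio, w1)` combinations by mean(SNR − |A|) at the true stimulus
frequency of synthetic records, mirroring how the operating point was fitted.

### Montages

Two montages ship as YAML: a 20-electrode motor-cortex layout (targets Cz,
CP1, CP2; WAR surround pinned to FC3, FC1, C3, C4, Pz; the six LAR
locations FCz, C1, C2, CPz, CP3, CP4 split into small/large rings by
geometric proximity to each target, the published source not stating the
assignment) and a 13-electrode occipito-parietal layout (targets O1, O2,
Oz).  Coordinates are the standard spherical-head projection of the 10-20
system in centimetres; only relative distances matter, and a
`unit_distances` flag removes geometry entirely.  WAR neighbor sets default
to "all other electrodes" and may be pinned per target in the montage file.

## Evaluation metrics

SSVEP SNR compares the magnitude spectrum at the stimulus frequency with the
ten flanking bins at ±0.2k Hz (k=1..5); spectra are rectangular-window FFTs
zero-padded so the grid divides 0.2 Hz.  The attenuation index carries the
printed `sign(I−O)` factor, which maps a ×2 gain and a ×2 loss to the same
−6.02 dB; `signed=False` yields the conventional signed gain.  Coherence is
the magnitude of Welch-averaged (50 % overlap) coherency — a single
unaveraged segment is degenerate (≡1) and is rejected.

The classifier model-selection loss weighs Cohen's kappa, the worst per-class
false-positive rate, accuracy, and the worst per-class PNM (0.3/0.3/0.15/
0.25).  `FPR_max` and `PNM_min` are maxima/minima over classes.  The linear
SVM uses balanced class weights: the gait protocol yields ~⅓ planning vs ~⅔
rest windows, and balancing makes the chance level of balanced accuracy
exactly 0.5, which is what the null calibration asserts.  The box constraint
is tuned on a 2-fold inner CV over {0.01, 0.05, 0.1, 1, 5, 10} by mean Idx
(ties to the smallest C); outer validation groups whole sessions (k2 = 3) so
train and test never share a session.

Recognition timing declares a planning command when the planning label
persists ≥ 88 ms (35 samples at 400 Hz); latency is the time that first
persistence completes, relative to movement onset (negative = anticipation);
the reported min/max continuous-recognition intervals are the median and
maximum qualifying run lengths.  When window predictions are produced at a
stride > 1 the pipeline re-expands them to the sample grid by repetition
before applying the rule.

## Feature bank and unsupervised selection

Twelve features per channel on 250 ms windows of the filtered (reference-
free) signal.  The "reference-free amplitude" feature is the window mean
(option: last sample).  The Sevcik–Higuchi fractal dimension is the
arithmetic mean of the two estimates (the combination rule being
interpretive).  Band powers are FFT power masses over half-open bands,
zero-padded to 1 Hz spacing — the 0.1–4 Hz band is therefore
resolution-limited at 250 ms windows and effectively measures low-frequency
power rather than resolving 0.1 Hz.  Sevcik's estimator converges to 1 on
straight lines only slowly (≈1.046 at N = 1000; ≈1.066 at N = 100), a
property of the formula `D = 1 + ln L / ln(2(N−1))`, not of the
implementation.

Selection pools the representation entropy of seeded random subsets covering
10–80 % of the features, screens values not significantly below the maximum
(one-sided Z at p ≥ 0.05) and takes their medoid as threshold; it then
repeatedly removes one member of the minimal-MICI pair, letting the pair
members and all previously rejected features compete by the RE they give the
remaining set, until the working set's RE exceeds the threshold.  Exactly
linearly dependent pairs (MICI ≈ 0 relative to the mean feature variance)
are always eliminated regardless of the threshold: a zero-eigenvalue pair is
definitionally redundant, and the pooled-subset threshold cannot be relied
on to force the loop (for weakly redundant banks the full set's RE typically
exceeds every subset's).  On the bundled synthetic features the threshold
consequently rarely binds and selection acts chiefly on exact redundancies;
real EEG features with stronger cross-correlations engage the loop more.

## Synthetic data: what it emulates, and what not

Records are sums of (a) common-mode components — a line tone, pink noise, an
EOG-like train of 200–400 ms raised-cosine blinks low-passed below 5 Hz with
front-weighted gains, slow drift — identical in waveform across channels up
to per-channel gains; (b) localized components — SSVEP fundamentals plus
1/h-decaying harmonics with an occipitally peaked gain profile, or a
quadratic movement-related ramp (default −8 µV at onset) plus a 10 Hz mu
rhythm attenuated 40 % during planning; (c) independent Gaussian noise
(default 2 µV SSVEP / 6 µV gait); and (d) electrode-pop artifacts: sustained
deflections with sharp (2 %) edges and ±10 % wander, scaled by
gain × channel σ — a popped electrode, not zero-mean scatter.  Every
component draws from its own substream of the master seed, so adding one
never perturbs the others.  Gait epochs are all rendered at the common 2 s
duration and cropped per class, so slow-component statistics cannot leak
class identity and the zero-effect dataset is genuinely null.

Not emulated: volume-conduction head models, non-stationary rhythm dynamics,
inter-subject variability, muscle artifacts.  Passing tests therefore show
the algorithms behave as specified under controlled statistical structure,
not that they reach any particular performance on real recordings.

## Problem sizes and numerical choices

Desk-scale defaults keep the full pipeline to a few seconds per run: 24
planning + 36 rest epochs over 6 sessions at 400 Hz, feature windows at a
25-sample (62.5 ms) stride, 50 random subsets per cluster fraction in the
selection threshold.  The batch filter vectorizes the sliding CCC and the
spread statistic and falls back to per-sample evaluation only where
selection engages (a few percent of samples on stationary data); it equals
the streaming implementation to < 1e−9 µV (summation order).  Degenerate
cases are mapped to explicit conventions rather than NaN: equal constant
windows have CCC 1, unequal constants 0; a constant window has Pearson r 0
and Sevcik dimension 1; an empty selection keeps the best neighbor.

## Known limitations

* For one similarity window after a large single-electrode artifact ends,
  that electrode's CCC is still contaminated while its amplitude is normal;
  the virtual-distance law then gives it a dominant weight until the window
  clears.  With Wf = 100 ms this bounds artifact recovery at ~100 ms and is
  the main contributor to the residual deviation (~10–15 % of output RMS on
  a 6 s record) between a burst run and a burst-free run.
* When selection engages, the median−MAD CCC threshold drops the
  lower-similarity quartile of legitimate neighbors along with the artifact
  channel, slightly changing the common-reference estimate relative to
  quiet samples.
* Session-running `Vstd` extremes drift over long stationary records (the
  minimum keeps falling), which increases how often selection engages; the
  cap bounds but does not remove the effect.  A sliding-horizon history is
  the natural extension.
* EDF I/O is not included; records travel as CSV (time column + labeled
  channels).
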