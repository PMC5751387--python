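# adaptref

Adaptive similarity-based spatial re-referencing for multichannel EEG, with
the evaluation machinery of a complete brain–computer-interface (BCI)
pipeline: SSVEP spectral metrics, a movement-planning feature bank,
unsupervised feature selection, nested classifier tuning, and seeded
synthetic-EEG generators so everything is testable offline.

## The problem and the method

Classic spatial filters subtract from a target electrode *i* a weighted
average of its neighbors *j* to cancel interference that is common across the
scalp (power-line pickup, eye blinks, shared physiological rhythms).  The
Local and Weighted Average Reference filters (LAR/WAR) fix those weights from
inter-electrode distances:

```
V_i_out = V_i − Σ_j g_ij V_j ,   g_ij = (1/d_ij) / Σ_j (1/d_ij)
```

Because the weights ignore the data, a neighbor carrying an artifact — or
carrying the very signal one wants to keep — contributes regardless.  The
adaptive variants implemented here (Ad LAR / Ad WAR) make the weights
data-driven through the concordance correlation coefficient (CCC)

```
ρc = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)
```

computed between target and each neighbor on a sliding window Wf (100 ms),
and replace the physical distance by a *virtual distance*

```
VD_ij = exp(−w1 · ρc_ij),   w1 = 5 ,   g_ij = VD_ij / Σ_j VD_ij .
```

Neighbors highly concordant with the target (which would subtract away its
neural signal) get small weights; dissimilar neighbors dominate the
common-interference estimate.  Two per-sample guards precede the weighting: a
**neighbor-selection** stage drops electrodes whose CCC falls under an
adaptive threshold whenever the instantaneous amplitude spread `Vstd` across
the candidate set is anomalous, and an **amplitude-correction** stage
re-centers electrodes by the median of their correlated subgroup during
high-spread samples.

Around the filter, the package provides:

* `spectral` — narrowband SSVEP SNR, the attenuation index
  `A = 20·log10(O(f)/I(f))·sign(I(f)−O(f))`, magnitude coherence;
* `features` — 12 features per channel per 250 ms window (reference-free
  amplitude, MAV, waveform length, Higuchi and Sevcik–Higuchi fractal
  dimensions, 7 band powers from 0.1–4 up to 50–70 Hz);
* `feature_selection` — unsupervised pruning by Representation Entropy
  (eigenvalue entropy of the feature correlation matrix) and the Maximal
  Information Compression Index (smallest pair-covariance eigenvalue);
* `evaluation` — confusion metrics including the per-class PNM index, the
  composite model-selection loss
  `Idx = 1 − (0.3·κ + 0.3·(1−FPRmax) + 0.15·ACC + 0.25·PNMmin)`,
  nested-CV linear-SVM tuning, CCA-based SSVEP target recognition with six
  harmonics, and the 88 ms-persistence latency rule;
* `synthetic` — seeded generators of SSVEP-like records and of labeled
  gait-planning/rest epochs (movement-related cortical potential ramp plus
  mu-band desynchronization) with common-mode interference, per-channel
  noise, and single-electrode artifact pops;
* `pipeline` — reproducible end-to-end workflows
  (`run_ssvep_eval`, `run_gait_pipeline`).

## Worked example

`examples/filter_ssvep_record.py` builds a 6 s occipital record with a 12 Hz
flicker response plus shared line noise, blinks and pink noise, filters Oz
with both the classic and the adaptive filter, and prints:

```
stimulus 12.0 Hz on Oz;   raw SNR  17.17 dB
    war: SNR  21.07 dB | stimulus attenuation  -5.86 dB | 50 Hz line attenuation -30.62 dB
 ad_war: SNR  21.77 dB | stimulus attenuation  -4.44 dB | 50 Hz line attenuation -30.69 dB
```

Both filters suppress the shared 50 Hz tone by ~30 dB, but the adaptive
filter loses ~1.4 dB less of the stimulus component — the preservation
property that motivates the method.  `examples/gait_decoding_pipeline.py`
runs the full planning-vs-rest decoder on synthetic epochs:

```
1548 feature windows, 36 features
fold 0: C=0.01  ACC 0.878  balanced 0.859  kappa 0.721  Idx 0.256  features kept 36
fold 1: C=0.01  ACC 0.833  balanced 0.846  kappa 0.646  Idx 0.301  features kept 36
fold 2: C=0.01  ACC 0.874  balanced 0.857  kappa 0.714  Idx 0.258  features kept 36
mean balanced accuracy: 0.854
timing: 0 failed planning cycles; mean latency -977.5 ms before movement onset
```

Balanced accuracy is 0.5 on effect-free data (see the methods note), so 0.85
reflects the planted movement-related potential and mu-band suppression; the
negative latency means planning is recognized well before movement onset.
The other examples demonstrate streaming (on-line) filtering with artifact
diagnostics and the feature bank with RE/MICI selection.

A thin CLI mirrors the stages: `adaptref simulate | filter | features |
select-features | evaluate-ssvep | run`.

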