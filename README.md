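# threatphys

Psychophysiological quantification and statistical inference for human
threat-conditioning (fear-conditioning) experiments, from raw multichannel
recordings to trialwise response amplitudes, mixed-model contrasts, and a
cross-validated permutation test of a group × CS effect — together with a
forward simulator that makes every stage verifiable by parameter recovery.

## Who this is for

Researchers analyzing discriminative threat-conditioning protocols in which
two conditioned stimuli (CS⁺) are partially reinforced with an aversive
electrical stimulus (US) and one CS⁻ is never reinforced, and where
conditioned responding is read out from:

- **SEBR** — startle eye-blink responses (orbicularis oculi EMG after
  acoustic startle probes), the typical primary memory readout;
- **SCR** — anticipatory and US-evoked skin-conductance responses;
- **PSR** — anticipatory pupil-size responses;
- **HPR** — heart-period responses (conditioned bradycardia) from ECG.

## The models at the core

Every measure is quantified under a *canonical response function* model: an
observed response is amplitude × fixed-shape kernel, so estimation reduces
to (possibly latency-shifted) regression.

- **SEBR**: the EMG is band-pass filtered (Butterworth order 4, 50–470 Hz),
  notch-filtered at 50 Hz and harmonics, rectified, and smoothed (order 4
  low-pass at 53.05 Hz). Each trial's amplitude is the nonnegative
  least-squares coefficient of a canonical blink kernel with variable onset
  searched on a 1 ms grid after the probe. Because electrode impedance and
  anatomy scale EMG multiplicatively, single-trial estimates are divided by
  the participant's mean CS⁻ amplitude.
- **SCR**: band-pass 0.0159–5 Hz (order 1, bidirectional), down-sampled to
  10 Hz; artifacts < 2 s interpolated, longer artifacts exclude the trial.
  Nonlinear inversion estimates, per trial, a fixed-dispersion anticipatory
  input at CS onset with free latency in [0, 2] s and an evoked input at the
  *potential* US time — blind to reinforcement; only nonreinforced trials
  are analyzed.
- **PSR**: blinks/saccades and off-screen gaze (> 5° from center) are
  missing data; the eye with fewer missing samples is used; trials with
  < 50 % valid data in the 10 s after CS onset are excluded; amplitudes come
  from a single-trial convolution GLM at 250 Hz.
- **HPR**: R spikes by a Pan–Tompkins-style detector; inter-beat intervals
  mapped to the following spike, gated to 400–1200 ms, interpolated to 10 Hz
  and band-passed 0.015–0.5 Hz; conditionwise amplitudes by convolution GLM.

Inference follows the field's convention: trialwise estimates enter linear
mixed-effects models, `response ~ drug * cs * time + (1 | participant)`,
with Satterthwaite-approximated F tests (verified against lme4/lmerTest);
conditionwise heart period enters a mixed-design repeated-measures ANOVA;
and the group × CS effect is probed by predicting each participant's
CS⁺/CS⁻ difference from the drug label in threefold cross-validation
(10 random partitionings), with a label-permutation null on the residual
variance proportion Σerr²/n/var.

## Worked example

```python
from threatphys import SimConfig, Phase, CVConfig
from threatphys.pipeline import run_pipeline

cfg = SimConfig(seed=7, n_per_group=3)      # tiny demo cohort
out = run_pipeline(cfg, "demo_out", cv_config=CVConfig(seed=1, n_permutations=100))
print(out["sebr_retention"].round(3).to_string(index=False))
print(out["crossval"].residual_variance_proportion, out["crossval"].p_value)
```

prints (seed 7):

```
           effect      F  df_num  df_den     p
             drug  1.566       1 265.985 0.212
       CS+ vs CS- 26.059       1 266.000 0.000
  drug:CS+ vs CS-  0.783       1 266.000 0.377
     CSr+ vs CSn+  1.687       1 176.000 0.196
drug:CSr+ vs CSn+  0.130       1 176.000 0.719
0.4251833231439564 0.0
```

The effect table is the retention-phase mixed-model F table on normalized
SEBR: strong conditioned discrimination (CS⁺ vs CS⁻), no reminder
specificity (CSr⁺ vs CSn⁺), and — at this demo size of 6 participants — an
undetectable drug × CS interaction. The cross-validation statistic 0.43
(≪ 1) with permutation p below resolution says the drug label predicts the
CS⁺/CS⁻ difference far better than the grand mean, because the simulator's
drug group retains a larger conditioned response. A command-line interface
(`threatphys simulate/fit/analyze/crossval/report`) wraps the same calls.

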