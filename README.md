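# exostrength

Estimating lower-limb muscular strength from how a person performs
resistance exercises in a hip-joint exoskeleton.

A hip exoskeleton that applies resistance torque during squats, knee-ups
and reverse lunges records a joint-torque trace from its motors while
wireless surface-EMG (sEMG) sensors record eight thigh muscles (rectus
femoris, vastus lateralis, biceps femoris, semitendinosus, both legs) at
2 kHz. From these signals alone — no musculoskeletal model — one can
extract simple performance metrics and regress a gold-standard strength
index on them. This package implements that full analysis chain for
researchers in exercise science and wearable-robotics analytics, plus a
calibrated synthetic-data generator so every stage is testable without
access to private participant recordings.

## The model

Each exercise is performed under two conditions: a short maximal-effort
bout (`Max`) and a longer metronome-paced bout (`Const`). The torque
trace shows one flexion peak per repetition; the flexion-to-flexion
intervals give per-repetition speed. Five metric families over three
exercises yield 27 metrics per participant:

* **NR** — repetitions completed;
* **IS** — initial speed, the mean rate over the opening repetitions
  (10 for squat/lunge, 30 for knee-up), in reps per 10 s;
* **CZ** — constant-speed zone, repetitions before the paced interval
  deviates persistently from the metronome target;
* **sEMG amp**, **iEMG** — change in MVIC-normalized sEMG amplitude /
  integrated EMG between the first and last 10 s of the bout, where
  MVIC normalization is `(sEMG − sEMG_rest) / (sEMG_max − sEMG_rest)`.

The dependent variable is a composite strength index from a standard
pre-measurement battery — vertical jump VJ, one-repetition-maximum leg
extension + curl, and isometric leg extension + curl, the load measures
normalized to body weight:

```
total_performance = z(VJ) + z((RM_LE + RM_LC)/weight) + z((ISO_LE + ISO_LC)/weight)
```

Candidate metrics are screened by Shapiro–Wilk normality, residual
normality and homoscedasticity (Breusch–Pagan) of the single-predictor
fit, and redundancy pruning by hierarchical clustering on 1 − |r| with
an |r| < 0.7 admissibility bound. The surviving predictors enter an OLS
model reported as B, SE, standardized β, multiple R, adjusted R²,
Cohen's f² = R²/(1 − R²), and post-hoc power of the overall F test
(noncentral F, λ = f²·n). Robustness is probed by bootstrap resampling
to 100/300 rows with 10%/30% SD-proportional Gaussian noise, the
composite index recomputed with the frozen original z-score moments.

The synthetic generator drives everything from a latent strength
variable: it sets both the muscle-parameter battery and the self-paced
squat speed (mean 8.47 reps/10 s, SD 2.0), with loadings solved in
closed form so that corr(squat initial speed, total_performance) = 0.873
and the single-predictor regression has slope 0.659 and intercept −5.58.

## Worked example

```python
from exostrength import (SimulationConfig, generate_cohort, generate_session,
                         generate_squat_only_cohort, get_protocol, detect_rep_peaks,
                         initial_speed, number_of_repetitions, constant_speed_zone,
                         fit_ols)

cfg = SimulationConfig(master_seed=42)
participant = generate_cohort(cfg)[0]
proto = get_protocol("squat", "const")          # 60 RPM for 90 s
bundle = generate_session(participant, proto, config=cfg)
series = detect_rep_peaks(bundle.torque, proto)
print("NR =", number_of_repetitions(series))
print("IS =", round(initial_speed(series, proto.initial_speed_window_reps), 2))
print("CZ =", constant_speed_zone(series, proto.target_rpm).constant_zone_reps)

df = generate_squat_only_cohort(30, seed=42)
m = fit_ols(df, "total_performance", ["Squat_IS_Max"])
print(f"B = {m.B[1]:.3f}  SE = {m.SE[1]:.3f}  beta = {m.beta[0]:.3f}")
print(f"R = {m.R:.3f}  adj R2 = {m.adj_r2:.3f}  f2 = {m.f2:.2f}")
```

prints

```
NR = 70
IS = 9.95
CZ = 43
B = 0.605  SE = 0.071  beta = 0.848
R = 0.848  adj R2 = 0.710  f2 = 2.57
```

This participant completed 70 of the 90 paced squat repetitions, opened
at 9.95 reps/10 s (the 60 RPM metronome is 10.0), and held the pace for
43 repetitions before fatigue broke the rhythm. On a 30-participant
cohort the squat-only regression recovers a slope and standardized
coefficient near the generating values (0.659 and 0.873) up to the
sampling noise expected at n = 30.

There is also a CLI for the full pipeline
(simulate → extract → metrics → model → validate → report):

```bash
exostrength run --out run_dir --seed 7
```

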