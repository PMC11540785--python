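# Methods

## Scope

`exostrength` implements an analysis chain for estimating baseline
lower-limb strength from exoskeleton resistance-exercise performance:
signal conditioning of joint torque and sEMG, repetition-level metric
extraction, construction of a composite strength index, statistically
screened multivariable regression, and bootstrap robustness checks. A
synthetic-data module generates cohorts with the statistical structure
the analysis assumes, because the original participant recordings are
private. Exoskeleton control, kinematics, and any claim about real
participants are out of scope.

## Synthetic data model

**Latent structure.** Each participant carries a standard-normal latent
strength `L`. Three battery quantities load linearly on `L` with
Gaussian noise: vertical jump (45 ± 8 cm), weight-normalized 1RM sum
(1.6 ± 0.35 kg/kg) and weight-normalized isometric sum (6.0 ± 1.2 N/kg).
The loadings are not free knobs: given the target correlation ρ = 0.873
between squat initial speed and the composite index, and the speed
model's own correlation with `L` (0.95), the common per-parameter
loading correlation is solved in closed form from
corr(speed, Σz) = 0.95 · 3r/√(3 + 6r²), giving r ≈ 0.8026. Raw LE/LC
values are recovered from the generated ratios by fixed split fractions
(0.60 for 1RM, 0.55 for isometric) times body weight, so the
weight-normalized ratios — the quantities the analysis actually uses —
follow the linear-Gaussian model exactly. Demographics use the study
cohort moments (weight 66.43 ± 9.8 kg, height 170.93 ± 8.5 cm, age
26.1 ± 2.8 y, 19/30 male).

**Pacing.** Metronome bouts use the protocol cadence (squat 60 RPM/90 s,
knee-up 132 RPM/180 s, lunge 48 RPM/120 s); self-paced bouts (squat
45 s, knee-up/lunge 60 s) map `L` through a per-exercise speed model,
for squats 8.47 + 1.9·L reps/10 s plus N(0, 0.6245²) — total SD 2.0.
The first flexion peak sits at half the base interval, so a bout of
duration D at fixed interval I plants ⌊D/I⌋ repetitions. After the
fatigue onset (default 40 s) each interval is the previous times
(1 + drift) with multiplicative noise (defaults 3 %/rep, SD 2 %);
pre-onset intervals jitter by 1 %. A repetition is only planted if its
torque lobe can descend before the recording ends (0.3 cycles of
post-peak margin) — an uncompleted movement is not a repetition.
Planted times are snapped to the 2 kHz sample grid and returned as
ground truth.

**Waveforms.** Torque: per cycle one positive raised-cosine flexion
lobe (8 Nm peak, below the device's 10 Nm limit, half-width 0.35
cycles) centred on the planted time, and one negative extension lobe
(−60 %, half-width 0.25 cycles) half a cycle later; additive Gaussian
noise 0.05 Nm. sEMG per channel: band-limited (20–450 Hz) unit-RMS
noise gated by one Gaussian burst window per repetition (SD 0.12
cycles), burst amplitude drifting linearly by +50 % first→last rep (the
classic sub-maximal fatigue pattern; the sign is configurable since
only the magnitude of the change is established), plus a mains sinusoid
(default 60 Hz, amplitude 0.2, configurable to 50 Hz) and white noise
(SD 0.05). Knee extensors carry unit gain, hamstrings 0.7.

**What the generator does not emulate.** Real sEMG nonstationarity
(spectral compression under fatigue, motion artefacts, electrode
drift), torque waveform asymmetries, left/right imbalance, and any
nonlinearity between strength and performance. Passing tests therefore
demonstrate that the *analysis chain* is correct and well calibrated
under its own assumptions, not that the regression would attain the
same accuracy on new human data.

**Calibrated squat-only model.** For parameter-recovery checks a direct
generator draws the predictor from N(8.47, 2.0²) and the response as
−5.58 + 0.659·x + ε, with ε's SD the closed-form value (0.7363)
producing corr = 0.873. Note −5.58 + 0.659·8.47 ≈ 0: the composite
index is mean-zero by construction. The implied closed-form slope SE at
n = 30 is σ_ε/(σ_x·√29) ≈ 0.068.

## Signal processing

All filters are 4th-order IIR applied forward–backward (zero phase):
a notch at the mains frequency (Q = 30) and a 20–500 Hz Butterworth
band-pass whose low edge doubles as the high-pass that removes slow
mechanical artefacts (a separate high-pass stage would be redundant).
The envelope is a moving RMS (default window 0.1 s, reflect padding, so
length is preserved). MVIC normalization acts on the envelope:
`sEMG_max` is the per-channel maximum envelope over the reference
recordings, `sEMG_rest` the median envelope of a rest recording (median
for robustness). In the pipeline the reference recordings are the
participant's own exercise sessions plus a generated rest trace; with
real data the 1RM/isometric recordings should be passed instead.

Peak detection uses local maxima with minimum inter-peak distance 0.5×
the protocol's expected interval and prominence ≥ 30 % of the trace's
95th-percentile amplitude (robust to double-bumped torque cycles).
Torque is pre-smoothed with a 50 ms centred moving average: symmetric,
so symmetric lobe peaks do not move, while broadband noise that would
jitter the flat lobe top is suppressed. On noiseless sessions detected
times equal planted times to the sample; at default noise they agree
within ~12 ms.

## Metrics

Initial speed is reported in reps per 10 s (60 RPM ↔ 10/10 s), which
makes the regression coefficients coherent with the calibrated speed
scale. The lunge IS window is 10 repetitions (the metric definitions
take precedence over a conflicting prose statement of 30; it is
configurable). The constant-speed zone flags an interval as deviating
when it differs from the metronome interval by more than 10 % and ends
the zone at the first run of 3 consecutive deviating intervals — the
threshold and persistence are unpublished, so both are configurable; a
brute-force scan over all windows is the test oracle. An optional
minimum-zone-duration check exists (default off) for protocols that
only evaluate the zone after a warm-in period. sEMG amp/iEMG deltas use
10 s end-minus-start windows per channel, averaged unweighted across
the eight muscles (per-channel values remain available). Undefined
metrics propagate as missing values, never zeros; rows with missing
cells are retained and dropped listwise only inside each fit.

## Statistics

Sample SDs use the n − 1 denominator throughout. Normality is
Shapiro–Wilk at α = 0.05; homoscedasticity uses Breusch–Pagan at
α = 0.05 as a reproducible substitute for visual residual/QQ
inspection. Clustering is average linkage on 1 − |r| cut at 0.3 (the
|r| = 0.7 bound); each cluster contributes its most target-correlated
member, ties alphabetical. OLS is fitted by `statsmodels`;
β_j = B_j·sd(x_j)/sd(y); R = √R²; f² = R²/(1 − R²); power is the
noncentral-F tail beyond the central critical value with λ = f²·n
(the G*Power convention — at the effect sizes involved every
convention saturates near 1). The standard adjusted-R² formula is used
even where published tables appear internally inconsistent with it.

Bootstrap validation resamples rows with replacement to the target size
and adds independent Gaussian noise with SD = fraction × the *original*
column SD to every predictor and every raw component of the composite
index, which is then recomputed with the frozen original z-score
moments. Because "10 %/30 % Gaussian noise" admits several readings,
the noise ordering (before/after resampling) and scope (predictors only
vs. all variables) are config options; defaults are after-resampling on
all variables. Only the qualitative pattern — mean R non-increasing in
the noise fraction — is asserted, not specific R values. With sex and
age included, sex enters as male = 1 / female = 0.

## Numerical and design notes

* Muscle-parameter positivity: rejection-resample up to 100 draws, then
  clip at 1 % of the mean — preserves configured moments almost
  everywhere.
* Degenerate inputs: constant samples fail the normality test
  explicitly; exact linear fits raise on residual diagnostics; rank
  deficiency raises with the collinear columns named; an empty peak
  series is returned with a warning (zero repetitions is a meaningful
  outcome).
* Stage seeding: one master seed fans out per stage by CRC-32 of the
  stage name, so stages are individually reproducible; all seeds stay
  below 2³¹.
* Problem sizes: population-level calibration checks use n = 5000
  cohorts through the repetition-planning fast path (waveform synthesis
  adds nothing to those invariants); end-to-end signal tests use single
  sessions and cohorts of ≤ 8; slope-recovery checks use 500 cohorts of
  n = 30 and one cohort of n = 100 000 through the direct calibrated
  generator.

## Known limitations

* The MVIC reference built from exercise sessions bounds normalized
  values by the session's own maximum; with real pre-measurement MVIC
  recordings the normalization is absolute.
* The composite-index variance implied by three correlated z-scores
  (≈ 2.6 SD) is larger than the calibrated regression's response SD
  (≈ 1.5): the full signal-level chain reproduces the target
  *correlation* 0.873, while slope-level recovery is defined against
  the direct calibrated generator.
* sEMG-derived repetition series are validated by agreement with the
  torque series (≥ 95 % within 150 ms), not by sample-exact recovery —
  burst maxima of stochastic envelopes are intrinsically jittered.
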