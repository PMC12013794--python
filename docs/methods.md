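# Methods

## Background and scope

Spinal motoneurons carry dendritic persistent inward currents (PICs) that
are facilitated by brainstem monoamines. PICs both amplify excitatory
synaptic input and prolong discharge after the input declines, producing
onset–offset hysteresis: a motor unit (MU) is derecruited at a lower drive —
and hence lower torque — than the drive at which it was recruited. `picpool`
implements the standard human-electrophysiology analysis chain for this
phenomenon (paired-unit ΔF, discharge-rate smoothing, brim/button/cap
classification on superimposition ("sombrero") tasks, sustained-discharge
and torque-variability metrics, MUAP-based unit matching, mixed-model
summaries) and pairs it with a synthetic motoneuron-pool simulator that
provides exact ground truth for every metric. High-density surface-EMG
decomposition itself is out of scope; the pipeline starts from spike trains.

## The simulator

### Drive-domain hysteresis model

Unit *i* has a recruitment threshold θᵢ in % MVT-equivalent drive. It is
recruited the first time the common drive reaches θᵢ; once recruited, its
effective drive is `drive(t) + Δᵢ·λ`, where Δᵢ ≥ 0 is the unit's PIC
hysteresis and λ the length factor (below). It is derecruited the first time
the drive falls below `θᵢ − Δᵢ·λ`, or at command end. While active, the mean
discharge rate is

    rᵢ(t) = rate_min + gᵢ · (drive(t) + Δᵢ·λ − θᵢ)   [pps]

This is deliberately *not* a conductance-based motoneuron model: it is the
smallest mechanism that reproduces the discharge signatures the analysis
measures — positive ΔF equal to `g_reporter · Δ_test · λ` exactly, prolonged
descending-limb discharge, and cap units on sombrero tasks — while keeping
every landmark analytically available. PIC activation is instantaneous at
recruitment; there is no onset time constant, no warm-up dependence, and no
saturation. Consequences are discussed under Limitations.

Event times are solved exactly on the piecewise-linear command breakpoints,
not by grid search, so the noiseless ground truth carries no discretization
error and classification/sustained-discharge checks can be asserted at
sample precision.

### Commands

* **sombrero** — plateau at 10 % MVT for 10 s, linear ramp at 3 % MVT/s to
  30 % MVT and back, plateau at 10 % MVT for 10 s. Segment labels
  (plateau_one, ramp_up, ramp_down, plateau_two) are recorded at the
  analytic breakpoints.
* **hold** — constant 10 % MVT for the matched sombrero's total duration,
  carrying the matched plateau windows.
* **ramp** — 0 → 30 → 0 % MVT triangle at 3 % MVT/s.

All trajectories are sampled on a uniform 2048 Hz grid, matching the torque
digitization rate the analysis assumes.

### Spiking

Spikes are a gamma-renewal process in rescaled (operational) time: the
cumulative intensity Λ(t) = ∫r is inverted at unit-mean gamma increments
with shape 1/CV² (`isi_cv = 0` gives deterministic interspike intervals).
Two boundary conventions matter for the analysis:

* a spike is emitted exactly at the recruitment crossing, and
* the final spike is pinned to the derecruitment crossing (the last interior
  spike is snapped there when it falls within half a mean ISI of it).

With these conventions the measured first/last-spike landmarks coincide with
the true event times, so the zero-hysteresis case has exactly equal
recruitment and derecruitment torques and the sustained-discharge metric is
exactly zero — the property the analysis uses as its null reference.

### Pool parameters and defaults

| parameter | default | rationale |
| --- | --- | --- |
| `n_units` | 20 | typical per-trial decomposition yield |
| `threshold_range` | (1, 25) % MVT | spans recruitment below and within the 10→30 % ramp |
| `threshold_shape` | 3 | exponential skew toward low thresholds (size principle); 0 = even spacing |
| `rate_min` | 5 pps | discharge rate at recruitment |
| `gain` | 1 pps / % MVT | drive-to-rate gain |
| `hysteresis` | 2 % MVT | yields ΔF ≈ 2 pps at unit gain, mid-range for healthy adults |
| `isi_cv` | 0.1 | interspike-interval variability of steady voluntary discharge |
| `length_factor` | long 0.7 / mid 1.0 / short 1.5 | muscle-length modulation of effective hysteresis |
| torque noise | 0.3 % MVT, low-passed at 10 Hz | physiological tremor-band noise floor |
| EMG SNR | 15 dB | usable surface-EMG recording |

The length factor encodes the working hypothesis that shorter agonist
muscles see more spinal excitability and less net inhibition, hence larger
*effective* PIC hysteresis. It multiplies Δᵢ directly; the analysis side
never sees it.

### Torque

Each spike contributes one twitch `P·(t/Tc)·exp(1 − t/Tc)`; twitch amplitude
grows ~30-fold and contraction time shrinks from 90 to 30 ms across the pool
(size principle). The MVT constant is defined analytically as the
steady-state noiseless torque under a sustained 100 % drive,
`Σᵢ rᵢ(100)·Pᵢ·Tcᵢ·e`. Tracking is open-loop: the twitch-summed torque is
rescaled by one least-squares gain onto the command, so plateau torque sits
near the commanded level but recruitment nonlinearity is not servoed away.
An optional proportional feedback controller (`feedback_gain > 0`)
renormalizes the drive against the predicted torque; it reproduces the
phenomenology in which cap units discharging in plateau two force the rest
of the pool (the brim units) to lower rates, and is off by default.

Because tracking is open-loop, *measured-torque* landmarks lag the command
by roughly a twitch time. Sustained-discharge crossings for simulated data
are therefore computed in the command domain (exact); for measured data the
50 Hz-filtered torque with linear interpolation is used, with a `no_crossing`
flag when the torque never falls back to the recruitment level.

### EMG

Each unit's MUAP is a biphasic wavelet (Gaussian first derivative, width
1.5–3 ms) scaled per channel by a spatial Gaussian (σ = 1.5 electrodes) on
the 13×5 grid; EMG is the spike-train/template convolution plus white noise
at the requested SNR. Unit properties are drawn from a dedicated
`unit_seed`, so the same unit keeps one waveform across trials — the premise
that makes cross-trial matching well-posed — while the trial seed drives
only the noise.

## The analysis chain

### Rates and smoothing

Instantaneous rates are reciprocals of the interspike intervals. The
continuous estimate is an RBF-kernel support vector regression with the
ε-insensitive (L1 soft-margin) loss — length scale 1 s, C = 10,
ε = 0.1 pps — evaluated on a uniform 2048 Hz grid from recruitment to
derecruitment, with no extrapolation beyond the spike span. The
hyperparameters target smoothness at the ~1 s timescale of the paradigms and
are recorded in `model_params`; below four samples the fit falls back to
flagged linear interpolation.

One numerical choice deserves emphasis: the regression is trained at the
interval **midpoints**. 1/ISI estimates the *average* rate over the
interval, which equals the instantaneous rate at the midpoint when the rate
is locally linear. Training at the later spike instead would lag the curve
by about half an ISI, and since ΔF subtracts the curve at two landmarks that
sit on opposite slopes of the ramp, that lag produces a systematic negative
ΔF bias of roughly (rate slope × ISI) ≈ 0.3 pps — large enough to matter at
the effect sizes of interest. The public `instantaneous_rates` samples keep
the later-spike timestamp convention for reporting.

### ΔF

For a higher-threshold test unit, ΔF against each lower-threshold reporter
is the reporter's smoothed rate at the test unit's recruitment minus at its
derecruitment (positive = hysteresis). Pairs are excluded when rate–rate
r² ≤ 0.7 (common drive), recruitment separation < 1 s (full PIC activation
in the reporter), or the reporter's smoothed range while the test is active
is < 0.5 pps (saturation); the first violated rule is recorded, the unit's
ΔF is the mean over surviving pairs, and the r² threshold is strict (> 0.7
survives). r² is computed on both curves resampled to a common 2048 Hz grid
over the test-active span.

### Sombrero classification and sustained discharge

Brim units recruit before the ramp window, button units recruit and stop
within it, cap units recruit in it but maintain discharge past the start of
plateau two. Maintained discharge tolerates gaps strictly below 1 s — a gap
of exactly 1 s terminates it. Sustained discharge is the signed time from
the descending-limb re-crossing of the recruitment torque to the discharge
end; the per-trial proportion counts cap units sustaining > 2 s over the
ramp-recruited units (cap + button) by default, with cap + brim available as
an option (`denominator="cap+brim"`), since both groupings are defensible
readings of the metric. Units recruited during plateau two are categorized
"other" and excluded from the three named classes.

### Torque variability

Torque is low-pass filtered at 50 Hz (5th-order Butterworth, zero-phase by
default so landmarks are not lag-shifted; a single-pass mode preserves the
textbook −3 dB cutoff semantics). CV is 100·SD/mean (sample SD) of % MVT
torque inside a plateau window, computed on the 50 Hz-filtered signal;
windows are trimmed by 0.5 s per side by default to avoid ramp transients.
ΔCV is plateau-two minus plateau-one. The 125 ms moving average mirrors the
feedback display smoothing and is not used for CV. An optional screen flags
trials deviating more than 5 % MVT from the command for over half of a
segment; flagged trials are never auto-dropped.

### Matching

MUAPs are spike-triggered averages over ±25 ms windows (edge-clipped windows
dropped; < 10 usable spikes flags low confidence). Similarity is the maximum
over ±5 ms time lags of the normalized (mean-subtracted, unit-norm)
channel×time inner product, on the channels present in both templates (at
least 75 % of the grid required); spatial shifts are not searched by
default. Assignment is greedy in descending correlation (unit-id
tie-break, so input order is irrelevant), one-to-one within each trial
pair, accepting only correlations strictly above 0.8; accepted pairs are
chained by union-find and every chain — or unmatched unit — gets one MU
identifier.

### Statistics

Metric tables are fit with `statsmodels` MixedLM: categorical fixed effects
with their interaction, a centered trial-number covariate, and a random
intercept per participant. Factor p-values come from likelihood-ratio tests
of ML fits with and without the factor (including its interactions).
Estimated marginal means average the fixed-effect design over the other
factors' levels at covariate zero; pairwise contrasts use the fixed-effect
covariance with Tukey (studentized-range) adjustment for factors with more
than two levels. Cohen's d uses the pooled-SD formula; a model-sigma-scaled
variant is provided separately (`cohens_d_model`) and labeled as such.
Singular or non-converged fits are reported in `result.warnings`, never
silently dropped.

## Validation experiments and problem sizes

`picpool.experiments` fixes the configurations used by the test suite and
by `scripts/acceptance.py`:

* **ΔF recovery** — 20 units, 30 % triangular ramp, uniform gain
  1.5 pps/%MVT, 2 %MVT hysteresis on the designated test unit (true
  ΔF = 3.0 pps for every pair), isi_cv = 0.1; 30 seeds per condition.
* **Classification / sustained discharge** — noiseless sombreros (isi_cv 0,
  torque noise 0) checked against the analytic event-time oracle.
* **Matching** — 3 trials × 15 units at 15 dB SNR with known identities.
* **Length contrast** — matched seeds at length factors 0.7 vs 1.5;
  20 seeds.
* **Mixed-model calibration** — tables with a −2 pps plateau effect,
  participant SD 0.5, residual SD 0.7, 12 participants × 4 trials;
  50 coverage and 200 null replicates.
* **Plateau gain-state probe** — identical 1.5 %MVT, 3 s drive pulses in
  each plateau of a sombrero whose ramp-recruited units all become caps.
  The probe pool leaves a threshold gap around the perturbed drive range so
  the pulse measures the gain of the already-discharging pool: in this
  minimal model a newly recruited unit receives its full PIC boost
  instantly and would otherwise dominate the plateau-one response, which is
  a model artifact rather than a property of the probe.

These sizes were chosen so each experiment's seed-to-seed standard error is
well below the effect it measures.

## What the simulator does and does not emulate

It emulates: orderly recruitment with threshold skew, onset–offset
hysteresis and its muscle-length modulation, renewal discharge variability,
twitch summation with size-principle scaling, band-limited torque noise,
spatially localized MUAPs on a 64-channel grid, and trial-stable unit
identities. It does not emulate: conductance dynamics or PIC onset/decay
kinetics, rate saturation and spike-frequency adaptation, common-drive
oscillations shared across units, decomposition errors (missed/merged
spikes), MUAP waveform changes with joint angle, or muscle mechanics beyond
a fixed twitch shape. Passing tests therefore demonstrate that the
*estimators* recover programmed discharge phenomena through the full
pipeline — not that real muscles obey the drive-domain model.

## Known limitations

* ΔF recovery retains a small residual bias (≲ 0.1 pps) from smoothing
  curvature and the boundary-pinned spikes; it is measured, not corrected.
* The greedy matcher is order-independent but not globally optimal; at the
  correlation separations the templates produce this is immaterial.
* The open-loop torque model cannot express the plateau-two *rate drop* of
  brim units without the optional feedback controller.
* Mixed-model p-values rely on asymptotic χ² likelihood-ratio distributions;
  at very small group counts they are approximate (the calibration
  experiment quantifies this at the sizes used).
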