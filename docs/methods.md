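# Methods

## Stimulus model

A block is a 300 s coherence time series at 100 Hz, piecewise constant over
"noise intervals". Interval durations are exponential with mean 270 ms,
truncated to [10, 1000] ms **by rejection resampling**, which preserves the
exponential shape within the bounds; clipping is *not* used (clipping would
pile mass at the bounds and change the interval-count distribution). The
final interval is clipped so intervals tile the block exactly. At these
statistics a 5-minute block carries on the order of 1100–1200 intervals
(expected duration of a truncated draw ≈ 254 ms).

Blocks alternate baseline and response periods. Baseline durations are
Uniform over the condition's range (only a range is specified by the task
design; uniform is the maximum-entropy choice on an interval). Response
periods last 5 s (LONG) or 3 s (SHORT) with mean coherence drawn uniformly
from ±{0.3, 0.4, 0.5}. Each interval's coherence is drawn
N(mean, SD) using the period active at the **interval onset** (intervals
are not split at period boundaries); draws outside [−1, 1] are set to ±1.
SDs are 0.5 (baseline) and 0.3 (response).

One root seed splits (via `numpy.random.SeedSequence.spawn`) into
independent sub-streams for the period schedule, the interval durations and
the coherence draws, so conditions sharing a seed share their noise
process; RARE and FREQUENT schedules then differ only through baseline
durations.

Interval onsets are kept unquantised in the interval table and rounded to
the nearest sample when the per-sample series is materialised.

## Scoring

A press inside a response period — or within 0.5 s after its end, if no
earlier press claimed the period — scores +3 when its direction matches the
sign of the period mean, −3 otherwise; either press terminates the period.
All other presses are false alarms (−1.5), and unclaimed response periods
are misses (−1.5). Total points always decompose as
3·nCorrect − 3·nIncorrect − 1.5·(nFA + nMiss).

Two scoring contexts exist and differ deliberately:

- `stimgen.score_responses` scores a press log against a **fixed,
  already-materialised** block. Early termination is recorded by setting
  the period's `actual_end_s` to the press time; subsequent period onsets
  stay where they were scheduled, because the coherence series was
  generated from that schedule and relabelling it post hoc would
  desynchronise labels from the noise statistics. Presses after a claimed
  period's termination are false alarms.
- `oumodel.run_closed_loop` couples generation and behaviour as in the
  live task: when the agent's press terminates a response period, the next
  scheduled baseline (with its own sampled duration) begins at the press
  time and all subsequent stimulus is generated from the shifted schedule.
  Re-scoring the emitted block and press list through `score_responses`
  reproduces the closed-loop outcomes exactly (tested).

## Integration kernels

Kernels average the signed coherence over the 5 s (501 samples) preceding
each press, with leftward presses sign-flipped. Presses earlier than 5 s
into a block are excluded rather than zero-padded (padding would bias early
lags toward zero). For correct-response kernels and RT summaries, LONG
responses slower than 3.5 s are excluded so LONG and SHORT compare on the
same support; false-alarm kernels have no RT and no such exclusion.
False-alarm rate divides false-alarm count by total scheduled baseline
time.

The exponential model k(t) = A·e^(−t/τ) (t in seconds before the kernel
peak) is fitted to all lags up to and including the peak. The peak is the
grid argmax, ties broken toward the lag closest to the response. The cost
is penalised least squares, Σ(k − k̂)² + 0.01·(A² + τ²), minimised with
Nelder–Mead on (log A, log τ) — positivity by construction — from
A₀ = kernel maximum, τ₀ = 1 s, tolerance 1e−8. R² = 1 − RSS/TSS is
computed over the fitted range without the penalty, with TSS about the
fitted-range mean; for a constant kernel (TSS = 0) R² is −∞ unless the fit
is exact. Fits are flagged when the optimiser fails or when τ̂ exceeds the
5 s window (the decay is then unidentified by the data). On synthetic
kernels (A ∈ [0.2, 0.6], τ ∈ [0.3, 2] s, noise SD 0.02) the median
relative error of τ̂ is below 10%, and the simplex solution agrees with a
dense 2-D grid minimiser of the same objective within grid resolution.

## Leaky accumulator

X_t = (1+λ)X_{t−1} + g·M_t + ε_t with ε_t ~ N(0, σ²), on the 10 ms sample
grid; λ and σ are therefore per-10 ms quantities. A response is emitted at
the first sample with |X| ≥ θ (with a 1e−9 absolute guard so exact
deterministic ramps cross at the mathematically intended step) and X resets
to 0 from the next sample. λ = 0 recovers drift-diffusion accumulation,
but the leak is constrained negative throughout: an accumulator that never
discounts stale evidence cannot perform this task, and the model family
deliberately excludes it from the default grids.

Defaults: g = 1 (held constant), σ = 0.25 per step, λ = −0.002, θ = 70.
With unit gain on per-sample coherence, stimulus-driven fluctuations
dominate σ; the accumulator's stationary scale is set by the integration
time 1/|λ| (in samples). A landscape survey showed the reward-positive
ridge lies at integration times of roughly 0.2–10 s (|λ| ∈ [0.001, 0.05])
with thresholds of order 10–150, the two trading off along a ridge; the
default grids (`DEFAULT_LAMBDA_GRID`, log-spaced over that leak range, and
`DEFAULT_THETA_GRID`) bracket this region. Outside it — e.g. heavy leak
with a low threshold — every parameterisation loses points and the argmax
degenerates to the never-press corner, which carries no information about
condition adaptation. The focused `COMPARISON_*` grids resolve the
multi-second integration regime finely and are used for matched per-block
optimum comparisons. No non-decision time and no time-varying urgency are
modelled.

The grid search holds g and σ fixed, runs closed loop by default, scores
through the task rule (no separate scoring path), and uses common random
numbers: streams on the same seed share stimulus and accumulator draws
across cells up to the point behaviour diverges. The top-decile mask marks
the round(10%) best cells (at least one), ties broken by a fixed argsort
order, and necessarily contains the argmax.

Model-kernel sweeps pool the agent's false alarms across streams, then
reuse the behavioural kernel and fit machinery unchanged. Settings with
fewer than 50 false alarms are flagged under-sampled. Across a θ sweep at
fixed λ the fitted τ̂ rises monotonically with θ (a higher threshold needs
sustained evidence before a crossing), while a λ sweep at fixed θ chiefly
moves the kernel amplitude Â.

## Deconvolutional GLM

Eleven regressors are derived per block: sticks at coherence change-points
("jump events"; the first interval's predecessor coherence is taken as 0),
their |level| and |Δevidence| modulators, continuous absolute and signed
evidence, response-period onset sticks with a |coherence| modulator, and
correct/false-alarm buttonpress sticks with signed (+1 right / −1 left)
twins. The five evidence-derived regressors are estimated from baseline
periods only, implemented by zeroing their values during response periods
(the stimulus statistics during baseline are identical across conditions);
buttonpress and period-onset regressors span the whole block. Parametric
modulators are not mean-centred (switchable).

Time expansion ("staircasing") gives one column per lag from −pre to +post
in 10 ms steps; a column at lag ℓ ≥ 0 models activity ℓ ms *after* the
event, negative lags anticipatory activity. Lag windows (pre/post ms →
columns at 100 Hz): jump event and level 1000/1500 → 251; |Δevidence| and
both continuous regressors 1500/1500 → 301; buttonpresses 5000/3500 → 851;
response-period regressors 500/8000 → 851. Lagged copies are zero-padded
at block edges (no wraparound), so the design-matrix product with any β
equals the sum of per-regressor convolutions (tested against a direct
convolution oracle).

TRFs are estimated per channel by OLS via the normal equations with
Cholesky factorisation; rank deficiency falls back to the minimum-norm
pseudoinverse solution with a warning recorded in the metadata. Noiseless
recovery is exact to machine precision whenever the design has full column
rank, also under row masking. For real recordings an artifact mask
excludes ±500 ms around any |sample| ≥ 100 µV; the pipeline performs no
filtering or re-referencing, and optional real-EEG ingestion accepts plain
(samples × channels) arrays with labels and sampling rate.

Synthetic EEG for recovery testing convolves the regressor streams with
known ground-truth curves, scales by per-channel spatial weights and adds
white or AR(1) noise. At the default demonstration scale (curve amplitude
~1.5, innovation SD 1.0, AR coefficient 0.5, one 5-minute block) a
triphasic evidence TRF is recovered with r > 0.95.

Collinearity tables report squared Pearson correlations between the
un-expanded regressor series. Our convention uses all samples of the
baseline-masked series; for |new level| vs |Δevidence| of consecutive
zero-mean Gaussians this sits near the analytic absolute-bivariate-normal
value (r = 1/√2 between level and difference gives R² ≈ 0.21 between their
absolute values, ignoring the ±1 clipping) — close to, but a different
convention from, event-level tabulations that report ≈ 0.18.

## Group statistics

Beta timecourses are smoothed with a unit-area Gaussian kernel of 75 ms
FWHM (SD = FWHM/(2√(2 ln 2))), truncated at 4 SD, with reflective edges.

The paired cluster test computes per-timepoint paired t-statistics across
subjects, forms clusters from contiguous runs with |t| above the threshold
(default 2.07), splitting runs at sign changes so each cluster carries a
consistent sign, and scores each cluster by its summed t ("mass"; the
extent statistic is not used). The null distribution of the maximal
|cluster mass| comes from random sign flips of the subject difference
curves — the standard exchangeability argument for paired designs — with
full enumeration when 2^n ≤ n_perm and the observed labelling included,
so p ≥ 1/n_perm. Significance is two-tailed at alpha 0.05. Under
exchangeable null conditions with 24 synthetic subjects the family-wise
error sits at the nominal 5% within Monte-Carlo error (500 simulations,
1000 permutations each). Electrode selection/averaging happens upstream;
the module operates on channel-averaged curves.

Across-subject brain–behaviour coupling uses Spearman rank correlation at
each timepoint between (smoothed) betas and one behavioural value per
subject (typically the kernel τ), plus the correlation of window-averaged
betas over a stated window (default 420–750 ms). Ties take average ranks;
constant inputs return NaN.

## Synthetic data: what it does and does not show

All tests run on internally generated data: stimulus blocks from the
generator above, agent behaviour from the closed-loop accumulator, and EEG
synthesised from known TRFs. This validates the *estimators* — that
kernels, fits, TRFs and cluster statistics recover known ground truth
under the stated noise models — and the *qualitative model phenomena*
(threshold→τ coupling, condition adaptation of optimal parameters). It
does not emulate human non-decision time, motor noise, attention lapses,
session drift, eye-movement or muscle artifacts, or spatially structured
EEG noise, so passing tests bound estimator correctness, not effect sizes
in real cohorts. Group-level numbers from the human cohort (e.g. median
fit R², across-subject ρ) depend on the deposited real data and are not
reproduced here.

## Problem sizes

Default analyses use 5-minute blocks at 100 Hz. The test suite sizes its
simulations to keep the full run around 1–2 minutes on one core: 100
blocks for interval density, 24 blocks per condition on the focused 8×4
comparison grid, 12 streams for kernel sweeps, 500 null simulations × 1000
permutations for calibration, and single-block TRF recoveries. All results
are seeded and deterministic.
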