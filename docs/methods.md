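# Methods

`boutlab` quantifies how larval zebrafish organize locomotion into discrete
swim bouts, and how lighting and circadian state reshape that organization.
This note records the models, the measurement definitions, the numerical
choices, and what the synthetic swimmer does and does not emulate.

## The measurement problem

A larva viewed from the side is described at each frame by horizontal
position *x* (mm), vertical position *z* (mm, up positive) and pitch angle
θ (degrees, nose-up positive), sampled uniformly (default 166 Hz) within
continuous *tracking epochs*. Larvae are front-heavy: between bouts they
passively rotate nose-down and sink; during bouts they translate and can
rotate nose-up. The pipeline decomposes the pose record into bouts and
inter-bout intervals (IBIs) and measures, per event:

- **Swim speed** — central difference of position,
  `s_i = fr·√(Δx² + Δz²)/2`, one-sided at epoch ends, then a centered
  3-frame moving average. Bouts are maximal runs with `s > 5 mm/s`.
  Runs shorter than 18 ms are discarded before runs separated by dips
  shorter than 50 ms are merged — in that order, so that noise blips can
  never seed a merge and the bout count is monotone in the merge gap.
- **Bout window** — 450 ms around the speed peak, −250 ms to +200 ms
  (`floor(0.25·fr)` + `floor(0.20·fr)` + 1 = 75 samples at 166 Hz). Bouts
  whose window would cross an epoch boundary are excluded as truncated.
- **Bout duration** — full width at half maximum (FWHM) of the speed
  profile, crossings located by linear interpolation; profiles that never
  fall below half-max inside the window are kept but flagged censored and
  excluded from duration summaries.
- **Displacement** — summed Euclidean step length over the super-threshold
  run.
- **Direction** — elevation of the instantaneous trajectory at the peak,
  `atan2(Δz, |Δx|)`; the absolute horizontal component makes left- and
  right-swimming equivalent, so direction lives in [−90°, +90°].
- **Rotation** — pitch at +200 ms minus pitch at −250 ms (window
  endpoints, a literal net change rather than a fitted slope).
- **IBI duration** — time between the super-threshold run edges of
  consecutive bouts. **IBI drift** — pitch at the next bout's window start
  minus pitch at the previous bout's window end. With these endpoint
  conventions, bout rotations and IBI drifts tile the pitch trajectory
  without overlap, so drift + subsequent rotation (the *compensation
  residual*) telescopes exactly.

## Postural compensation

The central statistic is the **compensation gain**: the absolute slope of a
robust regression of bout rotation on the drift of the preceding IBI,
restricted to middle bouts of 3-bout sequences (bouts with both a preceding
and a following IBI) and split by whether that IBI is *long* or *short*
relative to the median dark-condition IBI duration (strictly greater is
long; the dark pool is DD zeitgeber-day IBIs, or LD night IBIs when no DD
data are present). A gain of 1 means the bout fully corrects the drift
accrued since the previous bout.

The regression is iteratively reweighted least squares with Tukey bisquare
weights: tuning constant c = 4.685, robust scale 1.4826·median(|residual|)
re-estimated every iteration, convergence when the largest coefficient
change falls below 1e-8 (50 iterations maximum; non-convergence is flagged
and the last iterate reported). R² is reported unweighted about the robust
line — it can be negative when outliers dominate, which is informative and
deliberately not masked. Significance of the slope comes from case (pair)
resampling — B bootstrap refits, p = 2·(k+1)/(B+1) where k counts bootstrap
slopes on the opposite side of zero, capped at 1. Residual resampling is
avoided because robust-fit residuals are not exchangeable under
heteroscedasticity. Note the add-one correction floors the p-value at
2/(B+1): B = 1000 cannot report below 0.002.

**Compensation precision** is the median absolute deviation (MAD) of the
compensation residual.

## Navigation

Navigation metrics use sliding windows of five consecutive bouts within one
tracking epoch (stride 1, so k bouts yield k−4 windows; windows never span
an epoch break). *Displacement per second* is the straight-line — not
path — distance between the window-start positions of bouts 1 and 5 over
the elapsed time between those window starts. *Directional change per
second* sums the four absolute direction changes between consecutive bouts
over the same elapsed time. Windows containing an undefined direction
(stationary peak) are skipped and counted.

## Circadian analysis

Analyses are clock-anchored to a 48 h window starting 10 a.m. on day 1.
Phase labels follow the 14/10 entrainment schedule (lights 9:00–23:00),
with the hour on either side of each switch (8–10 h, 22–24 h) labelled
*transition* and excluded from day/night summaries; the same labels apply
to zeitgeber time under DD and LL (circadian day/night).

Per experimental repeat, a parameter is reduced to binned medians (2 h bins
for time courses, 0.5 h for rhythm detection; empty bins are missing, never
zero) and z-scored against the repeat's own mean and SD. Rhythmicity is
measured by the autocorrelation of the binned-median series. The
coefficient at lag k is the Pearson correlation between the series and its
k-lag shift over their overlapping span (each segment demeaned and scaled
by its own SD). This estimator was chosen over the global-demeaning,
shared-variance form because only the per-segment form guarantees that a
pure periodic series attains exactly 1 at its period and peaks *at* the
period — with global demeaning, the residual oscillatory term from
partial-period overlaps shifts a pure 24 h cosine's peak to 23.5 h on a
96-bin series. Lag 0 is 1 by construction, so the curve is normalized to
lag 0. Missing bins up to 20% are linearly interpolated; beyond that the
repeat is excluded with a logged reason. Lags are capped at 36 h to bound
variance (overlap never falls below 12 h of bins), and the reported
`peak_lag` is the argmax within an 18–30 h search band.

## Statistics

Pooled distributions are compared with Mood's median test (counts above vs
not-above the pooled median; ties count as not-above; chi-squared with K−1
df, no continuity correction — `scipy.stats.median_test(ties="below",
correction=False)` behind the module surface) with effect size χ²/N, which
is bounded by 1 for two groups. Headline comparisons collapse each
experimental repeat to its median and compare means of medians with an
equal-variance two-sample t-test (Welch by flag) and Cohen's d with pooled
SD (d = 0 when all medians are identical). Histogram bins follow Scott's
rule, h = 3.49·SD·n^(−1/3), bin count ⌈range/h⌉ spanning [min, max].

## The synthetic swimmer

The generator is an alternating renewal process that embodies the structure
the analysis assumes, so every stage can be validated against ground truth
without real recordings.

| parameter | default | meaning |
| --- | --- | --- |
| `frame_rate` | 166 Hz | acquisition rate |
| `drift_rate` ω | 3.3 °/s | nose-down pitch drift during IBIs |
| `drift_noise` | 0.3 °/√s | diffusion on the drift |
| `sink_rate` | 0.2 mm/s | passive sinking during IBIs |
| `gain` g | 0.86 | fraction of accrued drift corrected per bout |
| `rotation_noise` σ_r | 3.0 ° | SD of the rotation's stochastic part |
| dark `ibi_mean` / `fwhm_mean` | 1.615 s / 149.7 ms | long, infrequent bouts |
| light `ibi_mean` / `fwhm_mean` | 0.222 s / 71.8 ms | short, frequent bouts |
| `circadian_amplitude` A | 0 (presets: 0.18) | modulation of IBI/duration means |
| `circadian_period`/`phase` | 24 h / 4 h | peak at mid-circadian-night |

IBI gaps are Gamma-distributed with a circadian-modulated mean
`m(t) = m₀·(1 + A·cos(2π(t−phase)/period))`; bout durations are LogNormal
with the same modulation; peak speeds are LogNormal floored at 6 mm/s — a
"bout" below the 5 mm/s detection threshold is undetectable by definition,
and un-floored sub-threshold draws would silently fuse adjacent IBIs into
contaminated long IBIs. Each bout is a Gaussian speed pulse whose σ is
FWHM/(2√(2 ln 2)), so the drawn duration is analytically the pulse's FWHM;
positions integrate the pulse along a direction drawn per bout
(Normal(μ_φ, σ_φ) elevation; a persistent ±1 horizontal heading flipping
with probability 0.1 per bout). The bout's pitch change is
−g·(drift accrued since the previous bout's window end) + bias + ε applied
as a raised-cosine ramp across the window, so endpoint-difference rotation
recovers it exactly and small peak-detection jitter lands on the flat ends
of the ramp. Under LD the strategy set is re-evaluated at each bout's own
window start, so a light switch takes effect with no carry-over. Tracking
noise (0.005 mm on positions, 0.1° on pitch) is added after the dynamics.
Everything is bitwise deterministic given the seed.

Defaults were anchored to the day-time medians of multi-day recordings of
wild-type larvae: dark/light bout-duration medians 144.6/72.3 ms, IBI
medians 1.584/0.554 s (run-edge definition), IBI drift −4.27°, bout
rotations 7.5°/1.3°, compensation gain 0.86 with R² ≈ 0.57 for long
preceding IBIs.

**What passing tests do not show.** The generator omits: arena walls and
the finite field of view (real multi-bout sequences are selected toward
active crossings, which is why measured displacement-per-second rates on
synthetic data sit below published values — the path-rate ceiling implied
by bout displacement and IBI medians is lower than the printed rates);
between-bout direction correlation (real larvae hold headings across bouts,
so their between-bout directional change is far smaller than their overall
direction spread — with iid directions one σ_φ cannot match both);
asymmetric speed profiles (the Gaussian pulse is thinner than real bouts at
equal FWHM, so synthetic displacement medians run ~5–10% low); and
absolute-pitch homeostasis (rotation = −g·drift + bias makes absolute pitch
a random walk with drift; all analyses consume pitch *increments*, which
are stationary). Tests therefore validate the measurement and inference
machinery, not these aspects of real behavior.

## Problem sizes

Analytic identities use a 200 Hz grid, where −250 ms and +200 ms are whole
frames and the window identities are exact (at 166 Hz the discrete window
spans 445.8 ms). Oracle equivalences run 100 randomized small inputs per
operation. Gain recovery uses 4 h dark recordings (≈ 3300 long-IBI middle
bouts) per gain value; rhythm detection uses ten 48 h DD recordings per
amplitude condition; masking uses one 24 h LD recording; the median-test
calibration uses 2000 null simulations of 200 + 200 values. The
`scripts/acceptance.py` report uses a 6 h dark run, a 3 h light run, three
48 h circadian runs and four 4 h recovery runs.

## Known limitations

- The long/short IBI threshold pools dark IBIs across repeats; a per-repeat
  threshold is configurable but not the default.
- R² of the robust fit is the unweighted convention; a weight-aware R²
  would differ for heavily contaminated data.
- Sub-frame peak interpolation is not attempted; all event times are
  frame-quantized.
- The feeding-pause epoch break is supported but off by default in presets.
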