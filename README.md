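# boutlab

Bout-based kinematic analysis of larval zebrafish locomotion.

Larval zebrafish (*Danio rerio*) are front-heavy: between swim bouts they
passively rotate nose-down and sink, so posture must be re-stabilized by
swimming. `boutlab` is a pipeline for side-view pose recordings
(time, x, z, pitch at 166 Hz) that quantifies how larvae organize
locomotion into discrete bouts under different lighting and circadian
conditions:

- **segmentation** — swim speed from positions, bout detection by a 5 mm/s
  threshold, peak-aligned 450 ms windows (−250…+200 ms) and the inter-bout
  intervals (IBIs) between bouts;
- **kinematics** — per-bout peak speed, FWHM duration, displacement,
  trajectory direction and net pitch rotation; per-IBI duration and pitch
  drift;
- **compensation** — Tukey bi-square (robust IRLS) regression of bout
  rotation on preceding-IBI drift; the absolute slope is the *compensation
  gain* (1 = drift fully corrected), with case-resampled bootstrap p-values
  and MAD residual variability;
- **navigation** — displacement per second and directional change per
  second over sliding 5-bout windows, plus direction histograms;
- **circadian** — per-repeat binned medians and z-scores over a 48 h
  clock-anchored window, day/night summaries with transition-hour
  exclusion, and rhythm detection from lag-normalized autocorrelation
  (peak lag in an 18–30 h band);
- **stats** — Mood's median test with the χ²/N effect size, Scott's-rule
  binning, and repeat-median t-tests with Cohen's d;
- **simulate** — a generative swimmer (alternating renewal process with
  nose-down drift, gain-controlled compensatory rotations, circadian
  modulation and a light schedule) that produces ground-truthed synthetic
  recordings for every stage.

The core model: during an IBI of duration T the pitch drifts by roughly
−ωT (ω ≈ 3°/s nose-down); the next bout rotates the body by
Δθ ≈ −g·(accrued drift) + ε. Regressing measured rotations on measured
drifts with a bi-square fit recovers g robustly; in the dark, larvae show
g ≈ 0.86 after long IBIs. In the light they instead chain short, frequent,
direction-variable bouts — a navigation strategy that light *masks* onto
whatever the circadian clock is doing.

## Worked example

```python
import boutlab as bl

# 30 minutes of simulated dark-strategy swimming, ground truth included
params = bl.preset("dark_strategy", seed=7, duration_h=0.5)
tracks, meta, truth = bl.generate_recording(params)

bouts, ibis = bl.segment_recording(tracks, meta)
bdf = bl.bout_table(bouts, ibis)
idf = bl.ibi_table(ibis)
print(f"{len(bdf)} bouts, median duration "
      f"{bdf['duration_fwhm_ms'].median():.1f} ms, "
      f"median IBI {idf['duration_s'].median():.2f} s")

mid = bl.select_middle_bouts(bdf)
labels, thr = bl.classify_ibi(mid["prev_ibi_s"].to_numpy(),
                              idf["duration_s"].to_numpy())
sel = mid[labels == "long"]
fit = bl.fit_compensation(sel["prev_drift_deg"].to_numpy(),
                          sel["rotation_deg"].to_numpy())
print(f"long-IBI threshold {thr:.2f} s; compensation gain "
      f"{fit.gain:.3f} (R^2 = {fit.r_squared:.2f}, n = {fit.n})")
```

Output:

```
892 bouts, median duration 143.0 ms, median IBI 1.55 s
long-IBI threshold 1.55 s; compensation gain 0.846 (R^2 = 0.49, n = 443)
```

892 bouts were detected in 30 simulated minutes; their duration and IBI
medians sit where dark-adapted larvae sit. The robust fit of rotation
against preceding drift over the 443 long-IBI middle bouts recovers the
generator's programmed gain of 0.86 to within sampling error: each bout
undoes ~86% of the nose-down drift accrued since the previous bout.

There is also a CLI for shell use:

```sh
boutlab simulate rec.csv --preset ld_masking --seed 1 --duration 24
boutlab segment rec.csv --out bouts.csv --ibi-out ibis.csv
boutlab run-all config.yaml   # full pipeline from a YAML config
```

`run-all` writes bout/IBI/navigation/compensation/circadian CSVs, summary
tables, and a JSON manifest (config hash, seed, per-stage counts) that
suffices to reproduce any output.

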