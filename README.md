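# flyaim

Quantification of single-fly locomotion for dyskinesia phenotyping:
per-frame kinematics (speed, yawing, freezing) and a sliding-window
**AIM** (abnormal involuntary movement) score, together with a seeded
behavioural-state trajectory simulator so every stage of the pipeline is
testable without real tracking data.

## The problem

Levodopa-induced dyskinesia (LID) in fly models of Parkinson's disease
shows up in open-arena video tracking as slower walking, more freezing,
more yawing, and — most characteristically — abrupt single-frame
accelerations that coincide with large direction changes. Given a
tracker's per-frame output (centroid position and body heading, e.g. from
Ctrax: 5-minute recordings at 30.06 frames/s, 9018 frames), this package
turns each recording into a small set of interpretable numbers and
cohort-level statistics.

## The model

From a trajectory of *n* frames, the per-step quantities are the
displacement *dᵢ* between consecutive centroids, the instantaneous speed
*vᵢ = dᵢ · f* (frame rate *f*), and the signed wrapped heading change
*θᵢ*. The three locomotor parameters are the mean speed (mm/s), the
yawing metric (mean |θᵢ|, deg/frame), and the freezing fraction (share of
steps with *dᵢ ≤ ε*).

The AIM score compares each *vᵢ* with the mean speed *vₛ* of a centred
sliding window of *s* frames:

    vₛ(i) = (1/s) Σ_{j=i−(s−1)/2}^{i+(s−1)/2} vⱼ

    H = Σᵢ [ |log₁₀(vᵢ / vₛ)| > c ]

With the defaults *s* = 21 and *c* = 0.4, a frame counts when its speed
deviates from the local mean by more than a factor of 10^0.4 ≈ 2.5. Edge
frames without a full window are unscored; frames with (near-)zero *vᵢ*
or *vₛ* are skipped. Raw scores are reported relative to a control
cohort, whose mean normalizes to exactly 0.

## Worked example

```python
import numpy as np
from flyaim import AimParams, KinematicSeries, aim_raw

v = np.ones(200)                          # flat 1 mm/s record...
v[[30, 50, 70, 90, 110, 130, 150]] = 10.0 # ...with seven 10x bursts
res = aim_raw(KinematicSeries.from_speeds(v), AimParams(window_s=21, threshold_c=0.4))
print(res.raw_H, res.qualifying_frames.tolist())
```

prints

```
7 [30, 50, 70, 90, 110, 130, 150]
```

— exactly one count per burst frame and none for their neighbours: at a
burst, vᵢ/vₛ = 10/(30/21) = 7 so |log₁₀| = 0.85 > 0.4, while next to a
burst the ratio is 21/30 (|log₁₀| = 0.15).

The `analysis/` scripts run the full narrative on simulated cohorts
(`python analysis/01_simulate_cohorts.py` … `04_dose_response.py`),
writing tidy tables under `results/`. With the default generator the
dose-1 ("high L-DOPA") group shows a ~57% drop in mean speed and
~230%/~200% rises in freezing/yawing versus control, the mean raw AIM
score climbs monotonically from ~25 to ~189 across five dose levels, and
~99% of the generator's hidden ground-truth burst frames are caught by
the score. Spearman dose trends are |ρ| ≥ 0.97 at the permutation floor
p = 0.001.

A thin CLI covers the same pipeline from the shell:

```
flyaim simulate --out cohort/ --n-flies 6 --doses 0,0.5,1 --seed 7
flyaim score --manifest cohort/manifest.tsv --units mm --out per_fly.tsv
flyaim summarize --records per_fly.tsv --control 0.0 --out summary.tsv
```

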