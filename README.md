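# movemetrics

Objective quantification of seated classroom movement from multi-body
skeleton streams, for researchers studying hyperactivity — e.g. contrasting
children with an ADHD diagnosis against controls, or the same children with
and without medication — without attaching any sensor to the child.

A consumer depth camera (Kinect V2 class) tracks up to six bodies, each as a
25-joint skeleton with camera-space coordinates (x, y position, z distance
to the sensor, metres). `movemetrics` turns those raw, slot-unstable
detections into per-subject movement tables and runs the statistical battery
used in this literature:

1. **Tracking** — persistent identities 1–6 in order of first detection;
   when a body is lost and re-detected it is re-attached to the nearest
   remembered seat location (within a configurable radius). Short per-joint
   occlusions are repaired by linear interpolation; long gaps stay missing.
2. **Kinematics** — for each joint the 3-D path length per minute:
   `L_j(m) = Σ ‖p_{t+1} − p_t‖` over valid trajectory segments ending in
   minute *m*. Analysis restricts to 17 joints (hands, hand tips, thumbs and
   feet are unreliable for seated subjects; wrist and ankle stand in for
   them). A fully occluded minute is *missing*, never zero.
3. **Statistics** — per joint: Levene's variance test gating a pooled
   Student *t* vs Welch *t*; unsigned Cohen's
   `d = |M₁ − M₂| / s_pooled` with bands `<0.20` below threshold,
   `0.20–0.50` small, `0.51–0.80` moderate, `>0.80` large; ROC AUC as the
   normalized Mann–Whitney U (bands: 0.5 chance, 0.5–0.7 lower, 0.7–0.9
   moderate, >0.9 higher accuracy); and unweighted Cohen's κ for
   dual-observer behaviour counts ("squirm in seat" / "leave seat").
4. **Simulation** — a seeded generator of whole sessions (tethered random
   walks around seated rest poses, bursty intensity, occlusions, body
   dropouts) with closed-form calibration of the expected per-minute path
   length, so the entire pipeline is testable with known ground truth and
   programmed effect sizes.

## Worked example

Simulate two groups of 8 subjects (10-minute sessions, 30 Hz, programmed
effect size d = 0.8), run tracking → quantification → comparison, and write
the report tables:

```python
from movemetrics.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="out", simulate=True, n_per_group=8,
                effect_size_d=0.8, session_length=10, frame_rate=30.0,
                n_subjects=4, seed=42)
run_pipeline(cfg)
```

`out/comparison.tsv` then starts (one row per analysis joint):

```
joint        mean1    sd1     n1  mean2    sd2     n2  t        df      p           d         magnitude
spine_base   3.92547  2.03769 80  2.47463 1.36840  80  5.28685  138.211 4.7439e-07  0.835924  large
spine_mid    2.50473  1.30801 80  1.57994 0.878841 80  5.24902  138.252 5.6295e-07  0.829943  large
neck         3.61152  1.88416 80  2.27853 1.26120  80  5.25846  137.957 5.40741e-07 0.831436  large
```

Reading the first row: pooling the 80 minute-observations per group, the
simulated clinical group moved its spine base 3.93 m per minute on average
against 2.47 m for controls; Levene rejected homogeneity so a Welch *t* was
used (fractional df), and the standardized difference d ≈ 0.84 lands in the
"large" band — consistent with the programmed 0.8 at this small sample size.
`out/roc.tsv` reports the matching separation (e.g. spine base AUC 0.741,
"moderate" accuracy band), `out/minute_curves.tsv` holds the per-minute
group means behind the classic movement-average figures, and
`out/run_log.yaml` records every parameter and seed.

The same steps are available as a CLI:

```bash
movemetrics --seed 42 simulate --out-dir sess --n-subjects 4
movemetrics quantify --input sess/session.csv --session-length 30 --out mats/
movemetrics compare --group1 matsA/ --group2 matsB/ --out comparison.tsv
movemetrics kappa --counts observers.csv
```

File formats (documented in `movemetrics.io`) are plain text: long-format
CSV / JSON-lines for skeleton streams, TSV for movement matrices (empty
cell = missing minute).

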