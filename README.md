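# larvatrack

Multi-animal locomotion tracking for FTIR-style recordings of crawling
*Drosophila* larvae (and similar dark-background / bright-animal imagery),
plus a ground-truthed synthetic movie generator so the whole pipeline can be
developed and validated without an imaging rig.

Frustrated-total-internal-reflection (FTIR) imaging yields movies in which
the contact surface of each animal glows brightly on a large, nearly uniform
dark background. That image statistic makes a simple global analysis chain
viable, and this package implements it end to end:

1. **Illumination calibration** — image quality is scored on the grey-value
   histogram: Otsu's threshold *k* maximises the between-class variance
   σ²_B(k), and the separability η = σ²_B/σ²_T ∈ [0, 1] measures how well
   foreground and background split. The Weber contrast
   W_c = (μ₁ − μ₀)/μ₀ (foreground vs background mean luminance) is apt
   because background pixels dominate the frame. A simulated illumination
   sweep picks the light level maximising η, the software analogue of tuning
   an LED's PWM duty cycle.
2. **Segmentation** — global threshold, Moore border following into closed
   outer contours, hole filling, size filter.
3. **Midline geometry** — the spine is estimated from random interior
   points: each is joined to its nearest boundary point, the transversal
   chord midpoints are ordered and fitted with a least-squares smoothing
   spline whose ends are extended to the body tips. Seven equidistant
   landmarks (0–6) are placed by arc length: landmark 1 is the head,
   3 the centre, 5 the tail. The signed bending angle φ between the
   tail→mid and mid→head segments classifies head casts
   (none < 20° ≤ slight < 30° ≤ average < 50° ≤ strong). The head end is
   the spine end nearer the largest dark blob inside the body, with a
   movement-vector fallback.
4. **Tracking** — frame-to-frame assignment by contour overlap and centroid
   distance. When two animals' contours merge, their movement vectors v₁,
   v₂ between (t−2) and (t−1) translate the previous contours to
   hypothetical positions at t; uniquely covered pixels go to the owning
   animal and the rest are split by nearest neighbour, so identities
   survive moderate collisions. Merges of three or more animals are never
   resolved; affected frames carry a collision flag.
5. **Features** — per-landmark kinematics (distance, accumulated distance,
   distance to origin, velocity, acceleration), peristaltic contraction
   period and intensity from the body-area series, bending-event rates per
   side, and stop/go bout segmentation (windowed speed over t_window = 15
   frames above v = 10 px, |φ| < β = 20°, runs ≥ t_go = 7 frames).
6. **Analysis** — per-feature T×N tables (rows = time steps, columns =
   animals), classical (Torgerson) multidimensional scaling of animals into
   2D, discretised distributions and group summaries (median ± SD of area,
   bending angle, travel distance).

## Worked example

```python
import numpy as np
from larvatrack import (RunConfig, make_wander_scene, render_scene, track_movie,
                        compute_histogram, otsu_threshold, weber_contrast)
from larvatrack.features import contraction_metrics, stop_go_segmentation

spec = make_wander_scene(5, 300, body_length=40.0, seed=42)
frames, truth = render_scene(spec)

res = otsu_threshold(compute_histogram(frames[0]))
wc = weber_contrast(compute_histogram(frames[0]), res.k)
print(f"self-calibration: k = {res.k}, eta = {res.eta:.3f}, W_c = {wc.weber:.1f}")

ts = track_movie(frames, RunConfig(fps=10, seed=7))
print(f"{len(ts.tracks)} tracks, {len(ts.complete_tracks())} complete, "
      f"{len(ts.events)} collision events")

tr = ts.tracks[0]
area = np.array([tr.states[f].area for f in range(ts.n_frames)], float)
m = contraction_metrics(area, fps=10)
print(f"track 0: median area = {np.median(area):.0f} px^2, "
      f"contraction period = {m.period_s:.2f} s, intensity = {m.intensity:.3f}")

sg = stop_go_segmentation(ts)
print(f"go fraction = {sg.go.mean():.2f}")
```

prints

```
self-calibration: k = 97, eta = 0.933, W_c = 4.9
5 tracks, 5 complete, 0 collision events
track 0: median area = 224 px^2, contraction period = 0.70 s, intensity = 0.083
go fraction = 0.78
```

The threshold and η come from the first frame's bimodal histogram
(self-calibration); all five animals are followed without interruption; the
recovered contraction period matches the programmed 7-frame peristaltic
cycle at 10 fps; and the go fraction reflects the generator's randomised
stop/go schedule.

The same pipeline is available from the shell:

```sh
larvatrack simulate --n-larvae 5 --n-frames 300 --seed 42 --out movie/
larvatrack track    --movie movie/ --seed 7 --out tables/
larvatrack analyze  --tables tables/ --feature area --mds mds.csv
larvatrack overlay  --movie movie/ --seed 7 --out annotated/
```

## Layout

- `src/larvatrack/calibration.py` — histograms, Otsu statistics, Weber
  contrast, illumination sweep
- `src/larvatrack/segmentation.py` — thresholding, border following, size
  filter
- `src/larvatrack/geometry.py` — spine, landmarks, head detection, bending
  angle
- `src/larvatrack/tracking.py` — identity assignment and collision
  resolution
- `src/larvatrack/features.py` — kinematics, contraction, bending rate,
  stop/go
- `src/larvatrack/analysis.py` — feature matrices, classical MDS, group
  summaries
- `src/larvatrack/synthetic.py` — the ground-truthed movie generator
- `src/larvatrack/io.py`, `cli.py` — movie/table I/O, overlays, CLI
- `docs/methods.md` — the model, parameter and design notes
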