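# Methods

This note records the models, parameters and design choices behind
`larvatrack`, in the spirit of a package's statistical documentation: what
is computed, under which assumptions, and where the genuinely open choices
were made.

## Image model and calibration

The pipeline assumes 8-bit grey frames with a bright animal on a large,
nearly uniform dark background, a fixed camera and a constant frame rate.
Under that premise the grey-value histogram is strongly bimodal and a
single global threshold suffices for the whole movie.

For a normalised histogram p_i over L = 256 levels and a candidate
threshold k (background C₀ = {x ≤ k}, foreground C₁ = {x ≥ k+1}) the class
probabilities ω₀, ω₁, class means μ₀, μ₁ and the within/between/total
variances obey σ²_W(k) + σ²_B(k) = σ²_T for every k; the Otsu threshold
maximises σ²_B and the separability η = σ²_B/σ²_T ∈ [0, 1] scores image
quality. Ties in σ²_B (exact, across empty grey-level stretches between the
modes) are broken toward the smallest k, and the comparison carries a 1e-9
relative tolerance so floating-point noise cannot flip a tie. Weber
contrast W_c = (μ₁ − μ₀)/μ₀ is reported alongside because the dominant
background makes the average luminance approximate the background
luminance.

The illumination sweep evaluates a frame per candidate level, records
(p, k, η), and returns the smallest level attaining the maximal η
(preferring lower simulated power; degenerate single-level frames score
η = 0 so a sweep always completes). η is computed on the full frame; no
region of interest is used.

## Segmentation

Foreground is `pixel > k`. Connected components (8-connectivity) are traced
with Moore-neighbour border following (Jacob's stopping criterion) into
closed outer boundaries; internal holes are filled before measuring area
(the tracked quantity is whole-body area) and the centroid is the mean of
the filled pixels. The size filter keeps areas within 0.3×–3× of the
nominal body area 0.15·L² implied by the configured body length L — wide
enough for peristaltic area excursions and moderate merges of interest,
tight enough to reject speckle noise.

## Midline estimation

The spine is estimated from the contour alone, following the
random-interior-point scheme: 200 points are sampled uniformly inside the
3×3-eroded body mask (erosion depth and point count are engineering
defaults; both are configurable). Each point is joined to its nearest
boundary point b₁ and to the nearest boundary point on the opposite side
of the point (the first of its 48 nearest boundary points whose direction
has non-positive dot product with the direction to b₁); the midpoint of
that transversal chord samples the midline almost unbiasedly where the
body walls are locally parallel. Chords whose length falls outside
0.55×–1.8× of the median chord width are discarded — near the body tips a
chord connects an end cap to a side wall and its midpoint strays off the
midline.

Ordering of the midpoints (unspecified in the underlying scheme) is by
projection onto the first principal axis of the midpoint cloud, refined
once by arc position along a preliminary binned polyline; this prevents
zig-zag ordering on curved bodies. The ordered midpoints are averaged in
equal-count bins (~12 points per bin), fitted with a cubic smoothing
spline (residual budget 0.25 per bin mean, i.e. RMS ≈ 0.5 px), and the
outermost six spline samples — resting on sparse end bins — are trimmed.
Each end is then bridged straight to the body tip, defined as the mean of
the boundary points furthest along the outward tangent (within 1.5 px of
the extreme projection); averaging centres a flat end edge and lands on
the apex of a rounded cap. The result is resampled evenly in arc length
(100 points) and seven landmarks are placed at arc fractions i/6.

Degenerate inputs: a shape emptied by erosion raises "shape too thin"; a
near-circular shape (principal-axis aspect < 1.5) raises "degenerate
shape". Bodies whose tip-to-tip distance falls below a quarter of the arc
length (curled C/U postures) are flagged `shape_suspect` rather than
guessed. The estimator is deterministic given its seed.

Measured on the generator (100 larvae, straight and bent, 40/75/170-px
presets): mean midline error ≲ 0.9 px, end-to-end length within 5 %,
landmark arc spacings equal to well under 2 %.

## Head detection and orientation

The head is the biggest dark region inside the body: interior pixels (after
one 3×3 erosion, which removes the anti-aliased rim) more than 2 MADs —
with a floor of 2 grey levels on the MAD, so sensor-level noise cannot
produce spurious "dark" pixels — below the body median are grouped into
8-connected blobs. Blobs below max(3 px, 1 % of body area) are ignored;
if the two largest survivors are within a factor 1.2 in size the detection
abstains. The surviving blob's centroid assigns the nearer spine end as
the head. When detection abstains, orientation falls back to the centroid
movement vector over the last ≤ 5 frames (head = spine end with the larger
positive dot product; displacements ≤ 1 px keep the previous confident
orientation).

## Bending angle

φ is the signed angle at the body centre between tail→mid and mid→head
(landmarks 5, 3, 1 oriented head-first), in (−180°, 180°], positive when
the head deviates to the animal's left in image coordinates (row grows
downward). Head-cast classes on |φ|: none < 20° ≤ slight < 30° ≤ average
< 50° ≤ strong.

## Tracking and collision resolution

Assignment gates candidates at d_max = L/2 centroid distance (or any
contour overlap) and each live track picks the blob with the largest pixel
overlap with its previous body, ties by centroid distance. A blob claimed
by two tracks is a merge: the participants' movement vectors between
(t−2) and (t−1) translate their previous filled contours rigidly (no
rotation) to hypothetical positions at t; merged-blob pixels covered by
exactly one hypothesis belong to that animal, the remainder (doubly
covered or uncovered) go to the nearest already-claimed pixel. The
partition fails — and the event is marked unresolved with both tracks
suspended — when a piece falls below 50 % of its pre-collision area or the
piece area ratio drifts more than twofold from the pre-collision ratio.
Merges of ≥ 3 animals are always unresolved. Frames whose contours come
from a resolution carry `collision = True`.

A suspended track is revived by a blob within d_max of its last centroid
within 25 frames (an engineering default; the suspension horizon is not
prescribed anywhere), provided the blob's area is within 0.5×–1.5× of the
track's last area and the blob does not still cover the pre-collision
bodies of both participants of an unresolved event (which would mean the
merged blob has not split). Otherwise a new identity opens. When two fully
stacked animals render as one larva-sized blob, that blob is tracked under
one identity — the image genuinely shows one animal-sized object — and the
other identity is disrupted, matching the behaviour expected of
crawl-over events.

## Features

*Kinematics* — per-landmark step distances are Euclidean between
consecutive frames; accumulated distance is their running sum and does not
bridge suspension gaps (no invented path length); velocity = step × fps
(× mm/px when a scale is configured); acceleration is the first difference
of velocity. *Contraction* — peaks of the body-area series are detected on
a 3-frame moving mean with prominence ≥ 0.25 × the series MAD
(zero-crossing counting was rejected: area drift during turns would bias
it); the period is the mean peak interval over fps and the intensity is
the mean per-cycle (max − min) of the *raw* series (the smoothed copy
serves only to locate cycles, so the ~25 % amplitude attenuation of a
3-frame mean at a 7-frame period does not bias the excursion) normalised
by a reference area — by default the series median, standing in for the
relaxed-animal reference that a wet-lab protocol would supply. A constant
series has undefined period and zero intensity. *Bending rate* — an event
is a maximal run of frames with |φ| above threshold and constant sign;
counts are reported per side for thresholds 20°–90° (events, not frames,
are counted; per-frame series remain available in the tables).
*Stop/go* — at full frame rate, per-frame noise and true displacement are
of similar size, so speed is re-estimated as the centroid displacement
over t_window = 15 frames; a frame is go when that displacement exceeds
v = 10 px and |φ| < β = 20°; go runs shorter than t_go = 7 frames are
erased; stop is the logical not of go. Tracks shorter than the window are
entirely stop. Frames with undefined φ (spine failure, suspension) are
conservatively stop.

## Cohort analysis

Feature tables are T×N (rows = time steps, columns = animals). Embedding
uses classical (Torgerson) metric MDS on Euclidean distances between
animal columns: double-centre −½ J D² J, take the top-two spectral
coordinates. Classical MDS was chosen over iterative stress majorisation
because it is deterministic and reproducible without seeds; the full
eigenvalue spectrum is returned, a large negative tail flagging
non-Euclidean input. Features are not standardised before embedding; axis
signs are fixed so each axis's largest-magnitude coordinate is positive.
Group summaries reduce each animal to scalars first — median area, mean φ,
accumulated mid-landmark distance — then report the group median and SD of
each. Histogram bins are right-open [a, b) with the final bin closed.

## The synthetic arena

The generator emulates what an FTIR rig delivers, not its optics. A larva
is a midline anchored at the tail tip with local heading
θ(u) = heading + B(t)·g(u); the bend profile g ramps smoothly across the
"neck" (u ∈ [0.45, 0.75]) and holds at 1 toward the head, so head casts
are gentle swings rather than tight curls. Bend amplitudes B are
calibrated numerically (root finding on the rendered landmark geometry) so
a scheduled cast reaches its target φ exactly. The width profile is
constant mid-body and tapers within 12 % of either tip; a travelling wave
(phase span 0.25 wavelengths tail→head, i.e. posterior→anterior)
modulates it with an amplitude rescaled by the numerically computed
attenuation so that the projected area series oscillates with exactly the
programmed relative amplitude (default 4 %, period 7 frames at the default
10 fps). Bodies are rendered with a 1-px anti-aliased boundary band via a
distance transform to the dense midline; the ground-truth mask is the
≥ 50 % coverage set. A dark disc (default 50 % of the body contrast,
radius 0.8× the half-width) at arc position 0.84 near the head tip
provides the head blob. Noise is additive Gaussian (default SD 2),
clipped and quantised; there is no fixed-pattern noise or surface-scratch
model. Default scene conditions follow the recording protocol the package
targets: 10 fps, 40-px third-instar bodies (presets 25/40/75/170 px for
the four arena resolutions), speed 0.05·L per frame, go runs of 40–80
frames alternating with 16–30-frame pauses containing one 25–70° head
cast.

Multi-animal scenes either share the arena (rejection-sampled
non-overlapping placement) or confine each animal to its own grid cell
(`separate_cells`), which *guarantees* collision-free ground truth for
identity tests. Collision scenes are scripted: two parallel animals
approach laterally to a separation of (0.95 − 0.5·f)·width while
overlapping f·L longitudinally for a set duration, then part; f = 1 with
`crawl_over` stacks them almost fully. Everything derives from a single
seed; rendering is bit-reproducible.

The illumination-sweep source re-exposes one fixed scene with a
tent-shaped foreground gain peaking at the configured level. Two
quantisation/physics constraints shaped it: (i) the gain span keeps each
level step ≥ 1 grey level on both flanks, otherwise 8-bit rounding renders
neighbouring levels identically and blurs the η argmax; (ii) the gain
floor (40) keeps every level above the class-overlap regime — with a fixed
noise floor, Otsu's η is genuinely non-monotone in the contrast gap (a
noisy uniform frame scores η ≈ 0.63 from the tail split of a single
Gaussian, and a barely-separated unequal mixture dips below that), so a
sweep reaching gain 0 cannot have a unimodal η curve.

### What the generator does not model

Photorealistic FTIR physics, internal organs beyond the head blob,
body-shape deformation during contact (scripted collision bodies overlap
rigidly), fixed-pattern noise, illumination drift, and genuinely
behavioural trajectories (turning is a random walk with wall avoidance).
Consequently, passing tests demonstrate correctness of the measurement
chain under the stated image model — bimodal histograms, rigid-ish bodies,
moderate curvature — not performance on real recordings with soft-body
collision deformation or imaging artefacts.

## Validation problem sizes

The test suite and the acceptance script exercise: 200 random histograms
against an exhaustive threshold oracle; a full 255-level illumination
sweep; 100 single-frame larvae across the 40/75/170-px presets for midline
recovery; two 75-px animals over 400 frames for head orientation; fifteen
40-px animals over 900 frames (the package's standard screening group
size; 90 s at 10 fps) for identity preservation; nine scripted collision
scenes sweeping contact fractions 0.1–0.9 plus a 30-frame crawl-over; a
1800-frame programmed area oscillation; a 300-frame programmed stop/go
schedule; 200 noisy bend events; 15-point planar configurations and
two 55-animal cohorts (3 within-SD mean separation) for MDS; and a
3-animal, 150-frame end-to-end determinism run. These sizes are the
package's own validation choices and run comfortably on a single CPU.

## Known limitations

- Collision resolution translates rigid contours; long or deforming
  contacts degrade the partition and are deliberately left unresolved.
- Curled (C/U) postures are flagged, not resolved; φ is undefined there.
- The head-blob detector assumes the head is the *single* dominant dark
  region; two similar dark organs make it abstain (by design) and the
  motion fallback cannot orient a stationary animal that has never moved.
- Group summaries label "bending angle" as the per-animal mean φ; the
  per-track median is also derivable from the emitted tables since the
  convention is not universal.
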