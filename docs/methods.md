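# Methods

## The screening procedure

`metperim` implements binocular suprathreshold visual-field screening in
two paradigms that differ only in their test grid and stimulus size:

| | Esterman | modified Esterman (mET) |
|---|---|---|
| test locations | 120, weighted inferiorly | 160, evenly spread, symmetric about both axes |
| stimulus | Goldmann III (4 mm², 0.43°) | Goldmann V (64 mm², 1.72°) |
| level | 10 dB attenuation | 10 dB attenuation |
| presentation | each point up to twice | each point up to twice |

Pass 1 presents every location once in seeded-random order. Locations
missed on pass 1 are re-presented after pass 1 completes, in an
independently shuffled order; a location is a **defect** only if both
presentations are missed, **seen-on-retest** if the second presentation
is seen. Catch trials (presentations with no stimulus) are interleaved
at a rate of 1 per 10 scheduled presentations in each pass, at
seeded-random positions; a "seen" answer to a catch trial counts toward
the false-positive rate, and a run with a catch false-positive rate
above 20% is flagged unreliable. The retest-after-pass-1 schedule and
the 1-in-10 catch rate are design choices of this package (they avoid
local adaptation and give a usable false-positive estimate on a
160-presentation test); presentation timing is not modelled because the
responder is simulated — the responder contract reserves the hook point
a hardware driver would fill.

## Grids

Coordinates are degrees of visual angle, origin at fixation, x positive
toward the subject's right, y positive superior. The field boundary is
an axis-aligned ellipse with default semi-axes 85° horizontal and 60°
vertical (the superior semi-axis is capped at the 63° physiological
limit).

The **mET grid** is an offset rectangular lattice — points at
(±(i+½)s, ±(j+½)s) — clipped to the boundary ellipse, which makes it
closed under reflection in both axes and perfectly evenly spaced
(nearest-neighbour CV = 0). A deterministic scan of the spacing s over
[10°, 16°] in 0.05° steps shows that only s ∈ [10.0°, 10.1°] yields
exactly 160 points; the shipped fixture uses s = 10.0°, whose top row
sits at y = 55°. The fixture CSV is versioned in the package and tests
assert that regeneration reproduces it exactly.

The **Esterman grid** coordinates are not published in tabular form;
the shipped fixture (`esterman_grid_synthetic.csv`) is a synthetic
structural reconstruction satisfying the documented properties of the
layout: 120 points spanning 150° horizontally, exactly 2 points above
20° superior, 78 inferior vs 42 superior points, and density increasing
toward fixation and the inferior field. Analyses that depend only on
these structural properties (point counts, superior coverage, the
evenness contrast with the mET) transfer to the real layout; analyses
sensitive to individual point positions would not.

`strip_superior_rows` removes the top n rows of a grid (the rows most
affected by eyelid position); this deliberately breaks the x-axis
symmetry and is recorded in the grid metadata.

Goldmann stimulus geometry: a size-g stimulus has area 4^(g−3)·4 mm²;
a circle of area A at bowl radius R (default 300 mm) subtends
2·atan(√(A/π)/R), giving 1.72° for size V and 0.43° for size III.

## Simulated observers

A subject is a sensitivity surface plus response noise.

**Surface.** sensitivity(x, y) = max(0, peak − slope·ecc), default peak
30 dB and slope 0.1 dB/deg (a gentle normal hill of vision), minus the
deepest scotoma covering the location (depth ∞ = absolute scotoma),
with everything above an optional eyelid cut line masked to 0 dB.
Scotomata are rotationally defined: central discs, peripheral rings
(loss outside a preserved island), and wedge-limited sectors.

**Response.** P(seen) = fp + (1 − fp − fn)·Φ((sensitivity − level)/σ),
a cumulative-Gaussian frequency-of-seeing curve with default σ = 2 dB
and fp = fn = 0.03 — the smallest model that spans both deterministic
(σ → 0) and noisy regimes and is conventional in perimetry simulation.
Catch trials are answered "seen" with probability fp. All draws come
from a per-responder seeded stream.

**Phenotypes.** choroideremia → absolute peripheral ring outside a
preserved central island; Stargardt → absolute central scotoma. The
severity-to-radius calibration (island radius 45–58° mild, 25–40°
moderate, 5–15° severe; central scotoma 5–17° mild, 20–35° moderate,
40–60° severe, drawn uniformly per subject seed) was chosen so that the
radii are strictly ordered by severity, a severe rod-cone phenotype
always loses at least half the 160 mET locations, and a mild macular
phenotype stays within 20° eccentricity. These are internal-consistency
constants, not anatomical claims. The default cohort reproduces the
study composition: 19 choroideremia (6/8/5 mild/moderate/severe), 17
Stargardt (3/8/6), 26 controls — 62 subjects, with per-subject seeds
spawned from one master seed.

What the simulator does **not** model: fixation losses, reaction times,
learning and fatigue effects, media opacity, monocular-to-binocular
integration, and the spatially correlated, irregular scotoma borders of
real dystrophies. Passing tests therefore demonstrate correctness of
the algorithmic pipeline under a clean observer model, not clinical
performance on real patients.

## Field analysis and severity grading

The grid is tessellated with a Voronoi partition (scipy) clipped to the
boundary ellipse (shapely); a distant ghost-point ring bounds the outer
cells before clipping. Every field location then belongs to the cell of
its nearest test location, so no interpolation is involved. Two cells
are adjacent when their clipped polygons share an edge of positive
length; "clusters" of defects are connected components of the defect
set under this adjacency.

Grades, in precedence order (severe > moderate > mild):

* **severe** — ≥ 50% of locations missed;
* **moderate** — at least 2 clusters of ≥ 3 defects (and < 50% missed);
* **mild** — any other non-empty defect pattern ("a few scattered
  points"; left unquantified by the rule set, so mild is defined as the
  residual class, making the four classes exhaustive and exclusive);
* **normal** — no defects.

Test–retest pairs are graded on a per-location consensus map: a
location defective in exactly one of the two runs (mean indicator 0.5)
is counted defective — the conservative choice for safety monitoring.

Percent seen = 100 × (seen-first + seen-on-retest)/grid size; only
defects count as not seen.

`estimate_central_scotoma_radius` reports the midpoint between the
outermost defective eccentricity and the innermost seen eccentricity
beyond it, which for noise-free observers is within one grid spacing
(10° on the mET) of the true radius.

## Agreement statistics

* **Weighted kappa**: κ_w = 1 − Σw·p / Σw·e with disagreement weights
  |i−j|/(k−1) (linear, default) or squared (quadratic), expected
  proportions from marginal products. The 95% CI uses the large-sample
  Fleiss–Cohen–Everitt standard error; a seeded percentile bootstrap
  (2000 replicates) is available because either method may be
  appropriate on small cohorts. If both raters use a single category
  the chance-corrected statistic is undefined; the result is reported
  as κ = 1 with a degenerate CI and flagged.
* **Bland–Altman**: differences are Esterman − mET percent seen, so a
  positive bias means the mET records more loss. Pairs whose mean lies
  outside [20%, 80%] are excluded by default because scores saturate at
  the floor and ceiling; at least 2 in-band pairs are required (the
  limits of agreement need an SD).
* **Repeatability coefficient**: RC = 1.96·√2·s_w with
  s_w² = Σd²/(2n) for the two-replicate case; 95% of absolute
  test–retest differences are expected below RC.

## Numerical choices and degenerate inputs

* Voronoi rejects grids with < 4 points, duplicates, or collinear
  points; cell/boundary area agreement is asserted to 0.1% (the
  boundary ellipse is polygonised with 720 vertices).
* Probes used to validate the partition skip points within 1e-6° of a
  perpendicular bisector, where "nearest" is ambiguous.
* Consensus ties are defective (see above); cluster reports order
  largest-first with smallest-member tie-break for determinism.
* CSV writers use fixed `%.6g` floats, LF endings and sorted JSON keys,
  so outputs are byte-stable; log reading matches locations to grid
  points after rounding to 1e-4°.
* Seeds: every stochastic component (presentation order, catch
  positions, responder draws, phenotype radii, bootstrap) takes an
  explicit integer seed; derived per-subject seeds are reduced mod 2³¹.

## Problem sizes

The bundled analyses are sized for interactive use: single runs are
160–320 presentations; the synthetic cohort is the 62-subject default
(124 screening runs, well under a second); the direction-property
analysis uses a 100-subject choroideremia cohort; oracle validations
use 10⁴ Voronoi probes and 10³ random grade vectors.

## Known limitations

* The Esterman fixture is a structural reconstruction (see Grids);
  per-point comparisons with a hardware Esterman are out of scope.
* Suprathreshold screening yields presence/absence only — no defect
  depth, no Esterman functional disability score.
* The agreement statistics of the original patient study are not
  reproducible from simulation; the package instead verifies the
  qualitative direction (the mET records more loss than the Esterman in
  peripheral-loss phenotypes, driven by its superior/peripheral
  coverage).
* No GUI and no perimeter hardware driver; the responder contract is
  the integration point for one.
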