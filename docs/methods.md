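# Methods

This note records the models behind each analytical stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Film-coat hydration

The gel-layer change at grid point *n* is `(T_n − T_0)/T_n × 100`, i.e.
the change relative to the **current** hydrated thickness. This is a
deliberate departure from the conventional swelling ratio (which divides
by the initial thickness `T_0`); the current-thickness form is the
convention this framework is built around, and both are available via
`denominator="current" | "initial"`. The two agree to first order for
the sub-percent changes typical of thin film coats. The cumulative
metric is the running sum of per-interval terms `(T_i − T_0)/T_i`, kept
internally consistent with the same denominator convention.

Replicates (six by default) are averaged per time point before the
ratio; the replicate standard deviation is carried as metadata. The
default grid is 0–60 s in 4 s steps, matching the high-speed-camera
sampling of the bench protocol.

Plateau detection declares the curve settled at the earliest grid point
from which *all* successive gel-layer-change differences stay below the
tolerance; this is deliberately strict (a single late excursion above
tolerance postpones the plateau) because the plateau time feeds
qualitative statements, not the index.

Front extraction from calibrated frames uses a three-class Otsu split
(background / film annulus / dry core) and measures the front as the
difference of area-equivalent radii of the film+core and core regions
("radial" axis; widths along the centroid row/column are available as
alternatives). Area-equivalent radii are robust to boundary
pixelation: on noiseless rendered frames the recovered front is well
within one pixel. Frames with no segmentable boundary (blank, single
grey level) are excluded with a warning rather than failing the series.
Uncoated cores show no measurable swelling; the pipeline tests the
total thickness change against the replicate scatter (default 4
standard errors) and records GL = 0 throughout when it does not clear
it, which propagates SI = 0.

## Wettability

Droplets are modelled as spherical caps: `θ = 2·arctan(h/a)` from apex
height and contact half-width, curved cap area `π(a² + h²)`. The 10 µL
default drop volume is small enough that gravity flattening is ignored;
no Young–Laplace drop-shape solution is attempted. This is a model
limitation: for large drops or low surface tension the circle model
underestimates the true angle.

The image route detects the substrate baseline as the first image row
that is ≥ 90 % dark, extracts the droplet contour above it at sub-pixel
precision (marching squares at the mid-grey level), discards points
within 2 px of the baseline cut, and fits circles by Kåsa least
squares: one to the full contour (residual diagnostic) and one to each
half-contour. The reported angle is the mean of the left and right
tangent angles where the half-circles cross the baseline,
`θ = arccos(−y_c/R)`. Averaging the two sides and rejecting fits whose
sides disagree by more than 5° guards against tilted baselines and
asymmetric silhouettes; it stands in for the axial-thinning correction
applied to real recordings, whose exact algorithm is not specified.
Fits with RMS contour residual above 2 px are rejected as diagnostic
errors rather than silently reported. On rendered caps of ≥ 200 px
width the estimator recovers the true angle to well under 2° across
20°–140°. Angles ≤ 90° classify as hydrophilic (the boundary counts as
wetting), above 90° as hydrophobic. Angles are reported to two decimal
places.

## Incline-ramp friction

A tablet released from rest covering ramp length *L* in time *t* has
uniform acceleration `a = 2L/t²`. The Coulomb free body on the incline
gives `F_N = m·g·cosθ`, `F_F = m·(g·sinθ − a)` and
`µ = tanθ − a/(g·cosθ)`; mass cancels, which the tests assert across
0.1–1 g. Assumptions: start from rest at the gate, pure sliding (no
rolling), no fluid drag from the saliva film, g = 9.81 m/s²
(configurable). Defaults mirror the apparatus: 0.20 m ramp, 45°
inclination (the pharyngeal bolus angle), 1 mL/s irrigation recorded as
metadata. An acceleration above the frictionless limit `g·sinθ` is
physically inconsistent with gravity-driven sliding; such trials are
flagged with a warning and µ is clamped to 0 rather than reported
negative.

Friction readings published for rigs of this type are often normalised
into arbitrary units and can exceed `tan 45° = 1`, which no
gravity-driven slide can produce under this model; the module therefore
also provides `relative_cof`, expressing a formulation's mean µ against
a reference formulation measured on the same geometry, and makes no
claim to reproduce arbitrary-unit scales. Replicate summaries (n = 6 by
default) report mean ± sd (ddof = 1) of µ and of the transit
("mobility") time, and reject mixed ramp geometries.

## Shear adhesion

Traces are force vs extension at constant speed (defaults: 0.5 N normal
force, 300 mm/min, 50 mm range — the ASTM D1894 static/kinetic friction
protocol context). Segmentation: forces are smoothed with a centred
5-sample moving average (tensometer noise suppression; configurable);
movement onset is the first sample exceeding 5 % of the global maximum
and staying above it for 3 samples; the detachment peak is the earliest
global maximum (ties break to the earliest distance); the stress-drop
end (trough) is located where the smoothed force stops decreasing and
then refined to the first raw sample within twice the estimated noise
floor of the regional minimum — the refinement undoes the smoothing
lag, so on noiseless piecewise-linear spikes the trough lands exactly
on the breakpoint. Flat traces yield an empty peak region and a defined
degenerate behaviour for each metric.

Static friction coefficient = force at onset / normal force; dynamic =
mean sliding-region force / normal force. The work of adhesion
integrates the detachment spike by the composite trapezoidal rule
`Δx/2·[f(x₀) + 2f(x₁) + … + f(x_n)]` (N·mm = mJ), converted to joules
and divided by the contact area; non-uniform grids are first resampled
by degree-1 Lagrange (linear) interpolation onto a uniform grid. The
rule is exact on polylines sampled at their breakpoints and O(Δx²) on
smooth traces, both asserted by oracle tests. The default contact area
is a sledge of nine 13 mm flat-faced tablets, `9·π·6.5² ≈ 1194.6 mm²`;
the integration region defaults to the spike only (the detachment
event), with the full trace available for comparison, since published
protocols differ on the limits. Stick–slip events count local maxima
followed by a drop of at least 30 % of the global maximum before the
next rise — smooth coated traces give 0–1 events, uncoated sawtooths
one per tooth.

## The index and its bands

`SI = 1000·GL/(CA · W_a · 10F · CoF)`, read as a single numerator over
the product of the four resistance factors with `10F` meaning `10 × F`;
this grouping makes GL = 0 give exactly SI = 0 (the uncoated row) and
produces band-scale values for realistic factor magnitudes. GL entering
the index is the gel-layer change at the matching transit time on the
4–20 s grid. Band edges are half-open — Poor {0}, Pass (0,1), Good
[1,2), Very Good [2,4), Excellent [4,∞) — so every non-negative index
has exactly one rank; the half-open choice resolves edge values (1, 2)
that a strict-inequality reading would leave unassigned. SI is rounded
to two decimals only at presentation; full precision is kept
internally, and matrix CSV serialisation uses shortest-repr floats so a
round trip is bit-identical.

Row ordering: `rank_formulations` sorts ascending by the SI at a chosen
transit-time column (ties alphabetical). The bundled reference matrix's
published "presentational performance" row order corresponds to
ascending **row-mean** SI across the 4–20 s columns, not to any single
column, so `time_s=None` ranks by the row mean and reproduces that
order exactly.

The work-of-adhesion magnitudes of the bundled reference panel are on a
scale consistent with J/m² rather than the J/mm² label they carry (a
10⁶ discrepancy no physical contact area reconciles). The pipeline
therefore feeds W_a into the index in J/m² (`wa_index_scale = 1e6`,
configurable), which keeps synthetic-study indices inside the
interpretable 0–10 band range; rankings are unaffected by this common
factor, and the reference W_a values themselves are never recomputed.

## Synthetic data: what it emulates and what it does not

Generators are deterministic under a fixed seed (bit-identical
regeneration) and each retains its ground truth, so every estimator is
validated by round trip: exactly (to round-off) without noise, and with
1/√n-shrinking error under noise.

- Thickness: percent curves `P·(1 − e^{−kt})`, optionally hard-clamped
  at a saturation time, inverted through the current-denominator
  formula into thickness; additive Gaussian noise per replicate
  (defaults: T₀ = 300 µm, 0.1 µm noise — a relative precision of
  ~3×10⁻⁴, what resolving sub-percent swelling requires).
- Droplets: anti-aliased cap silhouettes over a dark baseline with
  exact angle; optional intensity noise.
- Ramp: `t = √(2L/(g(sinθ − µcosθ)))` with multiplicative log-normal
  jitter (2 % default — times are strictly positive, hence not
  Gaussian).
- Traces: linear rise (optionally from a step onset force) to the peak,
  linear stress drop to a sliding plateau, additive Gaussian noise
  (0.005 N default, a 10 N load cell at ~0.05 % of range); uncoated
  mode builds a sawtooth with a requested number of large drops. The
  default 1001-point grid over 50 mm places samples exactly on the
  spike breakpoints, so noiseless trapezoidal recovery is exact.

The presets for the eleven-formulation reference panel anchor contact
angles to the bundled reference table and preserve the published
friction rank order after rescaling into the gravity-consistent range
(µ = reported/2.75 < tan 45°); gel-layer plateaus, rates and force
levels are plausible illustrative choices. What the generators do
**not** emulate: polymer dissolution physics (Fickian/case-II
transport), tribo-rheology of the saliva film, image artefacts
(reflections, meniscus shadows, tilt), load-cell drift, or correlated
replicate errors. Passing recovery tests therefore demonstrates that
the estimators invert the assumed signal models at instrument-scale
noise — not that those models capture every behaviour of real
recordings.

The end-to-end synthetic study runs all eleven presets through the full
file-based pipeline (11 formulations × 6 replicates/trials per stage,
three droplet frames each at 160 px base width — sizes chosen to keep
the whole study under a second while leaving every estimator inside its
validated regime). Its index magnitudes depend on the W_a scale
convention above; its ranking and the uncoated-row zeros do not.

## Degenerate inputs and error policy

Invalid physical inputs (non-positive thicknesses, zero transit times,
angles outside [0°, 180°], non-positive denominator factors with
GL > 0) raise `ValueError` at construction or call. Measurement-stage
failures raise typed errors (`SegmentationError`, `NoDropletError`,
`NoBaselineError`, `FitQualityError`) that the pipeline catches per
formulation: a failed stage leaves that formulation's affected cells
missing without aborting the others, while absent input files are
recorded as missing rather than failures. The CLI exits 0/1/2 for
success / partial / invalid input.

## Known limitations

- The circle-fit contact angle ignores gravitational flattening and
  contact-angle hysteresis; no pendant-drop surface tension.
- The incline model omits lubrication-film hydrodynamics and
  chamber-climate effects (37 ± 2 °C, 65 % RH are metadata only).
- W_a's normalising area and integration limits are conventions, not
  measurements; absolute W_a values are comparable only within a fixed
  convention.
- The index is an in vitro preformulation ranking; no in vivo
  predictive validity is claimed.
- Descriptive statistics only (means ± sd); no hypothesis testing is
  built in.
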