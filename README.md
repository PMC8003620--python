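# swallowmetrics

In vitro swallowability analytics for film-coated tablets.

Swallowing difficulties affect a large share of elderly and paediatric
patients, and the ease with which a solid oral dosage form glides through
the mouth is governed by a handful of measurable surface-physics
quantities. `swallowmetrics` turns raw instrument-style measurements from
a bench-top swallowability rig — film-thickness time series, sessile-drop
images, incline-ramp transit times and friction-sledge force–distance
traces — into those quantities and combines them into a single
*swallowability index* with a colour-banded ranking matrix. It is aimed
at formulation scientists screening tablet film-coat candidates
(e.g. PVA, HPMC, PVA–PEG graft copolymer, HPMC–guar blends,
gelatin/λ-carrageenan systems) before any panel or in vivo work.

## The five critical factors and the index

| symbol | quantity | how it is measured |
|---|---|---|
| GL | axial gel-layer thickness change (%) | `(T_n − T_0)/T_n × 100` from replicated thickness series or calibrated frames |
| CA | apparent contact angle (°) | spherical-cap geometry `θ = 2·arctan(h/a)`, or a least-squares circle fit to a sessile-drop silhouette |
| CoF | coefficient of sliding friction | Coulomb model on a wetted incline: `µ = tanθ − a/(g·cosθ)` with `a = 2L/t²` from the transit time |
| F | peak detachment force (N) | maximum of the initial spike of a force–distance trace |
| W_a | work of adhesion (J/mm²) | composite trapezoidal area under the detachment spike, per contact area |

These combine into

```
SI = 1000·GL / (CA · W_a · 10F · CoF)
```

with five ordered rank bands: SI = 0 **Poor**, 0–1 **Pass**, 1–2 **Good**,
2–4 **Very Good**, ≥ 4 **Excellent**. A surface that hydrates quickly
(large GL) while wetting easily and sticking/rubbing little (small CA,
W_a, F, CoF) scores high. Contact angles at or below 90° classify the
surface as hydrophilic.

A synthetic-data module generates instrument-style inputs with exactly
known ground truth for every stage (saturating swelling curves, rendered
droplet caps, closed-form ramp times, spike-plus-plateau and stick–slip
force traces), so each estimator can be validated by parameter recovery.

## Worked example

Estimate a sliding-friction coefficient from one ramp run (0.20 m ramp
at 45°, transit in 0.5 s), then score a formulation:

```python
>>> from swallowmetrics import (RampTrial, coefficient_of_friction,
...                             swallowability_index, classify_si)
>>> coefficient_of_friction(RampTrial(transit_time_s=0.5)).mu
0.7693433537413912
>>> si = swallowability_index(GL=1.0, CA=100.0, Wa=1.0, F=0.1, CoF=1.0)
>>> si, classify_si(si).label
(10.0, 'Excellent')
```

The tablet accelerated at `2L/t² = 1.6 m/s²`, well below the
frictionless limit `g·sin45° ≈ 6.94 m/s²`, giving µ ≈ 0.77; the index
example shows a fast-hydrating, low-adhesion coat landing in the
Excellent band.

The same works from the shell on generated data:

```sh
$ swallowmetrics synth trace --seed 1 --preset OEZ --out demo
$ swallowmetrics adhesion --trace demo/OEZ_trace.csv
peak_force_N: 0.1800 at 5.00 mm
work_of_adhesion_J_mm2: 3.515849e-07
mu_static: 0.2800
mu_dynamic: 0.1200
stick_slip_events: 1
```

The trace's detachment spike peaks at 0.18 N at 5 mm extension; the
static (onset) and dynamic (sliding-plateau) friction ratios follow
from the 0.5 N normal force, and the smooth coated trace shows at most
one large stress drop (an uncoated tablet's stick–slip sawtooth would
show many).

A complete synthetic study — eleven formulations through all four
stages into the ranked matrix — runs with:

```sh
$ swallowmetrics synth study --seed 1 --out demo
$ swallowmetrics run --manifest demo/manifest.json --out-dir demo_out
wrote matrix.csv, report.html, records.json to demo_out
```

`matrix.csv` holds the SI per formulation and in-vitro oral transit
time (4–20 s); the uncoated control row is identically 0 (Poor) because
it shows no measurable swelling, and `report.html` renders the
red-to-dark-green band colours.

## Layout

- `src/swallowmetrics/hydration.py` — gel-layer percent metrics, plateau detection, front extraction from frames
- `src/swallowmetrics/wettability.py` — cap geometry, image-based contact angles, wetting classification
- `src/swallowmetrics/ramp_friction.py` — incline free-body chain, trial summaries, relative CoF
- `src/swallowmetrics/shear_adhesion.py` — trace segmentation, friction ratios, trapezoidal work of adhesion, stick–slip counting
- `src/swallowmetrics/swallowability.py` — the index, rank bands, matrix assembly and ordering
- `src/swallowmetrics/synthetic.py` — ground-truth generators and the eleven-formulation presets
- `src/swallowmetrics/pipeline.py`, `cli.py`, `io.py` — study driver, command line, file formats
- `docs/methods.md` — models, assumptions, parameter choices and limitations
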