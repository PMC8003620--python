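"""Bundled reference dataset: the eleven-formulation tablet-coating panel.

Summary measurements for a panel of film-coating formulations evaluated
on the in vitro swallowability bench: an uncoated control, four
commercial film formers (PVA, HPMC, Kollicoat IR "KIR", Opadry EZ
"OEZ") and binary/ternary gelatin / λ-carrageenan blends on a Kollicoat
IR base ("Ge"/"C" with % w/w solid inclusion).

The tables hold *reported summary values* (means of replicated
instrument readings), not raw traces; they serve as fixtures for the
classification, ranking and worked-example computations.  Work-of-
adhesion values are on a relative J/mm² scale and coefficient-of-
friction values in rig-normalised arbitrary units; neither is
recomputed by this package from first inputs.
"""

from __future__ import annotations

__all__ = [
    "FORMULATIONS",
    "CONTACT_ANGLES_DEG",
    "SI_MATRIX",
    "SI_COMPLEXITY_ORDER",
    "SI_PERFORMANCE_ORDER",
    "WORK_OF_ADHESION_J_MM2",
    "COF_AU",
    "KIR_ANGLE_20S_TEXT",
]

#: Panel formulation ids, in increasing coating-recipe complexity.
FORMULATIONS = (
    "Unc", "PVA", "HPMC", "KIR", "OEZ",
    "C1", "C3", "Ge1", "Ge3", "Ge3C1", "Ge3C3",
)

#: Apparent contact angles (deg): {formulation: {time_s: (mean, std)}}.
#: Time 0 is the immediate stable-droplet reading; n = 3.  The uncoated
#: core disintegrates before a stable droplet forms, recorded as 0.
CONTACT_ANGLES_DEG = {
    "Unc":    {0: (0.0, 0.0),     10: (0.0, 0.0),     20: (0.0, 0.0)},
    "KIR":    {0: (97.17, 1.46),  10: (89.92, 1.59),  20: (83.32, 1.33)},
    "OEZ":    {0: (91.64, 1.83),  10: (87.43, 1.34),  20: (81.03, 1.37)},
    "PVA":    {0: (96.24, 1.46),  10: (90.53, 1.49),  20: (88.62, 1.23)},
    "HPMC":   {0: (94.28, 1.21),  10: (89.24, 1.36),  20: (86.13, 1.16)},
    "C1":     {0: (93.06, 1.92),  10: (88.73, 1.21),  20: (75.77, 1.31)},
    "C3":     {0: (88.67, 1.24),  10: (81.97, 1.25),  20: (73.03, 1.83)},
    "Ge1":    {0: (98.37, 1.37),  10: (93.07, 1.15),  20: (80.87, 1.31)},
    "Ge3":    {0: (104.17, 1.55), 10: (91.17, 1.04),  20: (82.87, 1.82)},
    "Ge3C1":  {0: (93.23, 1.53),  10: (86.07, 1.54),  20: (76.33, 1.22)},
    "Ge3C3":  {0: (89.57, 1.64),  10: (81.87, 1.42),  20: (71.08, 1.36)},
}

#: KIR's 20 s contact angle as quoted in the running-text comparison
#: (differs slightly from the tabulated 83.32°; both are retained).
KIR_ANGLE_20S_TEXT = 84.3

#: Reported swallowability index per formulation and in-vitro oral
#: transit time (s): {formulation: {time_s: SI}} (55 cells).
SI_MATRIX = {
    "Unc":    {4: 0.00, 8: 0.00, 12: 0.00, 16: 0.00, 20: 0.00},
    "PVA":    {4: 0.11, 8: 0.17, 12: 0.37, 16: 0.54, 20: 0.82},
    "HPMC":   {4: 0.23, 8: 0.76, 12: 1.05, 16: 1.35, 20: 1.86},
    "KIR":    {4: 0.14, 8: 0.61, 12: 0.82, 16: 1.10, 20: 1.83},
    "OEZ":    {4: 1.19, 8: 4.82, 12: 5.42, 16: 6.78, 20: 7.99},
    "C1":     {4: 0.51, 8: 1.19, 12: 3.46, 16: 6.20, 20: 6.64},
    "C3":     {4: 0.60, 8: 1.40, 12: 4.49, 16: 6.18, 20: 7.41},
    "Ge1":    {4: 0.36, 8: 1.56, 12: 2.61, 16: 3.97, 20: 6.10},
    "Ge3":    {4: 0.29, 8: 1.41, 12: 2.22, 16: 3.19, 20: 4.36},
    "Ge3C1":  {4: 1.46, 8: 2.78, 12: 5.49, 16: 6.77, 20: 7.87},
    "Ge3C3":  {4: 1.42, 8: 2.34, 12: 5.65, 16: 6.93, 20: 9.47},
}

#: Matrix row order by increasing coating-recipe complexity.
SI_COMPLEXITY_ORDER = (
    "Unc", "PVA", "HPMC", "KIR", "OEZ",
    "C1", "C3", "Ge1", "Ge3", "Ge3C1", "Ge3C3",
)

#: Matrix row order by sequential presentational performance
#: (ascending overall swallowability).
SI_PERFORMANCE_ORDER = (
    "Unc", "PVA", "KIR", "HPMC", "Ge3", "Ge1",
    "C1", "C3", "Ge3C1", "Ge3C3", "OEZ",
)

#: Reported work of adhesion (relative J/mm²) per (formulation, substrate).
WORK_OF_ADHESION_J_MM2 = {
    ("Unc", "sodium_polyacrylate"): 8.95,
    ("Unc", "ptfe"): 1.99,
    ("OEZ", "ptfe"): 1.28,
    ("Ge3C1", "ptfe"): 2.19,
    ("KIR", "ptfe"): 3.72,
    ("HPMC", "ptfe"): 3.52,
    ("KIR", "sodium_polyacrylate"): 4.06,
    ("HPMC", "sodium_polyacrylate"): 4.25,
}

#: Reported coefficient-of-friction readings, rig-normalised a.u.
COF_AU = {
    "OEZ": 1.53,
    "Ge3C1": 1.54,
    "Ge3": 1.54,
    "Ge3C3": 1.57,
    "Ge1": 1.58,
    "KIR": 1.59,
}
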