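"""Reference values from the published global land-degradation assessment.

These are the printed inputs the package's reproduction checks run
against: year-2000 rural population columns (millions) by region on
degrading (DAL) and improving (IAL) agricultural land, descriptive
moments of the 83-country poverty panel, and the 3SLS system parameters
with their evaluation points. Populations and coefficients are data
inputs here; everything derived from them (shares, totals, impact
schedules) is recomputed by the package at run time.
"""

from __future__ import annotations

#: region -> (rural_pop, pop_DAL, pop_remote_DAL, pop_IAL, pop_remote_IAL),
#: millions of persons in 2000.
REGION_POPULATIONS_2000_M = {
    "EAP": (1398.4, 710.3, 125.2, 398.7, 67.9),
    "ECA": (173.8, 67.0, 6.2, 66.7, 6.6),
    "LAC": (294.1, 38.3, 5.6, 90.6, 9.3),
    "MENA": (195.6, 43.7, 5.4, 28.1, 1.7),
    "SA": (1090.4, 285.2, 27.4, 641.8, 37.3),
    "SSA": (554.6, 114.1, 32.4, 114.8, 32.5),
    "DEV": (404.7, 72.6, 3.2, 196.4, 9.0),
}

#: printed share cells (%) for spot checks: (region, column) -> percent
PRINTED_SHARES = {
    ("EAP", "d1"): 50.8,
    ("LAC", "d2"): 1.9,
    ("Developing", "i1"): 36.2,
}

#: printed aggregate rows (same column order as the regional rows); the
#: developing row is printed from unrounded data, so it differs from the
#: sum of the rounded regional cells by up to 0.1 M
AGGREGATE_ROWS_2000_M = {
    "Developing": (3706.8, 1258.7, 202.2, 1340.7, 155.3),
    "Developed": (404.7, 72.6, 3.2, 196.4, 9.0),
}

#: printed world totals, millions: developing + developed components
WORLD_DAL_COMPONENTS_M = (1258.7, 72.6)   # -> 1331.3 (1.33 billion)
WORLD_IAL_COMPONENTS_M = (1340.7, 196.4)  # -> 1537.1 (1.54 billion)

#: descriptive moments of the 83-country panel: variable -> (mean, median, sd)
PANEL_MOMENTS = {
    "H0": (46.41, 42.85, 29.56),
    "gamma_H": (-7.70, -4.26, 10.28),
    "gamma_mu": (3.36, 3.32, 3.52),
    "d1": (27.11, 22.44, 21.04),
    "d2": (5.02, 3.81, 4.43),
    "i1": (31.89, 29.60, 21.05),
    "i2": (13.45, 5.21, 18.83),
}

#: sample-mean annual income growth (%/yr) at which impacts are evaluated
MEAN_INCOME_GROWTH = 3.36

#: 3SLS parameters per share variable: column -> (beta1, delta1)
SYSTEM_PARAMETERS = {
    "d1": {"no_controls": (-2.15, 0.54), "controls": (-2.51, 0.58)},
    "d2": {"no_controls": (-2.31, 0.52), "controls": (-2.91, 0.57)},
    "i1": {"no_controls": (-2.36, 0.34), "controls": (-2.92, 0.37)},
    "i2": {"no_controls": (-2.30, 0.38), "controls": (-2.86, 0.41)},
}

#: impact cells (%/yr) that reproduce exactly from the printed-rounded
#: no-controls parameters, (share, evaluation point) -> printed value.
#: The with-controls cells were evidently computed from unrounded
#: parameter estimates and cannot be matched at 0.005 from the table.
PRINTED_IMPACT_CELLS = {
    ("d1", "low"): -3.66,
    ("d1", "mean"): -2.84,
    ("d1", "high"): -2.02,
    ("i2", "low"): -3.05,
    ("i2", "mean"): -3.33,
}

#: all-IAL impact magnitudes quoted in the published prose at one decimal,
#: (column, evaluation point) -> %/yr.
PROSE_IAL_IMPACTS = {
    ("no_controls", "low"): -3.0,
    ("no_controls", "mean"): -3.6,
    ("no_controls", "high"): -4.1,
    ("controls", "low"): -4.0,
    ("controls", "mean"): -4.8,
    ("controls", "high"): -5.6,
}

#: printed evaluation-point row labels (%) per share variable
PRINTED_EVALUATION_POINTS = {
    "d1": (6.1, 27.1, 48.2),
    "d2": (0.6, 5.0, 9.5),
    "i1": (10.8, 31.9, 52.9),
    "i2": (4.0, 13.5, 22.9),
}
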