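"""Published per-diet genetic parameter estimates for *Narnia femorata*.

These are the reported trait means, additive genetic variances (V_A),
phenotypic variances (V_P), CV_A, heritabilities with standard errors,
and evolvabilities (I_A) for body dry mass, femur area and testis dry
mass of male leaf-footed cactus bugs reared on cactus with ripe fruit,
unripe fruit, or without fruit.  The raw data behind them were never
deposited, so the table serves as a worked example: the arithmetic links
between its cells (h2 = V_A/V_P, I_A = V_A/mean^2) can be recomputed and
checked with this package, while the variance components themselves
cannot be re-estimated.

Two documented quirks, preserved as printed:

* the CV_A rows equal ``V_A/mean`` rather than the stated
  ``sqrt(V_A)/mean`` in every cell, so both variants are computed
  throughout this package;
* for testis mass without fruit the printed h2 (0.11) disagrees at the
  second decimal with V_A/V_P = 0.26/2.49 (0.10), presumably from input
  rounding, and that cell is therefore excluded from consistency checks;
* the testis-mass variance rows are on a scale incompatible with the
  milligram means (an unstated unit rescaling); ratios are used as
  printed.
"""

from __future__ import annotations

import pandas as pd

ENVIRONMENTS = ("ripe", "unripe", "none")

#: published estimates, keyed (trait, environment)
PUBLISHED = {
    # trait            env       mean    V_A    V_P    CV_A   h2    SE_h2  I_A
    ("body_mass_mg", "ripe"):   dict(mean=23.51, V_A=36.53, V_P=90.68, CV_A=1.56, h2=0.40, SE_h2=0.13, I_A=0.07),
    ("body_mass_mg", "unripe"): dict(mean=12.96, V_A=0.97, V_P=15.87, CV_A=0.07, h2=0.06, SE_h2=0.11, I_A=0.01),
    ("body_mass_mg", "none"):   dict(mean=12.29, V_A=1.51, V_P=20.63, CV_A=0.12, h2=0.07, SE_h2=0.07, I_A=0.01),
    ("femur_area_mm2", "ripe"):   dict(mean=7.14, V_A=0.41, V_P=3.09, CV_A=0.06, h2=0.13, SE_h2=0.11, I_A=0.01),
    ("femur_area_mm2", "unripe"): dict(mean=6.17, V_A=0.0, V_P=1.78, CV_A=0.00, h2=0.00, SE_h2=0.00, I_A=0.00),
    ("femur_area_mm2", "none"):   dict(mean=4.86, V_A=0.26, V_P=2.12, CV_A=0.05, h2=0.12, SE_h2=0.08, I_A=0.01),
    ("testis_mass_mg", "ripe"):   dict(mean=0.20, V_A=1.08, V_P=5.08, CV_A=5.40, h2=0.21, SE_h2=0.11, I_A=27.00),
    ("testis_mass_mg", "unripe"): dict(mean=0.13, V_A=0.16, V_P=1.79, CV_A=1.23, h2=0.09, SE_h2=0.12, I_A=9.50),
    ("testis_mass_mg", "none"):   dict(mean=0.13, V_A=0.26, V_P=2.49, CV_A=2.0, h2=0.11, SE_h2=0.07, I_A=15.40),
}

#: cells excluded from h2 = V_A/V_P consistency checks (input rounding)
INCONSISTENT_H2_CELLS = (("testis_mass_mg", "none"),)


def published_table() -> pd.DataFrame:
    """The published estimates as a tidy DataFrame."""
    rows = []
    for (trait, env), vals in PUBLISHED.items():
        rows.append({"trait": trait, "environment": env, **vals})
    return pd.DataFrame(rows)


def recompute_worked_example() -> pd.DataFrame:
    """Recompute h2 and I_A from the published (mean, V_A, V_P) cells.

    Returns the published table augmented with ``h2_recomputed`` (=
    V_A/V_P) and ``I_A_recomputed`` (= V_A/mean^2), which should agree
    with the printed values at two decimals everywhere except the
    documented inconsistent testis cell.
    """
    tab = published_table()
    tab["h2_recomputed"] = tab["V_A"] / tab["V_P"]
    tab["I_A_recomputed"] = tab["V_A"] / tab["mean"] ** 2
    tab["CVA_printed_recomputed"] = tab["V_A"] / tab["mean"]
    return tab
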