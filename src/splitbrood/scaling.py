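"""Trait expression and allometry across developmental environments.

This stage mirrors the phenotypic analyses of the diet study: each trait
is log-transformed, compared across the three rearing environments by a
one-way ANOVA with Tukey's HSD post hoc test, and the scaling
relationships among traits (femur ~ body, testis ~ body, testis ~ femur)
are compared across environments by ANCOVA.  The environment x covariate
interaction is screened at P = 0.20: when its p-value exceeds the
threshold it is removed and a common-slope model is reported.

Unbalanced designs use the Tukey-Kramer adjustment; pairwise tail
probabilities come from the studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm


def log_transform(values) -> np.ndarray:
    """Natural logarithm of strictly positive trait values.

    Raises ``ValueError`` listing the offending positions if any value is
    zero, negative or non-finite.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        shown = bad[:10].tolist()
        raise ValueError(
            f"{bad.size} non-positive value(s) cannot be log-transformed "
            f"(positions {shown}{'...' if bad.size > 10 else ''})"
        )
    return np.log(arr)


# ---------------------------------------------------------------------------
# One-way ANOVA with Tukey-Kramer HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    group_means: pd.Series
    group_sizes: pd.Series
    tukey: pd.DataFrame          # pairwise: group1, group2, diff, q, p, reject
    tukey_letters: dict          # compact letter display
    alpha: float = 0.05


def one_way_anova_tukey(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA with Tukey(-Kramer) pairwise comparisons.

    Requires at least two groups, each with at least two observations.
    The compact letter display assigns shared letters to groups whose
    difference is not significant at ``alpha``.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(groups).astype(str).reset_index(drop=True)
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups for an ANOVA")
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than two observations: {list(small.index)}")

    levels = sorted(sizes.index)
    k = len(levels)
    n = len(y)
    means = pd.Series({lev: y[g == lev].mean() for lev in levels})
    ns = pd.Series({lev: int((g == lev).sum()) for lev in levels})
    grand = y.mean()
    ss_between = float(sum(ns[lev] * (means[lev] - grand) ** 2 for lev in levels))
    ss_within = float(sum(((y[g == lev] - means[lev]) ** 2).sum() for lev in levels))
    df_num, df_den = k - 1, n - k
    mse = ss_within / df_den
    if mse == 0.0:
        F = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = (ss_between / df_num) / mse
        p = float(stats.f.sf(F, df_num, df_den))

    rows = []
    for a, b in combinations(levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))  # Tukey-Kramer
        if se == 0.0:
            q = 0.0 if diff == 0 else np.inf
            pv = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            pv = float(stats.studentized_range.sf(q, k, df_den))
        rows.append(
            {"group1": a, "group2": b, "diff": float(diff), "q": float(q),
             "p": pv, "reject": pv < alpha}
        )
    tukey = pd.DataFrame(rows)
    letters = compact_letter_display(levels, tukey, means)
    return AnovaResult(
        F=float(F), df_num=df_num, df_den=df_den, p=p,
        group_means=means, group_sizes=ns, tukey=tukey,
        tukey_letters=letters, alpha=alpha,
    )


def compact_letter_display(levels, pairwise: pd.DataFrame, means: pd.Series) -> dict:
    """Insert-and-absorb compact letter display from pairwise decisions.

    Groups sharing a letter are not significantly different.  Letters are
    assigned scanning groups from largest to smallest mean.
    """
    order = list(means.sort_values(ascending=False).index)
    nonsig = {frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if not r.reject}

    def compatible(group, letter_set):
        return all(frozenset((group, other)) in nonsig for other in letter_set)

    letter_sets: list[set] = []
    for gname in order:
        placed = False
        for s in letter_sets:
            if compatible(gname, s):
                s.add(gname)
                placed = True
        if not placed:
            letter_sets.append({gname})
    # absorb redundant sets
    pruned = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if s is not t):
            if s not in pruned:
                pruned.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for letter, s in zip(alphabet, pruned):
        for lev in order:
            if lev in s:
                out[lev] += letter
    return out


# ---------------------------------------------------------------------------
# ANCOVA with interaction screening
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    terms: pd.DataFrame              # term, df, F, p for the reported model
    interaction_retained: bool
    interaction_p: float             # from the screening (full-model) fit
    screening_threshold: float
    adjusted_means: pd.DataFrame     # environment, mean, se (at grand covariate mean)
    tukey_on_adjusted: pd.DataFrame
    slopes: pd.DataFrame             # common slope, or per-environment slopes
    model: object = field(repr=False, default=None)


def ancova_scaling(
    response,
    covariate,
    groups,
    screening_threshold: float = 0.20,
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA comparing group intercepts (and, if retained, slopes).

    Fits ``response ~ group * covariate``; if the interaction p-value
    (type-II ANOVA) exceeds ``screening_threshold`` the interaction is
    dropped and the common-slope model is reported.  Adjusted means are
    evaluated at the grand covariate mean and compared pairwise with a
    Tukey-Kramer-style studentized-range test.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(response, dtype=float),
            "x": np.asarray(covariate, dtype=float),
            "env": pd.Series(groups).astype(str).values,
        }
    )
    levels = sorted(df["env"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups for an ANCOVA")
    if df.groupby("env")["x"].nunique().min() < 2:
        raise ValueError("covariate is constant within a group (collinear with groups)")

    full = smf.ols("y ~ C(env) * x", data=df).fit()
    a_full = anova_lm(full, typ=2)
    p_int = float(a_full.loc["C(env):x", "PR(>F)"])
    retained = p_int <= screening_threshold

    model = full if retained else smf.ols("y ~ C(env) + x", data=df).fit()
    a_rep = anova_lm(model, typ=2)

    def _term_name(ix):
        return {"C(env)": "environment", "x": "covariate", "C(env):x": "environment:covariate"}.get(ix, ix)

    terms = pd.DataFrame(
        {
            "term": [_term_name(ix) for ix in a_rep.index if ix != "Residual"],
            "df": [int(a_rep.loc[ix, "df"]) for ix in a_rep.index if ix != "Residual"],
            "F": [float(a_rep.loc[ix, "F"]) for ix in a_rep.index if ix != "Residual"],
            "p": [float(a_rep.loc[ix, "PR(>F)"]) for ix in a_rep.index if ix != "Residual"],
        }
    )

    xbar = float(df["x"].mean())
    pred = pd.DataFrame({"env": levels, "x": xbar})
    sf = model.get_prediction(pred).summary_frame()
    adjusted = pd.DataFrame(
        {"environment": levels, "mean": sf["mean"].values, "se": sf["mean_se"].values}
    )

    # pairwise Tukey-Kramer on adjusted means via estimable contrasts
    df_resid = int(model.df_resid)
    k = len(levels)
    rows = []
    exog_names = model.model.exog_names
    for a, b in combinations(levels, 2):
        c = np.zeros(len(exog_names))
        for j, name in enumerate(exog_names):
            va = _design_value(name, a, xbar)
            vb = _design_value(name, b, xbar)
            c[j] = va - vb
        est = float(c @ model.params.values)
        se = float(np.sqrt(c @ model.cov_params().values @ c))
        if se == 0:
            q, pv = (0.0, 1.0) if est == 0 else (np.inf, 0.0)
        else:
            q = abs(est) / (se / np.sqrt(2.0))
            pv = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append({"group1": a, "group2": b, "diff": est, "q": q, "p": pv, "reject": pv < alpha})
    tukey_adj = pd.DataFrame(rows)

    params = model.params
    if retained:
        base = params.get("x", 0.0)
        slope_rows = []
        for lev in levels:
            extra = params.get(f"C(env)[T.{lev}]:x", 0.0)
            slope_rows.append({"environment": lev, "slope": float(base + extra)})
        slopes = pd.DataFrame(slope_rows)
    else:
        slopes = pd.DataFrame({"environment": ["common"], "slope": [float(params["x"])]})

    return AncovaResult(
        terms=terms,
        interaction_retained=retained,
        interaction_p=p_int,
        screening_threshold=screening_threshold,
        adjusted_means=adjusted,
        tukey_on_adjusted=tukey_adj,
        slopes=slopes,
        model=model,
    )


def _design_value(name: str, level: str, xval: float) -> float:
    """Value of a patsy design column for a given env level at covariate xval."""
    if name == "Intercept":
        return 1.0
    if name == "x":
        return xval
    if name == f"C(env)[T.{level}]":
        return 1.0
    if name == f"C(env)[T.{level}]:x":
        return xval
    return 0.0


# ---------------------------------------------------------------------------
# The full phenotypic battery
# ---------------------------------------------------------------------------

TRAITS = ("body_mass_mg", "femur_area_mm2", "testis_mass_mg")
ANCOVA_PAIRS = (
    ("femur_area_mm2", "body_mass_mg"),
    ("testis_mass_mg", "body_mass_mg"),
    ("testis_mass_mg", "femur_area_mm2"),
)


@dataclass
class ScalingReport:
    anovas: dict
    ancovas: dict
    table: pd.DataFrame  # model, term, df, F, p


def scaling_battery(
    data: pd.DataFrame,
    traits: Sequence[str] = TRAITS,
    ancova_pairs=ANCOVA_PAIRS,
    env_col: str = "environment",
    screening_threshold: float = 0.20,
    alpha: float = 0.05,
) -> ScalingReport:
    """Run the trait-expression analyses: 3 ANOVAs and 3 ANCOVAs.

    Each trait is log-transformed, compared across environments with a
    one-way ANOVA + Tukey's HSD, and each (response, covariate) pair is
    analysed by ANCOVA with the interaction screening rule.  Rows with a
    missing value for a trait are dropped from the analyses involving
    that trait only.
    """
    for t in traits:
        if t not in data.columns:
            raise KeyError(f"trait column {t!r} missing from the phenotype table")
    anovas, ancovas, rows = {}, {}, []
    for t in traits:
        sub = data.loc[data[t].notna()]
        res = one_way_anova_tukey(log_transform(sub[t]), sub[env_col], alpha=alpha)
        anovas[t] = res
        rows.append(
            {"model": f"anova:{t}", "term": "environment", "df": res.df_num,
             "F": res.F, "p": res.p}
        )
    for resp, cov in ancova_pairs:
        sub = data.loc[data[resp].notna() & data[cov].notna()]
        res = ancova_scaling(
            log_transform(sub[resp]),
            log_transform(sub[cov]),
            sub[env_col],
            screening_threshold=screening_threshold,
            alpha=alpha,
        )
        ancovas[(resp, cov)] = res
        label = f"ancova:{resp}~{cov}"
        for r in res.terms.itertuples(index=False):
            rows.append({"model": label, "term": r.term, "df": r.df, "F": r.F, "p": r.p})
    return ScalingReport(anovas=anovas, ancovas=ancovas, table=pd.DataFrame(rows))
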