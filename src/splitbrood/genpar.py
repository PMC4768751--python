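"""Heritability and evolvability summaries from fitted variance components.

Per environment *i* the quantities reported are

* ``h2_i   = s2_ai / (s2_ai + s2_e)`` -- narrow-sense heritability under
  the character-state model (phenotypic variance defined as additive plus
  residual; fixed effects excluded),
* ``SE(h2)`` by the delta method from the asymptotic covariance of the
  variance components,
* ``CV_A`` -- the coefficient of additive genetic variance.  Two variants
  are computed side by side: ``cva_stated = sqrt(V_A)/mean`` (the
  standard definition, reported without the conventional x100) and
  ``cva_printed = V_A/mean`` (a variant that appears in some published
  tables; it is *not* scale invariant), and
* ``I_A = V_A / mean^2`` -- mean-standardised evolvability, identically
  equal to ``cva_stated**2``.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .reml import FitResult, VarianceComponents


def heritability_by_environment(
    components: VarianceComponents,
    vcov: Optional[np.ndarray] = None,
    boundary=None,
) -> pd.DataFrame:
    """Per-environment heritability with delta-method standard errors.

    Parameters
    ----------
    components : VarianceComponents
        Fitted G and residual variance.
    vcov : array, optional
        Asymptotic covariance of the flattened components (diagonal
        genetic variances first, then off-diagonals, then the residual);
        when omitted the SEs are reported as NaN.
    boundary : sequence of bool, optional
        Environments whose genetic variance sits on its floor; these are
        reported as h2 = 0 with SE 0.
    """
    m = components.n_env
    s2e = components.sigma2_e
    diag = np.diag(components.G)
    if boundary is None:
        boundary = [False] * m
    rows = []
    for i in range(m):
        va = diag[i]
        tot = va + s2e
        if tot <= 0:
            raise ValueError(f"zero phenotypic variance in environment {components.env_labels[i]!r}")
        if boundary[i]:
            rows.append({"environment": components.env_labels[i], "h2": 0.0, "se_h2": 0.0})
            continue
        h2 = va / tot
        se = np.nan
        if vcov is not None:
            grad = np.array([s2e / tot**2, -va / tot**2])
            idx = [i, vcov.shape[0] - 1]
            sub = np.asarray(vcov)[np.ix_(idx, idx)]
            var_h2 = float(grad @ sub @ grad)
            se = float(np.sqrt(max(var_h2, 0.0)))
        rows.append({"environment": components.env_labels[i], "h2": float(h2), "se_h2": se})
    return pd.DataFrame(rows)


def evolvability_measures(V_A: float, mean: float) -> dict:
    """Mean-standardised measures of additive genetic variation.

    Returns a dict with ``cva_stated`` (sqrt(V_A)/mean), ``cva_printed``
    (V_A/mean) and ``I_A`` (V_A/mean^2).  ``I_A == cva_stated**2`` holds
    identically; ``cva_printed`` does not satisfy that identity and is
    retained only for comparison with tables that print it.
    """
    if mean <= 0:
        raise ValueError("trait mean must be positive for mean-standardised measures")
    if V_A < 0:
        raise ValueError("V_A must be non-negative")
    return {
        "cva_stated": float(np.sqrt(V_A) / mean),
        "cva_printed": float(V_A / mean),
        "I_A": float(V_A / mean**2),
    }


def genetic_correlations(components: VarianceComponents, boundary=None) -> pd.DataFrame:
    """Cross-environment genetic correlation matrix r_ij, clipped to [-1, 1].

    Pairs involving an environment whose genetic variance is zero (or at
    its boundary floor) are undefined and reported as NaN.
    """
    m = components.n_env
    diag = np.diag(components.G)
    if boundary is None:
        boundary = [False] * m
    bad = np.array([boundary[i] or diag[i] <= 0 for i in range(m)])
    R = np.full((m, m), np.nan)
    for i in range(m):
        if not bad[i]:
            R[i, i] = 1.0
        for j in range(i + 1, m):
            if not (bad[i] or bad[j]):
                r = components.G[i, j] / np.sqrt(diag[i] * diag[j])
                R[i, j] = R[j, i] = float(np.clip(r, -1.0, 1.0))
    return pd.DataFrame(R, index=components.env_labels, columns=components.env_labels)


def table2_summary(fits: Mapping[str, FitResult], data: pd.DataFrame) -> pd.DataFrame:
    """Genetic-parameter table: one row per trait x environment.

    Columns: raw trait mean in that environment, V_A, V_P (= V_A +
    residual), both CV_A variants, h2 with its SE, and I_A.  Genetic
    variances flagged as boundary estimates are printed as 0.0 with h2
    and SE 0.  Values are at full precision; rendered reports round to
    two decimals.
    """
    rows = []
    for trait, fit in fits.items():
        comp = fit.components
        h2tab = heritability_by_environment(comp, fit.vcov_components, fit.boundary)
        h2tab = h2tab.set_index("environment")
        sub = data.loc[data[trait].notna()]
        for i, env in enumerate(comp.env_labels):
            va = 0.0 if fit.boundary[i] else float(comp.G[i, i])
            vp = va + comp.sigma2_e
            xbar = float(sub.loc[sub["environment"] == env, trait].mean())
            ev = evolvability_measures(va, xbar)
            rows.append(
                {
                    "trait": trait,
                    "environment": env,
                    "mean": xbar,
                    "V_A": va,
                    "V_P": vp,
                    "CVA_stated": ev["cva_stated"],
                    "CVA_printed": ev["cva_printed"],
                    "h2": float(h2tab.loc[env, "h2"]),
                    "SE_h2": float(h2tab.loc[env, "se_h2"]),
                    "I_A": ev["I_A"],
                }
            )
    return pd.DataFrame(rows)
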