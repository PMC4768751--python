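"""Independent brute-force oracles used to validate the main implementations.

These deliberately share no code with the package internals: kinship is
computed by the recursive coancestry definition with memoisation, and the
restricted log-likelihood by naive dense construction of V and plain
``numpy.linalg`` calls.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd


def coancestry_kinship(ids, sire, dam):
    """Additive relationship matrix from the coancestry recursion.

    ``sire``/``dam`` map id -> parent id or None.  Individuals must be
    topologically ordered (parents first).  A_ij = 2 f_ij where f is the
    coefficient of coancestry: f(i,i) = (1 + f(s_i, d_i))/2 and, for i
    younger than j, f(i,j) = (f(s_i, j) + f(d_i, j))/2, with unknown
    parents contributing zero.
    """
    order = {v: k for k, v in enumerate(ids)}
    cache = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        key = (a, b) if order[a] <= order[b] else (b, a)
        if key in cache:
            return cache[key]
        if a == b:
            val = 0.5 * (1.0 + f(sire[a], dam[a]))
        else:
            # recurse on the younger individual
            x, y = (a, b) if order[a] > order[b] else (b, a)
            val = 0.5 * (f(sire[x], y) + f(dam[x], y))
        cache[key] = val
        return val

    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * f(ids[i], ids[j])
    return A


def reml_loglik_dense(pheno: pd.DataFrame, A_full: np.ndarray, a_ids, trait,
                      env_levels, G: np.ndarray, sigma2_e: float) -> float:
    """Restricted log-likelihood by explicit first-principles construction.

    V is filled entry by entry as A_ij * G[env_i, env_j] + sigma2_e * 1[i=j],
    X is built with pandas dummies, and the classic formula
    -(1/2)[(n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py] is evaluated
    with plain numpy inverses.
    """
    df = pheno.loc[pheno[trait].notna()].reset_index(drop=True)
    n = len(df)
    pos = {i: k for k, i in enumerate(a_ids)}
    env_pos = {e: k for k, e in enumerate(env_levels)}
    y = df[trait].to_numpy(dtype=float)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ai, aj = pos[df["id"][i]], pos[df["id"][j]]
            V[i, j] = A_full[ai, aj] * G[env_pos[df["environment"][i]], env_pos[df["environment"][j]]]
    V += sigma2_e * np.eye(n)

    X_parts = [np.ones((n, 1))]
    env_d = pd.get_dummies(pd.Categorical(df["environment"], categories=env_levels),
                           drop_first=True).to_numpy(dtype=float)
    X_parts.append(env_d)
    if "block" in df.columns and df["block"].nunique() > 1:
        X_parts.append(pd.get_dummies(df["block"].astype(str), drop_first=True).to_numpy(dtype=float))
    X = np.hstack(X_parts)
    p = np.linalg.matrix_rank(X)

    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtViX) @ X.T @ Vinv
    _, ldV = np.linalg.slogdet(V)
    _, ldW = np.linalg.slogdet(XtViX)
    return float(-0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldW + y @ P @ y))


def tukey_pairwise_bruteforce(values, groups, alpha=0.05):
    """All-pairs Tukey-Kramer decisions enumerated from first principles."""
    from scipy.stats import studentized_range

    y = np.asarray(values, float)
    g = np.asarray(groups)
    levels = sorted(set(g))
    k = len(levels)
    n = len(y)
    means = {lev: y[g == lev].mean() for lev in levels}
    ns = {lev: int((g == lev).sum()) for lev in levels}
    sse = sum(((y[g == lev] - means[lev]) ** 2).sum() for lev in levels)
    dfw = n - k
    mse = sse / dfw
    out = {}
    for a, b in combinations(levels, 2):
        q = abs(means[a] - means[b]) / np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
        p = studentized_range.sf(q, k, dfw)
        out[(a, b)] = (q, p, p < alpha)
    return out


def random_pedigree(rng: np.random.Generator, n: int):
    """A random valid pedigree of n individuals, possibly inbred.

    Each non-founder picks parents uniformly among earlier individuals
    (possibly the same lineage, creating inbreeding) or unknown.
    """
    ids = [f"I{k}" for k in range(n)]
    sire, dam = {}, {}
    records = []
    for k, i in enumerate(ids):
        if k < 2 or rng.random() < 0.2:
            s = d = None
        else:
            s = ids[int(rng.integers(k))]
            d = ids[int(rng.integers(k))]
            if d == s:
                d = ids[int(rng.integers(k))]
        sire[i], dam[i] = s, d
        records.append((i, s or "", d or ""))
    return ids, sire, dam, records
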