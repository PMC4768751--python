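"""Animal-model REML with an unstructured across-environment genetic covariance.

The model for a single trait measured on individuals reared in one of m
environments is::

    y = 1*mu + X1*tau + X2*beta + Z(a x tau) + e

with ``tau`` fixed environment effects, ``beta`` fixed dissector-block
effects, ``a x tau ~ MVN(0, A (x) G)`` the environment-specific additive
genetic effects (character states), and ``e ~ MVN(0, sigma2 * I)``.  ``A``
is the pedigree numerator relationship matrix and ``G`` the m x m
unstructured genetic covariance across environments.

Because every individual is phenotyped in exactly one environment, the
marginal covariance of the records is assembled directly as::

    V = A_obs  o  (U G U')  +  sigma2 * I

where ``A_obs`` is A restricted to phenotyped individuals, ``U`` the
n x m environment incidence matrix and ``o`` the elementwise product.
All linear algebra is dense; the target designs have ~10^3 records.

Estimation maximises the restricted log-likelihood

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X'V^-1 X| + y'Py ]

(with ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1`` and p = rank(X); the
constant term is included so values are comparable across software) by
EM-REML warm-start iterations followed by average-information (AI)
updates with step-halving.  EM steps can never decrease l_R; AI steps are
accepted only when they do not decrease it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = tuple(history or ())


class SingularModelError(np.linalg.LinAlgError):
    """The phenotypic covariance V is singular for the given components."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Genetic covariance G across environments plus residual variance.

    The flattened parameter order used throughout (``as_vector``,
    ``vcov_components``) is: the m diagonal genetic variances, then the
    off-diagonal covariances row-major ((1,2), (1,3), (2,3) for m = 3),
    then the residual variance.
    """

    G: np.ndarray
    sigma2_e: float
    env_labels: tuple = ("ripe", "unripe", "none")

    def __post_init__(self):
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "env_labels", tuple(self.env_labels))
        if G.shape[0] != G.shape[1] or not np.allclose(G, G.T, atol=1e-10 * (1 + abs(G).max())):
            raise ValueError("G must be symmetric")
        if len(self.env_labels) != G.shape[0]:
            raise ValueError("env_labels must match the dimension of G")

    @property
    def n_env(self) -> int:
        return self.G.shape[0]

    def as_vector(self) -> np.ndarray:
        m = self.n_env
        iu = np.triu_indices(m, k=1)
        return np.concatenate([np.diag(self.G), self.G[iu], [self.sigma2_e]])

    @classmethod
    def from_vector(cls, theta: Sequence[float], env_labels) -> "VarianceComponents":
        env_labels = tuple(env_labels)
        m = len(env_labels)
        theta = np.asarray(theta, dtype=float)
        G = np.diag(theta[:m]).astype(float)
        iu = np.triu_indices(m, k=1)
        G[iu] = theta[m:-1]
        G.T[iu] = theta[m:-1]
        return cls(G=G, sigma2_e=float(theta[-1]), env_labels=env_labels)


@dataclass(frozen=True)
class MixedModelSpec:
    """Names the response and model terms inside a phenotype table."""

    trait: str
    env_col: str = "environment"
    block_col: Optional[str] = "block"
    env_levels: Optional[tuple] = None  # None: sorted unique order of data


@dataclass
class FitResult:
    """REML estimates and everything needed by downstream summaries."""

    components: VarianceComponents
    reml_loglik: float
    vcov_components: np.ndarray
    fixed_effects: pd.DataFrame
    blups: pd.DataFrame
    converged: bool
    n_iter: int
    grad_norm: float
    history: tuple
    boundary: tuple
    n_obs: int
    rank_X: int
    env_levels: tuple
    block_levels: tuple
    # internals for Wald tests / adjusted means
    beta: np.ndarray = field(repr=False, default=None)
    cov_beta: np.ndarray = field(repr=False, default=None)
    term_cols: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

class _Design:
    """Dense design pieces shared by all REML computations."""

    def __init__(self, data: pd.DataFrame, A: KinshipMatrix, spec: MixedModelSpec):
        df = data.loc[data[spec.trait].notna()].copy()
        if df.empty:
            raise ValueError(f"no non-missing observations for trait {spec.trait!r}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"individual {dup!r} has more than one phenotype record")
        known = set(A.ids)
        missing = [i for i in df["id"] if i not in known]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped individual(s) absent from the pedigree, "
                f"e.g. {missing[:5]}"
            )
        self.ids = list(df["id"])
        self.y = df[spec.trait].to_numpy(dtype=float)
        self.n = len(self.y)

        env = df[spec.env_col].astype(str)
        if spec.env_levels is not None:
            levels = tuple(spec.env_levels)
            bad = sorted(set(env) - set(levels))
            if bad:
                raise ValueError(f"unknown environment label(s): {bad}")
        else:
            levels = tuple(sorted(env.unique()))
        self.env_levels = levels
        self.m = len(levels)
        pos = {lab: k for k, lab in enumerate(levels)}
        self.env_idx = np.array([pos[e] for e in env], dtype=int)
        self.U = np.zeros((self.n, self.m))
        self.U[np.arange(self.n), self.env_idx] = 1.0

        # fixed-effect design: intercept + env dummies + block dummies
        cols = [np.ones(self.n)]
        names = ["intercept"]
        term_cols: dict[str, list[int]] = {"intercept": [0]}
        term_cols["environment"] = []
        for lab in levels[1:]:
            term_cols["environment"].append(len(cols))
            cols.append((env == lab).to_numpy(dtype=float))
            names.append(f"environment[{lab}]")
        self.block_levels: tuple = ()
        if spec.block_col is not None and spec.block_col in df.columns:
            block = df[spec.block_col].astype(str)
            blevels = tuple(sorted(block.unique()))
            self.block_levels = blevels
            if len(blevels) > 1:  # a constant block column is absorbed by the intercept
                term_cols["block"] = []
                for lab in blevels[1:]:
                    term_cols["block"].append(len(cols))
                    cols.append((block == lab).to_numpy(dtype=float))
                    names.append(f"block[{lab}]")
        X = np.column_stack(cols)
        # drop redundant columns (e.g. a block nested in environment)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = sla.qr(X, pivoting=True, mode="economic")
            keep = sorted(piv[:rank])
            logger.warning(
                "fixed-effect design rank deficient (%d of %d columns kept)",
                rank, X.shape[1],
            )
            remap = {old: new for new, old in enumerate(keep)}
            term_cols = {
                t: [remap[c] for c in cs if c in remap] for t, cs in term_cols.items()
            }
            names = [names[c] for c in keep]
            X = X[:, keep]
        self.X = X
        self.coef_names = names
        self.term_cols = term_cols
        self.p = X.shape[1]

        self.A_obs = A.submatrix(self.ids)
        self.kinship = A

        # Connected components of the relatedness graph: distinct sire
        # families are mutually unrelated, so V is block diagonal and each
        # family can be factorised independently.
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        adj = csr_matrix(self.A_obs != 0.0)
        n_comp, labels = connected_components(adj, directed=False)
        self.blocks = [np.flatnonzero(labels == b) for b in range(n_comp)]


class _LikelihoodState:
    """All per-iteration quantities at one value of the components.

    Every O(n^3) operation is performed blockwise over the connected
    components of the relatedness graph (sire families), since V is block
    diagonal there; only the small p x p fixed-effect system couples the
    blocks, through ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1``.
    """

    __slots__ = ("theta", "ll", "v", "AV", "Q", "R", "trP", "vv",
                 "VX", "XtViX", "Vinv_blocks", "_design")

    def __init__(self, design: _Design, theta: np.ndarray):
        n, m = design.n, design.m
        G = _theta_to_G(theta, m)
        s2 = theta[-1]
        X, y = design.X, design.y

        logdetV = 0.0
        Vinv_blocks = []
        VX = np.empty((n, design.p))       # V^-1 X
        Viy = np.empty(n)                  # V^-1 y
        for idx in design.blocks:
            Ub = design.U[idx]
            Vb = design.A_obs[np.ix_(idx, idx)] * (Ub @ G @ Ub.T)
            Vb[np.diag_indices(len(idx))] += s2
            try:
                c, low = sla.cho_factor(Vb, lower=True, check_finite=False)
            except np.linalg.LinAlgError as e:
                raise SingularModelError(
                    f"phenotypic covariance V is singular (G diag {np.diag(G)}, "
                    f"sigma2_e={s2:.3g}): {e}"
                ) from None
            logdetV += 2.0 * np.log(np.diag(c)).sum()
            rhs = np.column_stack([X[idx], y[idx]])
            sol = sla.cho_solve((c, low), rhs, check_finite=False)
            VX[idx] = sol[:, :-1]
            Viy[idx] = sol[:, -1]
            Vinv_blocks.append(sla.cho_solve((c, low), np.eye(len(idx)), check_finite=False))

        XtViX = X.T @ VX
        sign, logdetW = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise SingularModelError("X'V^-1X is singular; check the fixed-effect design")
        XtViy = X.T @ Viy
        Wsolve_y = np.linalg.solve(XtViX, XtViy)
        v = Viy - VX @ Wsolve_y            # v = Py
        ypy = float(y @ v)
        self.ll = -0.5 * ((n - design.p) * np.log(2.0 * np.pi) + logdetV + logdetW + ypy)
        self.theta = theta
        self.v = v
        self.VX = VX
        self.XtViX = XtViX
        self.Vinv_blocks = Vinv_blocks
        self._design = design

        Vv = design.U * v[:, None]          # v_k = 1[env=k] o Py, columns k
        AV = np.zeros((n, m))
        for bi, idx in enumerate(design.blocks):
            AV[idx] = design.A_obs[np.ix_(idx, idx)] @ Vv[idx]
        self.AV = AV                         # A v_k, columns k
        self.Q = Vv.T @ AV                   # Q[k,l] = v_k' A v_l

        # R[k,l] = tr(P (A o u_k u_l')) via P entries on the A-support only
        R = np.zeros((m, m))
        trP = 0.0
        Winv_VXT = np.linalg.solve(XtViX, VX.T)
        for bi, idx in enumerate(design.blocks):
            Pb = self.Vinv_blocks[bi] - VX[idx] @ Winv_VXT[:, idx]
            PAb = Pb * design.A_obs[np.ix_(idx, idx)]
            Ub = design.U[idx]
            R += Ub.T @ PAb @ Ub
            trP += float(np.trace(Pb))
        self.R = R
        self.trP = trP
        self.vv = float(v @ v)

    def apply_P(self, M: np.ndarray) -> np.ndarray:
        """P @ M for an n x k matrix, blockwise."""
        out = np.empty_like(M)
        for bi, idx in enumerate(self._design.blocks):
            out[idx] = self.Vinv_blocks[bi] @ M[idx]
        out -= self.VX @ np.linalg.solve(self.XtViX, self.VX.T @ M)
        return out

    def score(self, m: int) -> np.ndarray:
        """Gradient of the restricted log-likelihood in flat parameter order."""
        iu = np.triu_indices(m, k=1)
        g_diag = -0.5 * (np.diag(self.R) - np.diag(self.Q))
        g_off = -0.5 * (2.0 * self.R[iu] - 2.0 * self.Q[iu])
        g_e = -0.5 * (self.trP - self.vv)
        return np.concatenate([g_diag, g_off, [g_e]])

    def ai_matrix(self, design: _Design) -> np.ndarray:
        """Average-information matrix: AI_ij = y'P B_i P B_j P y / 2."""
        n, m = design.n, design.m
        iu = np.triu_indices(m, k=1)
        npar = m + len(iu[0]) + 1
        W = np.empty((n, npar))
        for k in range(m):
            W[:, k] = design.U[:, k] * self.AV[:, k]
        for j, (k, l) in enumerate(zip(*iu)):
            W[:, m + j] = design.U[:, k] * self.AV[:, l] + design.U[:, l] * self.AV[:, k]
        W[:, -1] = self.v
        PW = self.apply_P(W)
        return 0.5 * (W.T @ PW)


def _theta_to_G(theta: np.ndarray, m: int) -> np.ndarray:
    G = np.diag(theta[:m]).astype(float)
    iu = np.triu_indices(m, k=1)
    G[iu] = theta[m:-1]
    G.T[iu] = theta[m:-1]
    return G


def _G_to_theta(G: np.ndarray, s2: float) -> np.ndarray:
    m = G.shape[0]
    iu = np.triu_indices(m, k=1)
    return np.concatenate([np.diag(G), G[iu], [s2]])


# ---------------------------------------------------------------------------
# Public likelihood
# ---------------------------------------------------------------------------

def restricted_log_likelihood(
    data: pd.DataFrame,
    A: KinshipMatrix,
    spec: MixedModelSpec,
    vc: VarianceComponents,
) -> float:
    """Restricted log-likelihood of the animal model at given components.

    The value includes the constant ``-(n - p)/2 * log(2*pi)`` with
    ``p = rank(X)``, so it matches a full multivariate-normal restricted
    likelihood evaluated on error contrasts.
    """
    design = _Design(data, A, spec)
    if vc.n_env != design.m:
        raise ValueError(
            f"components have {vc.n_env} environments, data has {design.m}"
        )
    _check_env_order(vc, design)
    return _LikelihoodState(design, vc.as_vector()).ll


def _check_env_order(vc: VarianceComponents, design: _Design):
    if tuple(vc.env_labels) != tuple(design.env_levels):
        raise ValueError(
            f"component environment order {vc.env_labels} does not match the "
            f"design order {design.env_levels}; pass spec.env_levels explicitly"
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class REMLOptions:
    max_iter: int = 500
    em_iters: int = 20          # EM warm-start iterations before quasi-Newton
    ll_tol: float = 1e-8
    grad_tol: float = 1e-4      # on the variance-standardised scale
    on_nonconvergence: str = "raise"  # or "warn"
    constrain: str = "psd"      # "psd": keep G PSD; "none": allow indefinite G


def _project(theta: np.ndarray, m: int, floor_a: float, floor_e: float,
             constrain: str = "psd") -> np.ndarray:
    """Project components onto the feasible set.

    In the default "psd" mode G is clipped to the PSD cone and the
    genetic variances floored; in "none" mode (ASReml-style unstructured
    fit) G may be indefinite and only the residual variance is floored.
    """
    if constrain == "none":
        out = theta.copy()
        out[-1] = max(out[-1], floor_e)
        return out
    G = _theta_to_G(theta, m)
    w, Vec = np.linalg.eigh(G)
    clip = 1e-8 * max(np.trace(G), 0.0)
    if w.min() < clip:
        w = np.clip(w, clip, None)
        G = (Vec * w) @ Vec.T
    d = np.diag(G).copy()
    low = d < floor_a
    if low.any():
        G[np.diag_indices(m)] = np.where(low, floor_a, d)
    s2 = max(theta[-1], floor_e)
    return _G_to_theta(G, s2)


def reml_fit(
    data: pd.DataFrame,
    A: KinshipMatrix,
    spec: MixedModelSpec,
    options: Optional[REMLOptions] = None,
) -> FitResult:
    """Fit the environment-specific animal model by EM + AI REML.

    The response is standardised internally (divided by its sample
    standard deviation) so that tolerances behave identically across
    traits of any scale; all reported quantities are transformed back.
    Genetic variances driven to their floor (1e-10 x sample variance of
    the response) are flagged as boundary estimates and reported as zero
    by the summary layer, not treated as failures.
    """
    opts = options or REMLOptions()
    design = _Design(data, A, spec)
    m = design.m

    y_raw = design.y
    vary = float(np.var(y_raw, ddof=1))
    if vary <= 0:
        raise ValueError("response has zero variance; nothing to decompose")
    c_scale = np.sqrt(vary)
    design.y = y_raw / c_scale  # standardised response; components in units of var(y)

    floor_a = 1e-10
    floor_e = 1e-8
    # moment-flavoured starting values: a third of the variance genetic
    theta = np.concatenate([np.full(m, 1.0 / 3.0), np.zeros(m * (m - 1) // 2), [2.0 / 3.0]])

    # --- EM warm start (monotone in the restricted log-likelihood) -----
    state = _LikelihoodState(design, theta)
    history = [state.ll]
    it = 0
    for _ in range(opts.em_iters):
        it += 1
        state = _LikelihoodState(design, _em_update(design, state, floor_a, floor_e, opts.constrain))
        history.append(state.ll)
        pgrad = _projected_gradient(state.score(m), state.theta, m, floor_a, floor_e, opts.constrain)
        if (history[-1] - history[-2]) < opts.ll_tol and \
                float(np.abs(pgrad).max()) < opts.grad_tol:
            break

    # --- quasi-Newton refinement on the Cholesky factor of G ----------
    # G = L L' keeps every iterate PSD and makes boundary optima
    # (zero variances, correlations at +/-1) ordinary stationary points;
    # the residual variance is optimised on the log scale.
    # Convergence is declared when the factor-space projected gradient is
    # below grad_tol, or when a restart (two EM steps + a fresh
    # quasi-Newton run) can no longer improve the restricted
    # log-likelihood by ll_tol: near machine precision the gradient of a
    # ~10^3-observation likelihood cannot always be driven to a small
    # absolute norm even at the exact optimum.
    l_pairs = _chol_factor_pairs(m)
    pgrad_norm = np.inf
    converged = False
    state, nit = _lbfgs_refine(design, state, l_pairs, floor_a, floor_e, opts, history)
    it += max(nit, 1)
    for attempt in range(3):
        pgrad = _projected_gradient(state.score(m), state.theta, m, floor_a, floor_e, opts.constrain)
        pgrad_norm = float(np.abs(pgrad).max())
        if pgrad_norm < opts.grad_tol:
            converged = True
            break
        prev_ll = state.ll
        for _ in range(2):
            it += 1
            state = _LikelihoodState(design, _em_update(design, state, floor_a, floor_e, opts.constrain))
            history.append(state.ll)
        state, nit = _lbfgs_refine(design, state, l_pairs, floor_a, floor_e, opts, history)
        it += max(nit, 1)
        if state.ll - prev_ll < opts.ll_tol:
            pgrad = _projected_gradient(state.score(m), state.theta, m, floor_a, floor_e, opts.constrain)
            pgrad_norm = float(np.abs(pgrad).max())
            converged = True
            break
    if not converged:
        msg = (
            f"REML did not converge in {it} iterations "
            f"(projected gradient norm={pgrad_norm:.3g})"
        )
        if opts.on_nonconvergence == "raise":
            raise ConvergenceError(msg, history)
        logger.warning(msg)

    # ----- assemble results on the original scale ----------------------
    theta = state.theta
    G_std = _theta_to_G(theta, m)
    if opts.constrain == "psd":
        boundary = tuple(bool(G_std[k, k] <= 10 * floor_a) for k in range(m))
    else:
        boundary = tuple(False for _ in range(m))
    ai = state.ai_matrix(design)
    try:
        vcov_std = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        logger.warning("AI matrix singular at the optimum; using pseudo-inverse")
        vcov_std = np.linalg.pinv(ai)

    c2 = c_scale ** 2
    components = VarianceComponents(
        G=G_std * c2, sigma2_e=float(theta[-1] * c2), env_labels=design.env_levels
    )
    vcov = vcov_std * c2 ** 2
    ll = state.ll - (design.n - design.p) * np.log(c_scale)

    # fixed effects at the optimum
    cov_beta_std = np.linalg.inv(state.XtViX)
    beta_std = cov_beta_std @ (state.VX.T @ design.y)
    beta = beta_std * c_scale
    cov_beta = cov_beta_std * c2
    fixed = pd.DataFrame(
        {
            "coef": design.coef_names,
            "estimate": beta,
            "se": np.sqrt(np.diag(cov_beta)),
        }
    )

    # BLUPs of environment-specific breeding values for every pedigree id
    obs_pos = [design.kinship.ids.index(i) for i in design.ids]
    A_cross = design.kinship.values[:, obs_pos]
    Vv = design.U * state.v[:, None]
    u_hat = (A_cross @ Vv) @ G_std * c_scale  # q x m, original trait units
    blups = pd.DataFrame(
        {
            "id": np.repeat(design.kinship.ids, m),
            "environment": list(design.env_levels) * len(design.kinship.ids),
            "blup": u_hat.ravel(),
        }
    )

    design.y = y_raw
    return FitResult(
        components=components,
        reml_loglik=float(ll),
        vcov_components=vcov,
        fixed_effects=fixed,
        blups=blups,
        converged=converged,
        n_iter=it,
        grad_norm=pgrad_norm,
        history=tuple(h - (design.n - design.p) * np.log(c_scale) for h in history),
        boundary=boundary,
        n_obs=design.n,
        rank_X=design.p,
        env_levels=design.env_levels,
        block_levels=design.block_levels,
        beta=beta,
        cov_beta=cov_beta,
        term_cols=dict(design.term_cols),
    )


def _em_update(design, state, floor_a, floor_e, constrain="psd") -> np.ndarray:
    """Exact EM-REML update; never decreases the restricted log-likelihood."""
    m, n = design.m, design.n
    theta = state.theta
    G = _theta_to_G(theta, m)
    s2 = theta[-1]
    G_new = G + (G @ (state.Q - state.R) @ G) / n
    s2_new = s2 + (s2 ** 2) * (state.vv - state.trP) / n
    return _project(_G_to_theta(G_new, s2_new), m, floor_a, floor_e, constrain)


def _chol_factor_pairs(m: int):
    """Parameter order of the lower-triangular factor: diagonal first."""
    return [(i, i) for i in range(m)] + [(i, j) for j in range(m) for i in range(j + 1, m)]


def _chol_jacobian(L: np.ndarray) -> np.ndarray:
    """d vech(G) / d vech(L) for G = L L' in the package's flat ordering.

    Rows follow the flat G order (diagonal variances, then upper-triangle
    covariances); columns follow ``_chol_factor_pairs``.
    """
    m = L.shape[0]
    iu = np.triu_indices(m, k=1)
    g_pairs = [(k, k) for k in range(m)] + list(zip(*iu))
    l_pairs = _chol_factor_pairs(m)
    J = np.zeros((len(g_pairs), len(l_pairs)))
    for col, (a, b) in enumerate(l_pairs):
        for row, (k, l) in enumerate(g_pairs):
            # dG_kl = delta_ka L_lb + L_kb delta_la
            val = 0.0
            if k == a:
                val += L[l, b]
            if l == a:
                val += L[k, b]
            J[row, col] = val
    return J


def _safe_cholesky(G: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * max(np.trace(G), 1.0)
        return np.linalg.cholesky(G + jitter * np.eye(G.shape[0]))


def _lbfgs_refine(design, state, l_pairs, floor_a, floor_e, opts, history):
    """Maximise the restricted log-likelihood by L-BFGS-B.

    In "psd" mode the optimisation runs over (vech(L), log sigma2) with
    G = L L', so every iterate is PSD; in "none" mode it runs over the
    raw components (vech(G), log sigma2) and G may become indefinite as
    long as V stays positive definite.  Exact analytic gradients are
    used (mapped through the Cholesky Jacobian in "psd" mode).  Returns
    the best state seen and the number of iterations.
    """
    from scipy.optimize import minimize

    m = design.m
    chol_mode = opts.constrain == "psd"
    if chol_mode:
        L0 = _safe_cholesky(_theta_to_G(state.theta, m))
        x0 = np.array([L0[i, j] for i, j in l_pairs] + [np.log(state.theta[-1])])
    else:
        x0 = np.concatenate([state.theta[:-1], [np.log(state.theta[-1])]])
    best = {"state": state}

    def unpack(x):
        if chol_mode:
            Lc = np.zeros((m, m))
            for val, (i, j) in zip(x[:-1], l_pairs):
                Lc[i, j] = val
            return Lc, _G_to_theta(Lc @ Lc.T, float(np.exp(x[-1])))
        theta_c = np.concatenate([x[:-1], [np.exp(x[-1])]])
        return None, theta_c

    def negll_and_grad(x):
        Lc, theta_c = unpack(x)
        theta_c = _project(theta_c, m, floor_a, floor_e, opts.constrain)
        s2 = theta_c[-1]
        try:
            st = _LikelihoodState(design, theta_c)
        except SingularModelError:
            return 1e12, np.zeros_like(x)
        if st.ll > best["state"].ll:
            best["state"] = st
        g = st.score(m)
        grad = np.empty_like(x)
        if chol_mode:
            grad[:-1] = _chol_jacobian(Lc).T @ g[:-1]
        else:
            grad[:-1] = g[:-1]
        grad[-1] = g[-1] * s2  # d ll / d log sigma2
        return -st.ll, -grad

    res = minimize(
        negll_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * (len(x0) - 1) + [(np.log(floor_e), None)],
        options={
            "maxiter": opts.max_iter,
            "ftol": 1e-13,
            "gtol": 0.1 * opts.grad_tol,
        },
    )
    final = best["state"]
    if history is not None and final.ll > history[-1]:
        history.append(final.ll)
    return final, int(res.nit)


def _projected_gradient(score, theta, m, floor_a, floor_e, constrain="psd") -> np.ndarray:
    """KKT stationarity measure of the constrained REML problem.

    In "psd" mode the genetic block is expressed in Cholesky-factor
    space (where the PSD constraint is free) and score entries pushing
    floored variances further down are zeroed; in "none" mode the raw
    score is returned with only the residual floor handled.
    """
    g = score.copy()
    if theta[-1] <= 10 * floor_e and g[-1] < 0:
        g[-1] = 0.0
    if constrain == "none":
        return g
    for k in range(m):
        if theta[k] <= 10 * floor_a and g[k] < 0:
            g[k] = 0.0
    L = _safe_cholesky(_theta_to_G(theta, m))
    J = np.zeros((len(theta), len(theta)))
    J[:-1, :-1] = _chol_jacobian(L)
    J[-1, -1] = 1.0
    return J.T @ g


# ---------------------------------------------------------------------------
# Post-fit inference on fixed effects
# ---------------------------------------------------------------------------

def wald_f_tests(fit: FitResult, spec: MixedModelSpec = None) -> pd.DataFrame:
    """Approximate F-tests of the fixed factors (environment, block).

    For each factor the Wald statistic on its treatment-coded
    coefficients is divided by the number of estimable contrasts to give
    an approximate F with denominator df ``n - rank(X)`` -- a documented,
    deliberately simple choice for the reference distribution.
    """
    rows = []
    df_den = fit.n_obs - fit.rank_X
    for term, cols in fit.term_cols.items():
        if term == "intercept":
            continue
        r = len(cols)
        if r == 0:
            raise ValueError(
                f"term {term!r} has no estimable contrasts (single level?); "
                "cannot form an F-test"
            )
        L = np.zeros((r, len(fit.beta)))
        for j, c in enumerate(cols):
            L[j, c] = 1.0
        lb = L @ fit.beta
        mid = L @ fit.cov_beta @ L.T
        F = float(lb @ np.linalg.solve(mid, lb)) / r
        p = float(stats.f.sf(F, r, df_den))
        rows.append({"term": term, "df_num": r, "df_den": df_den, "F": F, "p": p})
    return pd.DataFrame(rows)


def predicted_environment_means(fit: FitResult) -> pd.DataFrame:
    """Adjusted (model-predicted) trait means per environment with SEs.

    Fixed-effect linear combinations at each environment level with the
    dissector blocks averaged with equal weight, so the result does not
    depend on the treatment-coding reference level.
    """
    k = len(fit.beta)
    env_cols = fit.term_cols.get("environment", [])
    block_cols = fit.term_cols.get("block", [])
    n_blocks = len(fit.block_levels) if fit.block_levels else 1
    rows = []
    env_dummy_by_level = dict(zip(fit.env_levels[1:], env_cols))
    for lev in fit.env_levels:
        c = np.zeros(k)
        c[fit.term_cols["intercept"][0]] = 1.0
        if lev in env_dummy_by_level:
            c[env_dummy_by_level[lev]] = 1.0
        for bc in block_cols:
            c[bc] = 1.0 / n_blocks
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        rows.append({"environment": lev, "mean": est, "se": se})
    return pd.DataFrame(rows)
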