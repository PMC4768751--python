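"""Generative model for half-sib split-brood experiments.

Emulates the breeding design of the *Narnia femorata* diet study:
~35 sire families, three dams per sire, broods split at the 4th instar
among three developmental diets (ripe fruit, unripe fruit, no fruit) with
unbalanced per-environment family sizes.  Breeding values are simulated
under the character-state model: each individual carries a vector of
environment-specific additive effects with covariance ``A (x) G`` across
the pedigree, of which only the component matching the individual's own
rearing environment is expressed in its phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_pedigree

ENV_LABELS = ("ripe", "unripe", "none")

#: per-sire-family median offspring counts by environment in the study design
DEFAULT_ENV_MEDIANS = (11, 6, 14)


@dataclass(frozen=True)
class TrueParameters:
    """True simulation parameters for one trait.

    Parameters
    ----------
    G : (m, m) array
        Additive genetic covariance matrix across the m environments
        (character states), trait-units squared.  Must be PSD.
    sigma2_e : float
        Residual variance, identical in every environment.
    env_means : sequence of m floats
        Expected phenotype (mu + tau_i) in each environment.
    block_effects : mapping block-id -> effect
        Fixed effects of the dissector handling an individual.
    """

    G: np.ndarray
    sigma2_e: float
    env_means: tuple
    block_effects: Mapping[str, float] = field(default_factory=lambda: {"d1": 0.0})

    def __post_init__(self):
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "env_means", tuple(float(m) for m in self.env_means))
        if G.shape[0] != G.shape[1] or not np.allclose(G, G.T):
            raise ValueError("G must be a symmetric square matrix")
        if len(self.env_means) != G.shape[0]:
            raise ValueError("env_means length must match dimension of G")
        w = np.linalg.eigvalsh(G)
        if w.min() < -1e-8 * max(1.0, np.trace(G)):
            raise ValueError(f"G is not positive semidefinite (min eigenvalue {w.min():.3g})")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be non-negative")


@dataclass(frozen=True)
class DesignConfig:
    """Structure of the breeding design and of the environment allocation."""

    n_sires: int = 35
    dams_per_sire: int = 3
    offspring_per_dam: int = 10
    env_labels: tuple = ENV_LABELS
    env_weights: Optional[tuple] = None  # default: medians 11/6/14 normalised
    missing_cell_rate: float = 0.01
    n_blocks: int = 3
    family_level_allocation: bool = False
    resample_nonpositive: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sires, self.dams_per_sire, self.offspring_per_dam) <= 0:
            raise ValueError("design counts must be positive")
        if self.env_weights is None:
            med = DEFAULT_ENV_MEDIANS[: len(self.env_labels)]
            w = np.asarray(med, dtype=float)
        else:
            w = np.asarray(self.env_weights, dtype=float)
        if len(w) != len(self.env_labels):
            raise ValueError("env_weights length must match env_labels")
        if (w < 0).any():
            raise ValueError("environment weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("at least one environment must have positive weight")
        object.__setattr__(self, "env_weights", tuple(w / w.sum()))
        if not (0.0 <= self.missing_cell_rate < 1.0):
            raise ValueError("missing_cell_rate must be in [0, 1)")
        if self.n_blocks <= 0:
            raise ValueError("n_blocks must be positive")


def allocate_split_brood(
    family_sizes: Sequence[int],
    env_weights: Sequence[float],
    seed,
    sire_of_family: Optional[Sequence[int]] = None,
    missing_cell_rate: float = 0.0,
) -> list:
    """Assign the offspring of each brood to environments at random.

    Each offspring independently draws an environment with the given
    weights (the split-brood scheme).  When ``missing_cell_rate`` > 0,
    whole sire-family x environment cells are first declared empty, and
    offspring that drew an empty cell redraw among the remaining
    environments -- reproducing the occasional empty cells of unbalanced
    real designs.

    Returns a list of integer arrays, one per brood, containing
    environment indices.
    """
    sizes = np.asarray(list(family_sizes), dtype=int)
    if (sizes < 0).any():
        raise ValueError("family sizes must be non-negative")
    w = np.asarray(env_weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and sum to a positive value")
    w = w / w.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(w)

    if sire_of_family is None:
        sire_of_family = list(range(len(sizes)))
    sires = sorted(set(sire_of_family))

    # sire x environment cells knocked out wholesale
    dead: dict[int, set] = {s: set() for s in sires}
    if missing_cell_rate > 0:
        for s in sires:
            for e in range(m):
                if rng.random() < missing_cell_rate:
                    dead[s].add(e)
            if len(dead[s]) == m:  # never empty a whole sire family
                dead[s].discard(int(rng.integers(m)))

    out = []
    for fam, n in enumerate(sizes):
        s = sire_of_family[fam]
        alive = np.array([e for e in range(m) if e not in dead[s]], dtype=int)
        wa = w[alive]
        if wa.sum() <= 0:
            # all surviving cells have zero weight: put everything in the
            # first surviving environment rather than fail the brood
            draw = np.full(n, alive[0], dtype=int)
        else:
            draw = rng.choice(alive, size=n, p=wa / wa.sum())
        out.append(draw)
    return out


def _default_block_assignment(rng: np.random.Generator, n: int, n_blocks: int) -> np.ndarray:
    return rng.integers(n_blocks, size=n)


def simulate_breeding_design(cfg: DesignConfig, truth: TrueParameters):
    """Simulate a half-sib split-brood dataset for a single trait.

    Founder breeding-value vectors are drawn from MVN(0, G); each
    offspring inherits the parental average plus a Mendelian-sampling
    deviation MVN(0, G/2) (parents are non-inbred by design).  The
    observed phenotype of an individual reared in environment *i* is::

        y = env_means[i] + block_effect + a_i + e,   e ~ N(0, sigma2_e)

    Returns
    -------
    (Pedigree, DataFrame)
        The pedigree (founders first) and a phenotype table with columns
        ``id, environment, block, value`` plus ``sire`` for convenience.
        Column ``value`` is the simulated trait.

    Notes
    -----
    With ``cfg.resample_nonpositive`` the residual of any record whose
    phenotype lands at or below zero is redrawn (up to 1000 times); this
    truncates the lower residual tail very slightly and exists so that
    log-scale analyses can run on the same synthetic data.
    """
    m = len(cfg.env_labels)
    if truth.G.shape[0] != m:
        raise ValueError(
            f"truth has {truth.G.shape[0]} environments but design has {m}"
        )
    rng = np.random.default_rng(cfg.seed)

    # --- pedigree ------------------------------------------------------
    records = []
    sires = [f"S{i+1}" for i in range(cfg.n_sires)]
    records += [(s, "", "") for s in sires]
    dams, brood_parent = [], []
    for i, s in enumerate(sires):
        for j in range(cfg.dams_per_sire):
            d = f"D{i+1}_{j+1}"
            dams.append(d)
            records.append((d, "", ""))
            brood_parent.append((s, d, i))
    off_records = []
    k = 0
    for s, d, i in brood_parent:
        for _ in range(cfg.offspring_per_dam):
            k += 1
            off_records.append((f"O{k}", s, d))
    records += off_records
    ped = build_pedigree(records)

    # --- breeding values (vector per individual, one entry per env) ----
    n_ped = len(ped)
    chol = _psd_cholesky(truth.G)
    a = np.zeros((n_ped, m))
    for i in range(n_ped):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0 and di < 0:
            a[i] = chol @ rng.standard_normal(m)
        else:
            mid = np.zeros(m)
            if si >= 0:
                mid += 0.5 * a[si]
            if di >= 0:
                mid += 0.5 * a[di]
            a[i] = mid + np.sqrt(0.5) * (chol @ rng.standard_normal(m))

    # --- environments, blocks, phenotypes ------------------------------
    brood_sizes = [cfg.offspring_per_dam] * len(brood_parent)
    sire_of_family = [i for (_, _, i) in brood_parent]
    if cfg.family_level_allocation:
        env_assign = []
        for fam in range(len(brood_sizes)):
            e = rng.choice(m, p=np.asarray(cfg.env_weights))
            env_assign.append(np.full(brood_sizes[fam], e, dtype=int))
    else:
        env_assign = allocate_split_brood(
            brood_sizes,
            cfg.env_weights,
            rng,
            sire_of_family=sire_of_family,
            missing_cell_rate=cfg.missing_cell_rate,
        )

    off_ids = [r[0] for r in off_records]
    off_pos = np.array([ped.index[i] for i in off_ids])
    env_idx = np.concatenate(env_assign)
    n_off = len(off_ids)
    block_idx = _default_block_assignment(rng, n_off, cfg.n_blocks)
    block_ids = [f"d{b+1}" for b in range(cfg.n_blocks)]
    beffects = dict(truth.block_effects)
    beff = np.array([beffects.get(block_ids[b], 0.0) for b in block_idx])

    mu = np.asarray(truth.env_means)[env_idx]
    g = a[off_pos, env_idx]
    sd = np.sqrt(truth.sigma2_e)
    e = sd * rng.standard_normal(n_off)
    y = mu + beff + g + e
    if cfg.resample_nonpositive and sd > 0:
        bad = np.flatnonzero(y <= 0)
        tries = 0
        while bad.size and tries < 1000:
            y[bad] = mu[bad] + beff[bad] + g[bad] + sd * rng.standard_normal(bad.size)
            bad = bad[y[bad] <= 0]
            tries += 1
        if bad.size:
            raise RuntimeError("could not draw positive phenotypes; means too close to zero")

    sire_col = [off_records[i][1] for i in range(n_off)]
    pheno = pd.DataFrame(
        {
            "id": off_ids,
            "environment": [cfg.env_labels[e] for e in env_idx],
            "block": [block_ids[b] for b in block_idx],
            "value": y,
            "sire": sire_col,
        }
    )
    return ped, pheno


def _psd_cholesky(G: np.ndarray) -> np.ndarray:
    """Cholesky-like factor valid for singular PSD matrices."""
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(G)
        w = np.clip(w, 0.0, None)
        return V @ np.diag(np.sqrt(w))


def correlation_to_covariance(variances: Sequence[float], r: float) -> np.ndarray:
    """Build a genetic covariance matrix from per-environment variances and
    a common cross-environment genetic correlation ``r``."""
    v = np.asarray(variances, dtype=float)
    sd = np.sqrt(v)
    G = r * np.outer(sd, sd)
    np.fill_diagonal(G, v)
    return G


# ---------------------------------------------------------------------------
# Default trait parameter sets (study-scale magnitudes)
# ---------------------------------------------------------------------------

def default_truth(trait: str = "body_mass_mg") -> TrueParameters:
    """Study-scale true parameters for one of the three measured traits.

    Magnitudes mirror the published per-diet estimates for *N. femorata*
    (means and genetic/phenotypic variances by environment), with a single
    residual variance chosen to match the ripe-fruit phenotypic variance
    and a cross-environment genetic correlation of 0.5.  Testis-mass
    variances are expressed on a mean-consistent scale (the published
    table's variance scale is incompatible with its milligram means); the
    heritabilities are preserved.  Dissector-block effects are small and
    arbitrary -- the study does not report them -- and exist to exercise
    the block term.
    """
    if trait == "body_mass_mg":
        return TrueParameters(
            G=correlation_to_covariance((36.53, 0.97, 1.51), 0.5),
            sigma2_e=54.15,
            env_means=(23.51, 12.96, 12.29),
            block_effects={"d1": 0.0, "d2": 1.0, "d3": -1.0},
        )
    if trait == "femur_area_mm2":
        return TrueParameters(
            G=correlation_to_covariance((0.41, 0.005, 0.26), 0.5),
            sigma2_e=2.68,
            env_means=(7.14, 6.17, 4.86),
            block_effects={"d1": 0.0, "d2": 0.1, "d3": -0.1},
        )
    if trait == "testis_mass_mg":
        return TrueParameters(
            G=correlation_to_covariance((1.08e-4, 0.16e-4, 0.26e-4), 0.5),
            sigma2_e=4.00e-4,
            env_means=(0.20, 0.13, 0.13),
            block_effects={"d1": 0.0, "d2": 0.005, "d3": -0.005},
        )
    raise KeyError(f"no default parameters for trait {trait!r}")


DEFAULT_TRAITS = ("body_mass_mg", "femur_area_mm2", "testis_mass_mg")


def simulate_study(cfg: DesignConfig, truths: Optional[Mapping[str, TrueParameters]] = None):
    """Simulate all three traits on a single shared pedigree/design.

    Traits are simulated independently (no between-trait genetic or
    residual correlation): each trait gets its own breeding values and
    residuals, but the pedigree, environment and block assignments are
    shared so downstream stages see one coherent dataset.
    """
    if truths is None:
        truths = {t: default_truth(t) for t in DEFAULT_TRAITS}
    traits = list(truths)
    first = truths[traits[0]]
    ped, base = simulate_breeding_design(cfg, first)
    table = base.rename(columns={"value": traits[0]})
    for j, t in enumerate(traits[1:], start=1):
        # same design, fresh genetics and noise via a derived seed
        cfg_t = replace(cfg, seed=(cfg.seed + 77_003 * j) % (2**31 - 1))
        table[t] = _resimulate_values_on_design(cfg_t, truths[t], ped, table)
    cols = ["id", "environment", "block"] + traits + ["sire"]
    return ped, table[cols], truths


def _resimulate_values_on_design(
    cfg: DesignConfig, truth: TrueParameters, ped: Pedigree, table: pd.DataFrame
) -> np.ndarray:
    """Draw a fresh trait on an existing design (environments/blocks fixed)."""
    rng = np.random.default_rng(cfg.seed)
    m = len(cfg.env_labels)
    chol = _psd_cholesky(truth.G)
    a = np.zeros((len(ped), m))
    for i in range(len(ped)):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0 and di < 0:
            a[i] = chol @ rng.standard_normal(m)
        else:
            mid = 0.5 * (a[si] if si >= 0 else 0.0) + 0.5 * (a[di] if di >= 0 else 0.0)
            a[i] = mid + np.sqrt(0.5) * (chol @ rng.standard_normal(m))
    env_pos = {lab: k for k, lab in enumerate(cfg.env_labels)}
    env_idx = np.array([env_pos[e] for e in table["environment"]])
    pos = np.array([ped.index[i] for i in table["id"]])
    beff = np.array([truth.block_effects.get(b, 0.0) for b in table["block"]])
    mu = np.asarray(truth.env_means)[env_idx]
    g = a[pos, env_idx]
    sd = np.sqrt(truth.sigma2_e)
    y = mu + beff + g + sd * rng.standard_normal(len(table))
    if cfg.resample_nonpositive and sd > 0:
        bad = np.flatnonzero(y <= 0)
        tries = 0
        while bad.size and tries < 1000:
            y[bad] = mu[bad] + beff[bad] + g[bad] + sd * rng.standard_normal(bad.size)
            bad = bad[y[bad] <= 0]
            tries += 1
        if bad.size:
            raise RuntimeError("could not draw positive phenotypes; means too close to zero")
    return y
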