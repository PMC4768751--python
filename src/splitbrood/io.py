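"""Reading and writing the pipeline's delimited-text formats.

Pedigree CSV: header ``id,sire,dam``; unknown parents empty or ``0``.
Phenotype CSV: header ``id,environment,block,<trait columns...>``;
environment labels from {ripe, unripe, none} unless other levels are
declared; missing trait values empty.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_pedigree
from .simulate import ENV_LABELS, TrueParameters

FLOAT_FORMAT = "%.17g"  # full double precision: round-trip exact and deterministic


class SchemaError(ValueError):
    """A file does not conform to the declared CSV schema."""


def read_pedigree(path, allow_implicit_founders: bool = False) -> Pedigree:
    """Read a pedigree CSV (``id,sire,dam``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"{path}: pedigree header must contain {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    return build_pedigree(df[["id", "sire", "dam"]], allow_implicit_founders=allow_implicit_founders)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_phenotypes(
    path,
    traits: Optional[Sequence[str]] = None,
    env_labels: Sequence[str] = ENV_LABELS,
    normalize_case: bool = False,
) -> pd.DataFrame:
    """Read and validate a phenotype CSV.

    Every row must carry a unique id, an environment from ``env_labels``
    (case-normalised first when ``normalize_case``), and a block label.
    Trait columns are parsed as floats; empty cells become NaN.  Rows
    with unparseable numbers raise with their (1-based, header-inclusive)
    line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "environment", "block"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if traits is None:
        traits = [c for c in df.columns if c not in ("id", "environment", "block", "sire")]
    if not traits:
        raise SchemaError(f"{path}: no trait columns found")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"{path}: duplicate individual id {dup!r}")

    env = df["environment"].str.strip()
    if normalize_case:
        env = env.str.lower()
    bad = ~env.isin(list(env_labels))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(
            f"{path}: line {row}: unknown environment label "
            f"{df['environment'].iloc[row - 2]!r} (expected one of {tuple(env_labels)})"
        )
    df["environment"] = env

    for t in traits:
        if t not in df.columns:
            raise SchemaError(f"{path}: missing trait column {t!r}")
        raw = df[t].str.strip().replace("", np.nan)
        # pd.to_numeric's fast path is not correctly rounded; detect
        # malformed cells with it, then convert via Python float()
        probe = pd.to_numeric(raw, errors="coerce")
        malformed = probe.isna() & raw.notna()
        if malformed.any():
            row = int(np.flatnonzero(malformed.to_numpy())[0]) + 2
            raise SchemaError(
                f"{path}: line {row}: malformed value {raw.iloc[row - 2]!r} in column {t!r}"
            )
        df[t] = raw.astype(float)
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_truth(truths: dict, path) -> None:
    """JSON sidecar recording the true simulation parameters per trait."""
    doc = {}
    for trait, t in truths.items():
        doc[trait] = {
            "G": np.asarray(t.G).tolist(),
            "sigma2_e": float(t.sigma2_e),
            "env_means": list(t.env_means),
            "block_effects": dict(t.block_effects),
        }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    doc = json.loads(Path(path).read_text())
    return {
        trait: TrueParameters(
            G=np.asarray(d["G"]),
            sigma2_e=d["sigma2_e"],
            env_means=tuple(d["env_means"]),
            block_effects=d["block_effects"],
        )
        for trait, d in doc.items()
    }


def write_fit_json(fit, path) -> None:
    """Machine-readable fit report (components, vcov, convergence trace)."""
    doc = {
        "env_levels": list(fit.env_levels),
        "G": fit.components.G.tolist(),
        "sigma2_e": fit.components.sigma2_e,
        "reml_loglik": fit.reml_loglik,
        "vcov_components": np.asarray(fit.vcov_components).tolist(),
        "fixed_effects": fit.fixed_effects.to_dict(orient="records"),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "grad_norm": float(fit.grad_norm),
        "boundary": list(map(bool, fit.boundary)),
        "n_obs": int(fit.n_obs),
        "rank_X": int(fit.rank_X),
        "loglik_trace": list(fit.history),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_table(df: pd.DataFrame, path, rounding: Optional[int] = None) -> None:
    if rounding is not None:
        df = df.copy()
        num = df.select_dtypes(include=[np.number]).columns
        df[num] = df[num].round(rounding)
        df.to_csv(path, index=False)
    else:
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
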