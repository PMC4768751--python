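"""End-to-end orchestration: simulate (optionally) -> fit -> summarise -> scaling.

Outputs are deterministic for a fixed configuration and seed: CSVs are
written with a fixed float format and contain no timestamps; the run
metadata records the seed, package version and a hash of the canonical
configuration document.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

try:
    from importlib.metadata import version as _pkg_version

    _version = _pkg_version("splitbrood")
except Exception:  # pragma: no cover - not installed
    _version = "0+unknown"
from .genpar import genetic_correlations, table2_summary
from .io import (
    read_pedigree,
    read_phenotypes,
    write_fit_json,
    write_pedigree,
    write_phenotypes,
    write_table,
    write_truth,
)
from .pedigree import additive_relationship_matrix
from .reml import MixedModelSpec, REMLOptions, predicted_environment_means, reml_fit, wald_f_tests
from .scaling import scaling_battery
from .simulate import DesignConfig, ENV_LABELS, default_truth, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_TRAITS = ("body_mass_mg", "femur_area_mm2", "testis_mass_mg")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs, serialisable to a single YAML document."""

    out_dir: str = "splitbrood_run"
    mode: str = "synthetic"                  # "synthetic" or "analysis"
    pedigree_path: Optional[str] = None      # analysis mode inputs
    phenotype_path: Optional[str] = None
    traits: tuple = DEFAULT_TRAITS
    env_labels: tuple = ENV_LABELS
    seed: int = 1
    report_rounding: int = 2
    allow_implicit_founders: bool = False
    normalize_case: bool = False
    # REML options
    max_iter: int = 500
    em_iters: int = 20
    ll_tol: float = 1e-8
    grad_tol: float = 1e-4
    # simulation block (synthetic mode)
    n_sires: int = 35
    dams_per_sire: int = 3
    offspring_per_dam: int = 10
    missing_cell_rate: float = 0.01
    n_blocks: int = 3
    interaction_screen: float = 0.20

    def validate(self):
        if self.mode not in ("synthetic", "analysis"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        if self.mode == "analysis":
            for name in ("pedigree_path", "phenotype_path"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError(f"config: {name} is required in analysis mode")
                if not Path(p).exists():
                    raise PipelineError(f"config: {name} {p!r} does not exist")
        if self.mode == "synthetic" and self.seed is None:
            raise PipelineError("config: a seed is required in synthetic mode")

    def to_yaml(self, path=None) -> str:
        doc = yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        cfg = cls(**doc)
        for f in ("traits", "env_labels"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        doc = asdict(self)
        doc.pop("out_dir")
        return hashlib.sha256(
            json.dumps(_jsonable(doc), sort_keys=True).encode()
        ).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns a dict with the in-memory results: pedigree, phenotypes,
    per-trait fits, the genetic-parameter table and the scaling report.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # stage 1: data ----------------------------------------------------
    try:
        if cfg.mode == "synthetic":
            design = DesignConfig(
                n_sires=cfg.n_sires,
                dams_per_sire=cfg.dams_per_sire,
                offspring_per_dam=cfg.offspring_per_dam,
                env_labels=tuple(cfg.env_labels),
                missing_cell_rate=cfg.missing_cell_rate,
                n_blocks=cfg.n_blocks,
                resample_nonpositive=True,
                seed=cfg.seed,
            )
            truths = {t: default_truth(t) for t in cfg.traits}
            ped, pheno, truths = simulate_study(design, truths)
            write_pedigree(ped, out / "pedigree.csv")
            write_phenotypes(pheno.drop(columns=["sire"]), out / "phenotypes.csv")
            write_truth(truths, out / "truth.json")
        else:
            ped = read_pedigree(cfg.pedigree_path, cfg.allow_implicit_founders)
            pheno = read_phenotypes(
                cfg.phenotype_path,
                traits=list(cfg.traits),
                env_labels=cfg.env_labels,
                normalize_case=cfg.normalize_case,
            )
            unknown = set(pheno["id"]) - set(ped.ids)
            if unknown:
                raise PipelineError(
                    f"stage=data: {len(unknown)} phenotyped id(s) missing from the "
                    f"pedigree, e.g. {sorted(unknown)[:5]}"
                )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage=data: {e}") from e
    logger.info("data stage done (%.2fs, n=%d)", time.perf_counter() - t0, len(pheno))

    # stage 2: kinship + per-trait REML fits ---------------------------
    try:
        A = additive_relationship_matrix(ped)
        opts = REMLOptions(
            max_iter=cfg.max_iter,
            em_iters=cfg.em_iters,
            ll_tol=cfg.ll_tol,
            grad_tol=cfg.grad_tol,
            on_nonconvergence="warn",
        )
        fits, wald, means = {}, {}, {}
        for trait in cfg.traits:
            t1 = time.perf_counter()
            spec = MixedModelSpec(trait=trait, env_levels=tuple(cfg.env_labels))
            fit = reml_fit(pheno, A, spec, opts)
            fits[trait] = fit
            wald[trait] = wald_f_tests(fit)
            means[trait] = predicted_environment_means(fit)
            if any(fit.boundary):
                logger.warning(
                    "trait %s: genetic variance at the boundary in %s",
                    trait,
                    [e for e, b in zip(fit.env_levels, fit.boundary) if b],
                )
            logger.info(
                "fit %s: loglik=%.4f, %d iterations (%.2fs)",
                trait, fit.reml_loglik, fit.n_iter, time.perf_counter() - t1,
            )
            write_fit_json(fit, out / f"fit_{trait}.json")
            fit.blups.to_csv(out / f"blup_{trait}.csv", index=False, float_format="%.17g")
            write_table(wald[trait], out / f"wald_{trait}.csv")
            write_table(means[trait], out / f"adjusted_means_{trait}.csv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage=fit: {e}") from e

    # stage 3: genetic-parameter table ---------------------------------
    try:
        gp = table2_summary(fits, pheno)
        write_table(gp, out / "genetic_parameters.csv")
        write_table(gp, out / "genetic_parameters_rounded.csv", rounding=cfg.report_rounding)
        corrs = {
            t: genetic_correlations(f.components, f.boundary).to_dict()
            for t, f in fits.items()
        }
    except Exception as e:
        raise PipelineError(f"stage=summarise: {e}") from e

    # stage 4: trait expression and allometry --------------------------
    try:
        rep = scaling_battery(
            pheno, traits=cfg.traits, screening_threshold=cfg.interaction_screen
        )
        write_table(rep.table, out / "scaling_tests.csv")
        adj = []
        for (resp, cov), r in rep.ancovas.items():
            a = r.adjusted_means.copy()
            a.insert(0, "model", f"{resp}~{cov}")
            a["interaction_retained"] = r.interaction_retained
            adj.append(a)
        if adj:
            import pandas as pd

            write_table(pd.concat(adj, ignore_index=True), out / "scaling_adjusted_means.csv")
        letters = {t: rep.anovas[t].tukey_letters for t in cfg.traits}
    except Exception as e:
        raise PipelineError(f"stage=scaling: {e}") from e

    meta = {
        "package": "splitbrood",
        "version": _version,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_individuals": int(len(pheno)),
        "tukey_letters": letters,
        "genetic_correlations": _jsonable(corrs),
    }
    (out / "run_meta.json").write_text(json.dumps(_jsonable(meta), indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete in %.2fs", time.perf_counter() - t0)
    return {
        "pedigree": ped,
        "phenotypes": pheno,
        "fits": fits,
        "wald": wald,
        "adjusted_means": means,
        "genetic_parameters": gp,
        "scaling": rep,
        "meta": meta,
    }
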