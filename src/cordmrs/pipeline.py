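"""End-to-end orchestration: simulate → qc → cells → ewas → meta →
build-mrs → score → evaluate → associate, driven by one YAML/JSON config.

Every stage writes its artifacts under the output directory and records
them in a plain-JSON run manifest with sha256 hashes, the parameters and
the seed, so a rerun with the same config reproduces the artifacts
bit-identically. A single global seed is fanned out to per-stage seeds by
fixed offsets, so toggling one stage does not perturb another's draws.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import io as mio
from . import meta as metamod
from . import mrs as mrsmod
from . import qc as qcmod
from .ewas import run_ewas
from .simulate import CohortBundle, SimConfig, simulate_cohort, simulate_discovery_sumstats, write_fixture

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline"]

_STAGES = ("simulate", "qc", "cells", "ewas", "meta", "build_mrs", "score",
           "evaluate", "associate")

#: fixed per-stage seed offsets (global seed + offset, kept < 2^31)
_SEED_OFFSETS = {"simulate": 11, "discovery": 29, "evaluate": 47}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "mrs_run",
    "stages": {s: True for s in _STAGES},
    "qc": {"sample_thresh": 0.10, "probe_thresh": 0.10, "lo": 0.1, "hi": 0.9},
    "grid": {"n_lambda": 50, "n_alpha": 10},
    "bootstrap": {"n_boot": 2000},
    "discovery": {"n_discovery": 5000},
    "ewas": {"outcome": "current"},
    "sim": {},
    "cohorts": {
        "valid_european": {"population": "european", "n_samples": 400, "role": "validation"},
        "test_european": {"population": "european", "n_samples": 400, "role": "test"},
        "south_asian": {"population": "south_asian", "n_samples": 500, "role": "test"},
    },
}

_STAGE_DEPS = {
    "qc": ["simulate"],
    "cells": ["simulate"],
    "ewas": ["qc", "cells"],
    "meta": ["ewas"],
    "build_mrs": ["qc", "cells"],
    "score": ["build_mrs"],
    "evaluate": ["score"],
    "associate": ["score"],
}


@dataclasses.dataclass
class PipelineConfig:
    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def stage_enabled(self, name: str) -> bool:
        return bool(self.raw["stages"].get(name, False))


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config, filling defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise mio.ValidationError(f"{path}: config must be a mapping")
    if "cohorts" in data:
        merged = _merge({k: v for k, v in _DEFAULTS.items() if k != "cohorts"}, data)
    else:
        merged = _merge(_DEFAULTS, data)
    return PipelineConfig(raw=merged)


def validate_config(config: PipelineConfig | str | Path) -> dict:
    """Schema and cross-field checks; returns {errors: [...], warnings: [...]}."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    raw = config.raw
    errors: list[str] = []
    warnings: list[str] = []
    if "seed" not in raw or raw["seed"] is None:
        raw["seed"] = 0
        warnings.append("seed missing; defaulted to 0")
    qc = raw["qc"]
    for field in ("sample_thresh", "probe_thresh", "lo", "hi"):
        v = qc.get(field)
        if v is None or not 0 < v < 1:
            errors.append(f"qc.{field}: must lie in (0, 1), got {v!r}")
    for field, default in (("sample_thresh", 0.10), ("probe_thresh", 0.10),
                           ("lo", 0.1), ("hi", 0.9)):
        if qc.get(field) != default and f"qc.{field}" not in " ".join(errors):
            warnings.append(f"qc.{field}={qc.get(field)} differs from default {default}")
    grid = raw["grid"]
    for field, default in (("n_lambda", 50), ("n_alpha", 10)):
        v = grid.get(field)
        if not isinstance(v, int) or v < 1:
            errors.append(f"grid.{field}: must be a positive integer, got {v!r}")
        elif v != default:
            warnings.append(f"grid.{field}={v} differs from default {default}")
    nb = raw["bootstrap"].get("n_boot")
    if not isinstance(nb, int) or nb < 1:
        errors.append(f"bootstrap.n_boot: must be a positive integer, got {nb!r}")
    elif nb != 2000:
        warnings.append(f"bootstrap.n_boot={nb} differs from default 2000")
    nd = raw["discovery"].get("n_discovery")
    if not isinstance(nd, int) or nd <= 1:
        errors.append(f"discovery.n_discovery: must exceed 1, got {nd!r}")
    if raw["ewas"].get("outcome") not in ("current", "ever", "exposure"):
        errors.append(
            f"ewas.outcome: must be current/ever/exposure, got "
            f"{raw['ewas'].get('outcome')!r}"
        )
    roles = [c.get("role") for c in raw["cohorts"].values()]
    if "validation" not in roles:
        errors.append("exactly one cohort must have role 'validation'")
    for name in raw["stages"]:
        if name not in _STAGES:
            errors.append(f"unknown stage {name!r}")
    for stage, deps in _STAGE_DEPS.items():
        if config.stage_enabled(stage):
            for dep in deps:
                if not config.stage_enabled(dep):
                    errors.append(
                        f"stage '{stage}' requires stage '{dep}' (disabled): "
                        f"missing input"
                    )
    return {"errors": errors, "warnings": warnings}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    report = validate_config(config)
    if report["errors"]:
        raise mio.ValidationError("invalid config: " + "; ".join(report["errors"]))

    raw = config.raw
    seed = config.seed
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": seed, "parameters": copy.deepcopy(
            {k: v for k, v in raw.items() if k != "output_dir"}),
        "artifacts": {}, "warnings": report["warnings"],
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def fail(stage: str, msg: str) -> None:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {msg}")

    bundles: dict[str, CohortBundle] = {}
    sim_overrides = dict(raw["sim"])
    if config.stage_enabled("simulate"):
        for i, (name, spec) in enumerate(raw["cohorts"].items()):
            kw = dict(sim_overrides)
            kw.update({k: v for k, v in spec.items() if k not in ("population", "role")})
            kw.setdefault("structure_seed", seed + 1)
            kw["seed"] = seed + _SEED_OFFSETS["simulate"] + 101 * (i + 1)
            bundle = simulate_cohort(SimConfig(**kw), population=spec.get("population", "european"))
            bundle = dataclasses.replace(bundle, name=name)
            bundles[name] = bundle
            paths = write_fixture(bundle, outdir / name)
            for key, p in paths.items():
                record(f"{name}/{key}", p)

    clean: dict[str, pd.DataFrame] = {}
    if config.stage_enabled("qc"):
        if not bundles:
            fail("qc", "no simulated cohorts available")
        for name, bundle in bundles.items():
            sex = bundle.phenotypes.set_index("sample_id")["newborn_sex"]
            cleaned, rep = qcmod.run_qc(
                bundle.beta, bundle.manifest, reported_sex=sex, **raw["qc"]
            )
            clean[name] = cleaned
            rp = outdir / name / "qc_report.json"
            rp.write_text(json.dumps(rep.to_dict(), indent=1))
            cp = outdir / name / "beta_clean.tsv"
            mio.write_beta(cleaned, cp)
            record(f"{name}/qc_report", rp)
            record(f"{name}/beta_clean", cp)

    cells: dict[str, pd.DataFrame] = {}
    if config.stage_enabled("cells"):
        # generated proportions serve as the cell-composition covariates;
        # reference-based estimation is available via qc.estimate_cell_proportions
        for name, bundle in bundles.items():
            cells[name] = bundle.cell_props

    validation = next(
        n for n, s in raw["cohorts"].items() if s.get("role") == "validation"
    )
    europeans = [
        n for n, s in raw["cohorts"].items()
        if s.get("population", "european") == "european"
    ]

    ewas_tables: dict[str, pd.DataFrame] = {}
    if config.stage_enabled("ewas"):
        outcome = raw["ewas"]["outcome"]
        for name in europeans:
            table = run_ewas(clean[name], bundles[name].phenotypes, cells[name],
                             outcome=outcome)
            path = outdir / name / f"ewas_{outcome}.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.8g")
            ewas_tables[name] = table
            record(f"{name}/ewas_current", path)

    if config.stage_enabled("meta"):
        if len(ewas_tables) < 2:
            fail("meta", "needs EWAS tables from ≥ 2 cohorts")
        outcome = raw["ewas"]["outcome"]
        meta_table = metamod.meta_ewas(list(ewas_tables.values()))
        path = outdir / f"meta_{outcome}.tsv"
        meta_table.to_csv(path, sep="\t", index=False, float_format="%.8g")
        record(f"meta_{outcome}", path)

    model = None
    if config.stage_enabled("build_mrs"):
        bundle = bundles[validation]
        sumstats = simulate_discovery_sumstats(
            SimConfig(**{**sim_overrides, "structure_seed": seed + 1}),
            bundle.truth,
            n_discovery=raw["discovery"]["n_discovery"],
            seed=seed + _SEED_OFFSETS["discovery"],
        )
        sp = outdir / "sumstats.tsv"
        mio.write_sumstats(sumstats, sp)
        record("sumstats", sp)
        beta_v = clean[validation]
        panel = mrsmod.reference_correlation(
            mrsmod.standardize(beta_v)[0], source=validation
        )
        b = mrsmod.prepare_b(sumstats, panel.probe_ids)
        grid = mrsmod.TuningGrid.default(
            b, n_lambda=raw["grid"]["n_lambda"], n_alpha=raw["grid"]["n_alpha"]
        )
        qc_bundle = dataclasses.replace(bundles[validation], beta=beta_v)
        model, trace = mrsmod.tune(b, panel, qc_bundle, grid=grid,
                                   provenance=f"tuned on {validation}")
        mp, tp = outdir / "model.json", outdir / "tune_trace.tsv"
        mio.save_model(model, mp)
        trace.to_csv(tp, sep="\t", index=False, float_format="%.8g")
        record("model", mp)
        record("tune_trace", tp)

    scores: dict[str, pd.Series] = {}
    if config.stage_enabled("score"):
        if model is None:
            fail("score", "no fitted model")
        for name in raw["cohorts"]:
            s, n_used = mrsmod.score_samples(model, clean.get(name, bundles[name].beta))
            scores[name] = s
            path = outdir / name / "scores.csv"
            s.rename("mrs").to_csv(path, float_format="%.8g")
            record(f"{name}/scores", path)

    if config.stage_enabled("evaluate"):
        results = {}
        for name in europeans:
            if bundles[name].phenotypes["current_smoker"].sum() == 0:
                continue
            rep = ev.evaluate_scores(
                scores[name], bundles[name].phenotypes,
                n_boot=raw["bootstrap"]["n_boot"],
                seed=seed + _SEED_OFFSETS["evaluate"],
            )
            results[name] = rep.to_dict()
        path = outdir / "evaluation.json"
        path.write_text(json.dumps(results, indent=1))
        record("evaluation", path)

    if config.stage_enabled("associate"):
        phenos = {n: b.phenotypes for n, b in bundles.items()}
        assoc = ev.assoc_outcomes(scores, phenos)
        path = outdir / "assoc.tsv"
        assoc.to_csv(path, sep="\t", index=False, float_format="%.8g")
        record("assoc", path)

    mpath = outdir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
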