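"""Synthetic two-population birth cohorts with the statistical structure the
maternal-smoking methylation analysis assumes.

The generator emulates the design of paired European-origin birth cohorts
(~5% current smokers) and a South-Asian-origin cohort (~0% smokers):

* **β-values** are logit-normal: a per-probe baseline on the logit scale
  plus cell-composition confounding, a smoking effect at causal CpGs, and
  block-AR(1) correlated noise (a stand-in for local co-methylation),
  mapped through the inverse logit so every value lies in (0, 1).
* **Latent smoke burden** ``u_i = smoking_history_i + η_i`` with
  ``η_i ~ N(0, burden_sd)`` models passive/unreported exposure. Causal
  CpGs shift by ``delta × u`` (signed per probe); newborn size and weight
  decline with ``u``. Because η varies even where nobody actively smokes,
  a methylation score can associate with birth outcomes in the
  zero-prevalence cohort — the portability phenomenon the analysis tests.
* **Exposure hours** are zero-inflated log-normal, skewed right, with both
  the nonzero probability and the magnitude increasing in ``u``.
* **Cell composition** is Dirichlet with means loosely matching published
  cord-blood proportions and enters every CpG through random loadings,
  a confounder the EWAS must adjust away.

Structural parameters (probe baselines, causal set, cell loadings,
manifest) are drawn from ``structure_seed`` so that several cohorts can
share one generative model while their samples differ (``seed``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio

__all__ = [
    "SimConfig",
    "CohortBundle",
    "simulate_cohort",
    "simulate_discovery_sumstats",
    "write_fixture",
    "read_truth",
    "PREVALENCE_EUROPEAN",
    "PREVALENCE_SOUTH_ASIAN",
]

#: smoking-history prevalence (never, quit-before, quit-during, current),
#: matching the published European epigenetic subsample (~5% current) and
#: the South Asian cohort (~0% current, ~0.4% ever).
PREVALENCE_EUROPEAN = (0.67, 0.175, 0.10, 0.055)
PREVALENCE_SOUTH_ASIAN = (0.994, 0.003, 0.003, 0.0)

_POPULATIONS = ("european", "south_asian")

#: Dirichlet concentration for (CD8T, CD4T, NK, Bcell, Mono, Gran, nRBC)
_CELL_ALPHA = (1.0, 11.0, 2.0, 2.0, 1.0, 60.0, 8.0)


@dataclasses.dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    delta is the logit-β shift per unit of latent smoke burden at causal
    CpGs; outcome_effect is kg of birth weight lost per burden unit (birth
    length uses 3× this value, in cm).
    """

    n_samples: int = 400
    n_cpgs: int = 1000
    block_size: int = 10
    block_rho: float = 0.4
    n_causal: int = 20
    delta: float = 0.25
    smoker_prevalence: tuple[float, float, float, float] | None = None
    exposure_zero_fraction: float = 0.8
    outcome_effect: float = 0.15
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0
    # structural knobs shared across cohorts of one "study"
    structure_seed: int = 1000
    burden_sd: float = 0.5
    cell_alpha: tuple[float, ...] = _CELL_ALPHA
    cell_effect_sd: float = 2.0
    sex_effect: float = 1.5
    mask_rate: float = 0.02
    x_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_cpgs", "block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_cpgs:
            raise ValueError("n_causal must lie in [0, n_cpgs]")
        if not -1 < self.block_rho < 1:
            raise ValueError("block_rho must lie in (-1, 1)")
        if self.smoker_prevalence is not None:
            _check_prevalence(self.smoker_prevalence)
        for name in ("exposure_zero_fraction", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _check_prevalence(prev: Sequence[float]) -> None:
    prev = np.asarray(prev, dtype=float)
    if prev.shape != (4,) or (prev < 0).any() or abs(prev.sum() - 1) > 1e-8:
        raise ValueError(
            "smoker_prevalence must be 4 nonnegative fractions summing to 1"
        )


@dataclasses.dataclass
class CohortBundle:
    """One simulated cohort: β matrix, phenotypes, cell proportions,
    manifest, and the simulation truth (causal CpGs, signs, burden)."""

    name: str
    beta: pd.DataFrame
    phenotypes: pd.DataFrame
    cell_props: pd.DataFrame
    manifest: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        ids = list(self.beta.columns)
        if list(self.phenotypes["sample_id"]) != ids:
            raise ValueError("phenotype sample ids disagree with β matrix")
        if list(self.cell_props["sample_id"]) != ids:
            raise ValueError("cell-proportion sample ids disagree with β matrix")


# ---------------------------------------------------------------------------
# structural (probe-level) model shared across cohorts


def _structure(config: SimConfig) -> dict:
    rng = np.random.default_rng(config.structure_seed)
    p = config.n_cpgs
    probe_ids = [f"cg{j:06d}" for j in range(p)]
    n_blocks = int(np.ceil(p / config.block_size))
    # whole blocks are assigned to chromosomes; a small fraction to X
    n_x_blocks = int(round(config.x_fraction * n_blocks))
    block_chrom = np.array(
        ["X"] * n_x_blocks + [str(1 + b % 22) for b in range(n_blocks - n_x_blocks)]
    )
    rng.shuffle(block_chrom)
    block_of = np.arange(p) // config.block_size
    chrom = block_chrom[block_of]
    position = 1 + (np.arange(p) % config.block_size) * 500 + block_of * 100_000
    mask = rng.random(p) < config.mask_rate
    baseline = rng.uniform(-1.8, 1.8, size=p)
    loadings = rng.normal(0.0, config.cell_effect_sd, size=(p, len(config.cell_alpha)))
    eligible = np.flatnonzero((chrom != "X") & ~mask)
    if config.n_causal > len(eligible):
        raise ValueError("n_causal exceeds the number of autosomal unmasked probes")
    causal_idx = np.sort(rng.choice(eligible, size=config.n_causal, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)
    gene = np.array([""] * p, dtype=object)
    gene[causal_idx] = [f"GENE{k}" for k in range(config.n_causal)]
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chrom,
            "position": position,
            "gene": gene,
            "mask": mask,
        }
    )
    return {
        "probe_ids": probe_ids,
        "manifest": manifest,
        "baseline": baseline,
        "loadings": loadings,
        "causal_idx": causal_idx,
        "signs": signs,
        "block_of": block_of,
    }


def _block_ar1_noise(
    rng: np.random.Generator, block_of: np.ndarray, n: int, rho: float, sd: float
) -> np.ndarray:
    """Probe × sample noise, AR(1) with parameter rho within each block."""
    p = len(block_of)
    e = rng.normal(0.0, 1.0, size=(p, n))
    z = np.empty_like(e)
    scale = np.sqrt(1.0 - rho**2)
    z[0] = e[0]
    for j in range(1, p):
        if block_of[j] == block_of[j - 1]:
            z[j] = rho * z[j - 1] + scale * e[j]
        else:
            z[j] = e[j]
    return sd * z


def _zero_inflated_exposure(
    rng: np.random.Generator, u: np.ndarray, zero_fraction: float
) -> np.ndarray:
    base = logit(np.clip(1.0 - zero_fraction, 1e-6, 1 - 1e-6))
    p_nonzero = expit(base + 0.8 * u)
    nonzero = rng.random(len(u)) < p_nonzero
    hours = np.where(
        nonzero, rng.lognormal(mean=np.log(2.0) + 0.5 * np.clip(u, 0, None), sigma=1.0), 0.0
    )
    return np.round(hours, 2)


def simulate_cohort(config: SimConfig, population: str = "european") -> CohortBundle:
    """Draw one cohort from the shared generative model.

    population selects the default smoking prevalence and the baseline
    anthropometry (South-Asian newborns are lighter with shorter
    gestation, mirroring the published cohort contrasts); an explicit
    ``config.smoker_prevalence`` overrides the default.
    """
    if population not in _POPULATIONS:
        raise ValueError(f"population must be one of {_POPULATIONS}")
    prev = config.smoker_prevalence
    if prev is None:
        prev = PREVALENCE_EUROPEAN if population == "european" else PREVALENCE_SOUTH_ASIAN
    _check_prevalence(prev)

    struct = _structure(config)
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_cpgs
    sample_ids = [f"{population[:2].upper()}{config.seed}_{i:04d}" for i in range(n)]

    history = rng.choice(4, size=n, p=np.asarray(prev, dtype=float))
    burden = history + rng.normal(0.0, config.burden_sd, size=n)
    female = rng.random(n) < 0.5

    k_cells = len(config.cell_alpha)
    props = rng.dirichlet(np.asarray(config.cell_alpha, dtype=float), size=n)
    mean_props = np.asarray(config.cell_alpha) / np.sum(config.cell_alpha)

    logits = np.tile(struct["baseline"][:, None], (1, n))
    logits += struct["loadings"] @ (props - mean_props).T
    x_probes = (struct["manifest"]["chromosome"] == "X").to_numpy()
    logits[np.ix_(x_probes, female)] += config.sex_effect
    causal, signs = struct["causal_idx"], struct["signs"]
    logits[causal] += config.delta * signs[:, None] * burden[None, :]
    logits += _block_ar1_noise(rng, struct["block_of"], n, config.block_rho, config.noise_sd)
    beta_vals = expit(logits)

    if config.missing_rate > 0:
        miss = rng.random((p, n)) < config.missing_rate
        beta_vals = np.where(miss, np.nan, beta_vals)

    beta = pd.DataFrame(beta_vals, index=struct["probe_ids"], columns=sample_ids)
    beta.index.name = "probe_id"

    sa = population == "south_asian"
    exposure = _zero_inflated_exposure(rng, burden, config.exposure_zero_fraction)
    ga = 39.4 - 0.05 * burden + rng.normal(0, 1.35, n)
    bw = (3.26 if sa else 3.50) - config.outcome_effect * burden + rng.normal(0, 0.35, n)
    bl = (51.4 if sa else 51.0) - 3 * config.outcome_effect * burden + rng.normal(0, 1.8, n)
    bw = np.clip(bw, 1.0, None)
    bl = np.clip(bl, 40.0, None)
    bmi = bw / (bl / 100.0) ** 2
    ponderal = bw / (bl / 100.0) ** 3

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "smoking_history": history.astype(float),
            "current_smoker": (history == 3).astype(float),
            "ever_smoker": (history >= 1).astype(float),
            "exposure_hours": exposure,
            "maternal_age": np.round(rng.normal(30.1 if sa else 32.3, 4.5, n), 1),
            "education_years": np.round(rng.normal(15.8 if sa else 16.9, 3.0, n), 1),
            "sdi": np.round(0.3 * burden + rng.normal(0, 1, n), 3),
            "gdm": (rng.random(n) < (0.36 if sa else 0.10)).astype(float),
            "parity": np.minimum(rng.poisson(0.8, n), 5).astype(float),
            "newborn_sex": female.astype(float),  # 1 = female
            "gestational_age": np.round(ga, 1),
            "birth_weight": np.round(bw, 3),
            "birth_length": np.round(bl, 1),
            "newborn_bmi": np.round(bmi, 2),
            "ponderal_index": np.round(ponderal, 2),
        }
    )
    # early-childhood follow-up, linked to the same latent burden
    pheno["height_1y"] = np.round(75.5 - 0.5 * burden + rng.normal(0, 2.5, n), 1)
    pheno["height_2y"] = np.round(87.0 - 0.6 * burden + rng.normal(0, 3.0, n), 1)
    pheno["height_5y"] = np.round(109.0 - 0.7 * burden + rng.normal(0, 4.0, n), 1)
    pheno["weight_1y"] = np.round(9.6 - 0.15 * burden + rng.normal(0, 1.1, n), 2)
    pheno["weight_3y"] = np.round(14.5 - 0.2 * burden + rng.normal(0, 1.6, n), 2)
    pheno["weight_5y"] = np.round(18.5 - 0.25 * burden + rng.normal(0, 2.3, n), 2)
    pheno["skinfold_3y"] = np.round(15.0 + 0.3 * burden + rng.normal(0, 2.5, n), 1)
    pheno["skinfold_5y"] = np.round(15.5 + 0.35 * burden + rng.normal(0, 3.0, n), 1)
    pheno["exposure_1y"] = _zero_inflated_exposure(rng, 0.8 * burden, config.exposure_zero_fraction)
    pheno["exposure_3y"] = _zero_inflated_exposure(rng, 0.8 * burden, config.exposure_zero_fraction)
    pheno["allergy_5y"] = (rng.random(n) < expit(-1.8 + 0.1 * burden)).astype(float)
    for visit in (1, 2, 3, 5):
        pheno[f"child_age_{visit}y"] = np.round(visit + rng.normal(0, 0.08, n), 2)

    cell_props = pd.DataFrame(props, columns=list(mio.CELL_TYPES)[:k_cells])
    cell_props.insert(0, "sample_id", sample_ids)

    truth = {
        "population": population,
        "causal_probes": [struct["probe_ids"][j] for j in causal],
        "signs": signs.tolist(),
        "delta": config.delta,
        "noise_sd": config.noise_sd,
        "burden": dict(zip(sample_ids, np.round(burden, 6).tolist())),
    }
    return CohortBundle(
        name=f"{population}_{config.seed}",
        beta=beta,
        phenotypes=pheno,
        cell_props=cell_props,
        manifest=struct["manifest"],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# discovery summary statistics


def simulate_discovery_sumstats(
    config: SimConfig, truth: dict, n_discovery: int, seed: int | None = None
) -> pd.DataFrame:
    """Emulate an external discovery EWAS over all probes of the model.

    Per-CpG effect = true effect + N(0, se) with se = noise_sd/√n_discovery,
    so causal Wald z grows like √n while null effects stay zero-centred;
    p-values are two-sided normal.
    """
    if n_discovery <= 1:
        raise ValueError("n_discovery must exceed 1")
    struct = _structure(config)
    rng = np.random.default_rng(config.seed + 91 if seed is None else seed)
    p = config.n_cpgs
    true_effect = np.zeros(p)
    causal_ids = truth["causal_probes"]
    idx = {pid: j for j, pid in enumerate(struct["probe_ids"])}
    for pid, s in zip(causal_ids, truth["signs"]):
        true_effect[idx[pid]] = truth["delta"] * s
    se = np.full(p, config.noise_sd / np.sqrt(n_discovery))
    effect = true_effect + rng.normal(0.0, se)
    from scipy.stats import norm

    z = effect / se
    pvals = np.clip(2 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "probe_id": struct["probe_ids"],
            "effect": effect,
            "se": se,
            "p": pvals,
            "n": n_discovery,
        }
    )


# ---------------------------------------------------------------------------
# fixtures


def write_fixture(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write one cohort as the standard fixture file set.

    Emits beta.tsv, phenotypes.csv, cells.csv, manifest.tsv, truth.json
    (formats of :mod:`cordmrs.io`); returns the path map.
    """
    if bundle.beta.shape[1] == 0:
        raise ValueError("refusing to write a bundle with zero samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "phenotypes": directory / "phenotypes.csv",
        "cells": directory / "cells.csv",
        "manifest": directory / "manifest.tsv",
        "truth": directory / "truth.json",
    }
    mio.write_beta(bundle.beta, paths["beta"])
    mio.write_phenotypes(bundle.phenotypes, paths["phenotypes"])
    mio.write_cells(bundle.cell_props, paths["cells"])
    mio.write_manifest(bundle.manifest, paths["manifest"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=1))
    return paths


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
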