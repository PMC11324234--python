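"""Inverse-variance fixed-effect meta-analysis with Cochran's Q.

Weights w_i = 1/se_i²; pooled effect = Σw b / Σw with SE (Σw)^{-1/2} and a
two-sided normal p. Heterogeneity: Q = Σ w (b − pooled)² on χ² with k−1
degrees of freedom. Only the fixed-effect model is provided; heterogeneity
is reported for the caller to judge, never used to filter.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .ewas import bh_fdr

__all__ = ["MetaResult", "ivw_fixed", "cochran_q", "meta_ewas"]


@dataclasses.dataclass
class MetaResult:
    fixed_effect: float
    se: float
    p: float
    k: int
    het_q: float | None = None
    het_p: float | None = None


def ivw_fixed(effects: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Pool k study effects by inverse-variance weighting."""
    b = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0 or b.shape != s.shape:
        raise ValueError("effects and ses must be equal-length, non-empty")
    if np.any(~(s > 0)):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    effect = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = effect / se
    p = float(2 * norm.sf(abs(z)))
    res = MetaResult(fixed_effect=effect, se=se, p=p, k=int(b.size))
    if b.size >= 2:
        res.het_q, res.het_p = cochran_q(b, s, effect)
    return res


def cochran_q(
    effects: Sequence[float], ses: Sequence[float], fixed_effect: float
) -> tuple[float, float]:
    """Cochran's heterogeneity Q and its χ²_{k−1} p-value."""
    b = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("heterogeneity needs k ≥ 2 studies")
    w = 1.0 / s**2
    q = float(np.sum(w * (b - fixed_effect) ** 2))
    p = float(chi2.sf(q, df=b.size - 1))
    return q, p


def meta_ewas(
    tables: Sequence[pd.DataFrame], common_probes_only: bool = True
) -> pd.DataFrame:
    """Meta-analyse per-cohort EWAS tables probe-by-probe.

    Probe sets are intersected (probes with missing effect/SE in a cohort
    are treated as absent there); BH-FDR is computed over exactly the
    meta-analysed probes.
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs ≥ 2 cohort tables")
    cleaned = []
    for t in tables:
        c = t.dropna(subset=["effect", "se"]).set_index("probe_id")
        cleaned.append(c)
    common = cleaned[0].index
    for c in cleaned[1:]:
        common = common.intersection(c.index)
    if len(common) == 0:
        raise ValueError("no probes are shared across all cohorts")
    if not common_probes_only:  # union mode: pool whatever studies have a probe
        common = cleaned[0].index
        for c in cleaned[1:]:
            common = common.union(c.index)

    rows = []
    for probe in common:
        b = [c.loc[probe, "effect"] for c in cleaned if probe in c.index]
        s = [c.loc[probe, "se"] for c in cleaned if probe in c.index]
        res = ivw_fixed(b, s)
        rows.append(
            [probe, res.fixed_effect, res.se, res.p, res.het_q, res.het_p, res.k]
        )
    out = pd.DataFrame(
        rows, columns=["probe_id", "fixed_effect", "se", "p", "het_q", "het_p", "k"]
    )
    out["fdr_p"] = bh_fdr(out["p"].to_numpy())
    return out
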