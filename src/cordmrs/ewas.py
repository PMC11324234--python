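"""Per-CpG association of methylation with maternal smoking phenotypes.

The regression is "reversed" relative to classic EWAS: the smoking
phenotype is the outcome and the methylation β-value the predictor, which
lets per-CpG marginal effects be combined additively into a score later.
Models:

* ``logistic_current`` — current smoker (history 3 vs {0,1,2}), logistic;
* ``logistic_ever``    — ever smoker ({1,2,3} vs 0), logistic;
* ``linear_exposure``  — weekly smoking-exposure hours, linear; the
  outcome is rank-inverse-normal transformed (Blom offset 3/8) by default
  because the raw hours are highly skewed and zero-inflated; a raw-scale
  fit is available as a sensitivity option.

Covariates follow the published specification: estimated cord-blood cell
proportions (one granulocyte column dropped to break the sum-to-one
collinearity), maternal age, social disadvantage index, education years,
GDM, and parity. Wald effect/SE/p for the methylation term are reported,
with Benjamini–Hochberg FDR and a genomic-inflation diagnostic λ.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri
from scipy.stats import chi2, rankdata
from statsmodels.stats.multitest import multipletests

from .io import CELL_TYPES

__all__ = [
    "rank_inverse_normal",
    "run_ewas",
    "bh_fdr",
    "inflation_lambda",
    "DEFAULT_COVARIATES",
    "OUTCOME_MODELS",
]

DEFAULT_COVARIATES = ("maternal_age", "sdi", "education_years", "gdm", "parity")

#: cell column dropped from covariates to break sum-to-one collinearity
_DROPPED_CELL = "Gran"

OUTCOME_MODELS = {
    "current": ("current_smoker", "logistic_current"),
    "ever": ("ever_smoker", "logistic_ever"),
    "exposure": ("exposure_hours", "linear_exposure"),
}


def rank_inverse_normal(x: np.ndarray | pd.Series, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform z = Φ⁻¹((r−c)/(n−2c+1)).

    Ties get average ranks; missing values propagate. With all values
    identical the transform is undefined and zeros are returned.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("rank-inverse-normal needs ≥ 3 non-missing values")
    vals = x[obs]
    if np.all(vals == vals[0]):
        import warnings

        warnings.warn("all values identical; rank-INT returns zeros")
        out[obs] = 0.0
        return out
    r = rankdata(vals, method="average")
    out[obs] = ndtri((r - offset) / (n - 2 * offset + 1))
    return out


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ≤ 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # 0.4549...


def inflation_lambda(p: Sequence[float]) -> float:
    """Genomic inflation λ: median observed χ²₁ statistic / null median."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 50:
        raise ValueError("λ needs ≥ 50 p-values")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / _CHI2_1_MEDIAN)


# ---------------------------------------------------------------------------


def _covariate_matrix(
    pheno: pd.DataFrame, cells: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    cov = pheno.set_index("sample_id")[list(covariates)]
    cell_cols = [c for c in CELL_TYPES if c != _DROPPED_CELL and c in cells.columns]
    cell = cells.set_index("sample_id")[cell_cols]
    return cov.join(cell, how="inner")


def run_ewas(
    beta: pd.DataFrame,
    pheno: pd.DataFrame,
    cells: pd.DataFrame,
    outcome: str = "current",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    raw_exposure: bool = False,
) -> pd.DataFrame:
    """Fit outcome ~ methylation + covariates + cell proportions per CpG.

    Returns a table with probe_id, effect, se, p, fdr_p, n_used, model,
    flag. Probes with perfect separation, non-convergence, or zero
    variance are flagged and carry missing effect/SE/p (excluded from the
    FDR family).
    """
    if outcome not in OUTCOME_MODELS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_MODELS)}")
    ycol, model_label = OUTCOME_MODELS[outcome]
    if raw_exposure and outcome != "exposure":
        raise ValueError("raw_exposure applies only to the exposure outcome")

    covs = _covariate_matrix(pheno, cells, covariates)
    y_all = pheno.set_index("sample_id")[ycol]
    base = covs.join(y_all.rename("__y__"), how="inner").dropna()
    samples = base.index.intersection(beta.columns)
    base = base.loc[samples]
    logistic = model_label.startswith("logistic")
    if logistic and base["__y__"].nunique() < 2:
        raise ValueError(f"outcome {ycol!r} has fewer than 2 classes")

    if model_label == "linear_exposure" and not raw_exposure:
        base = base.assign(__y__=rank_inverse_normal(base["__y__"].to_numpy()))

    rows = []
    X_base = sm.add_constant(base.drop(columns="__y__"), has_constant="add")
    y = base["__y__"].to_numpy(dtype=float)
    for probe in beta.index:
        meth = beta.loc[probe, base.index].astype(float)
        ok = meth.notna().to_numpy()
        n_used = int(ok.sum())
        flag = ""
        eff = se = pval = np.nan
        if n_used < X_base.shape[1] + 1:
            flag = "insufficient_n"
        elif np.nanstd(meth.to_numpy()) == 0:
            flag = "zero_variance"
        else:
            X = X_base.loc[ok].copy()
            X.insert(1, "meth", meth[ok].to_numpy())
            yy = y[ok]
            try:
                if logistic:
                    with np.errstate(all="ignore"):
                        fit = sm.Logit(yy, X).fit(disp=0, maxiter=200)
                    if not fit.mle_retvals.get("converged", True):
                        flag = "not_converged"
                else:
                    fit = sm.OLS(yy, X).fit()
                eff = float(fit.params["meth"])
                se = float(fit.bse["meth"])
                pval = float(fit.pvalues["meth"])
                if not np.isfinite(se) or se <= 0 or se > 1e4:
                    flag = flag or "unstable_se"
                    eff = se = pval = np.nan
            except (np.linalg.LinAlgError, ValueError, Exception) as exc:
                # statsmodels raises PerfectSeparationError (subclass of
                # Exception) for separated logistic fits
                flag = type(exc).__name__
                eff = se = pval = np.nan
        rows.append([probe, eff, se, pval, n_used, model_label, flag])

    out = pd.DataFrame(
        rows, columns=["probe_id", "effect", "se", "p", "n_used", "model", "flag"]
    )
    out["fdr_p"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "fdr_p"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out[["probe_id", "effect", "se", "p", "fdr_p", "n_used", "model", "flag"]]
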