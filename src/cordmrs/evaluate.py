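"""Evaluation of a methylation risk score against smoking phenotypes and
newborn/child outcomes.

Discrimination is summarized by the Mann–Whitney AUC with a percentile
bootstrap confidence interval (2000 resamples by default); dose–response
across the four smoking-history categories uses a one-way ANOVA F-test
plus Welch t-tests of each category against never-smokers. Outcome
associations are per-cohort linear (continuous) or logistic (binary)
regressions of the outcome on the MRS — adjusting for the child's age at
the relevant visit where applicable — meta-analysed across cohorts by
inverse-variance fixed effect, with BH-FDR over the meta-analysed outcome
family. Cohort descriptive comparisons mirror the usual Table-1 tests
(ANOVA/t for continuous, chi-square for categorical with the
expected-count<5 exclusion rule).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, f_oneway, rankdata, ttest_ind

from .ewas import bh_fdr
from .meta import ivw_fixed

__all__ = [
    "EvalReport",
    "auc_mw",
    "bootstrap_auc_ci",
    "dose_response",
    "evaluate_scores",
    "assoc_outcomes",
    "cohort_compare",
    "score_correlations",
    "DEFAULT_OUTCOMES",
]

#: outcome label → (phenotype column, model kind, child-age column or None)
DEFAULT_OUTCOMES: dict[str, tuple[str, str, str | None]] = {
    "smoking_exposure": ("exposure_hours", "linear", None),
    "gestational_age": ("gestational_age", "linear", None),
    "birth_weight": ("birth_weight", "linear", None),
    "birth_length": ("birth_length", "linear", None),
    "newborn_bmi": ("newborn_bmi", "linear", None),
    "ponderal_index": ("ponderal_index", "linear", None),
    "height_1y": ("height_1y", "linear", "child_age_1y"),
    "height_2y": ("height_2y", "linear", "child_age_2y"),
    "height_5y": ("height_5y", "linear", "child_age_5y"),
    "weight_1y": ("weight_1y", "linear", "child_age_1y"),
    "weight_3y": ("weight_3y", "linear", "child_age_3y"),
    "weight_5y": ("weight_5y", "linear", "child_age_5y"),
    "skinfold_3y": ("skinfold_3y", "linear", "child_age_3y"),
    "skinfold_5y": ("skinfold_5y", "linear", "child_age_5y"),
    "exposure_1y": ("exposure_1y", "linear", "child_age_1y"),
    "exposure_3y": ("exposure_3y", "linear", "child_age_3y"),
    "allergy_5y": ("allergy_5y", "logistic", "child_age_5y"),
}


def auc_mw(score: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann–Whitney U statistic / (n₁·n₀); ties count 0.5."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(score)
    u = float(np.sum(r[labels == 1]) - n1 * (n1 + 1) / 2)
    return u / (n1 * n0)


def bootstrap_auc_ci(
    score: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over resampled samples.

    Resamples that lack one of the classes are redrawn. Reproducible from
    the seed.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    if np.sum(labels == 1) == 0 or np.sum(labels == 0) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n = len(score)
    aucs = np.empty(n_boot)
    done = 0
    while done < n_boot:
        take = min(n_boot - done, 512)
        idx = rng.integers(0, n, size=(take, n))
        lab = labels[idx]
        n1 = lab.sum(axis=1)
        valid = (n1 > 0) & (n1 < n)
        if not valid.any():
            continue
        idx, lab, n1 = idx[valid], lab[valid], n1[valid]
        r = rankdata(score[idx], axis=1)
        u = (r * (lab == 1)).sum(axis=1) - n1 * (n1 + 1) / 2
        vals = u / (n1 * (n - n1))
        aucs[done : done + len(vals)] = vals
        done += len(vals)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def dose_response(
    score: Sequence[float], smoking_history: Sequence[float]
) -> tuple[float, dict[int, float], list[int]]:
    """One-way ANOVA F-test across smoking-history categories plus Welch
    t-tests of each category against never-smokers (category 0).

    Returns (anova_p, {category: p vs never}, skipped categories with < 2
    samples).
    """
    score = np.asarray(score, dtype=float)
    hist = np.asarray(smoking_history, dtype=float)
    obs = ~(np.isnan(score) | np.isnan(hist))
    score, hist = score[obs], hist[obs]
    groups, skipped = {}, []
    for cat in sorted(set(hist.astype(int))):
        vals = score[hist == cat]
        if len(vals) < 2:
            skipped.append(int(cat))
        else:
            groups[int(cat)] = vals
    if len(groups) < 2:
        raise ValueError("need ≥ 2 categories with ≥ 2 samples")
    anova_p = float(f_oneway(*groups.values()).pvalue)
    pairwise = {}
    if 0 in groups:
        for cat, vals in groups.items():
            if cat == 0:
                continue
            pairwise[cat] = float(ttest_ind(vals, groups[0], equal_var=False).pvalue)
    return anova_p, pairwise, skipped


@dataclasses.dataclass
class EvalReport:
    """MRS performance summary against the smoking phenotypes."""

    auc: float
    auc_ci: tuple[float, float]
    anova_f_p: float
    pairwise_t_p: dict[int, float]
    or_per_unit: float
    or_ci: tuple[float, float]
    adj_r2: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_scores(
    score: pd.Series,
    pheno: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    continuous: Sequence[str] = ("smoking_history", "exposure_hours"),
) -> EvalReport:
    """Evaluate one cohort's scores: AUC (+bootstrap CI) for current
    smoking, dose–response, OR per score unit, adjusted R² for continuous
    smoking measures."""
    df = pheno.set_index("sample_id").join(score.rename("mrs"), how="inner")
    cc = df.dropna(subset=["mrs", "current_smoker", "smoking_history"])
    labels = cc["current_smoker"].to_numpy().astype(int)
    s = cc["mrs"].to_numpy()
    auc = auc_mw(s, labels)
    ci = bootstrap_auc_ci(s, labels, n_boot=n_boot, seed=seed)
    anova_p, pairwise, _ = dose_response(s, cc["smoking_history"].to_numpy())
    X = sm.add_constant(pd.DataFrame({"mrs": s}, index=cc.index))
    logit = sm.Logit(labels, X).fit(disp=0)
    coef, bse = logit.params["mrs"], logit.bse["mrs"]
    or_unit = float(np.exp(coef))
    or_ci = (float(np.exp(coef - 1.96 * bse)), float(np.exp(coef + 1.96 * bse)))
    adj = {}
    for col in continuous:
        sub = df.dropna(subset=["mrs", col])
        Xc = sm.add_constant(sub[["mrs"]])
        adj[col] = float(sm.OLS(sub[col], Xc).fit().rsquared_adj)
    return EvalReport(
        auc=auc, auc_ci=ci, anova_f_p=anova_p, pairwise_t_p=pairwise,
        or_per_unit=or_unit, or_ci=or_ci, adj_r2=adj, n=int(len(cc)),
    )


# ---------------------------------------------------------------------------
# outcome associations with cross-cohort meta-analysis


def _fit_outcome(
    score: pd.Series, pheno: pd.DataFrame, column: str, kind: str, age_col: str | None
) -> tuple[float, float, float, int] | None:
    df = pheno.set_index("sample_id").join(score.rename("mrs"), how="inner")
    cols = ["mrs", column] + ([age_col] if age_col else [])
    if column not in df.columns or (age_col and age_col not in df.columns):
        return None
    cc = df.dropna(subset=cols)
    if len(cc) < 10:
        return None
    X = sm.add_constant(cc[["mrs"] + ([age_col] if age_col else [])])
    y = cc[column].to_numpy(dtype=float)
    try:
        if kind == "logistic":
            if len(np.unique(y)) < 2:
                return None
            fit = sm.Logit(y, X).fit(disp=0)
        else:
            fit = sm.OLS(y, X).fit()
    except Exception:
        return None
    return (
        float(fit.params["mrs"]),
        float(fit.bse["mrs"]),
        float(fit.pvalues["mrs"]),
        int(len(cc)),
    )


def assoc_outcomes(
    scores: Mapping[str, pd.Series],
    phenotypes: Mapping[str, pd.DataFrame],
    outcomes: Mapping[str, tuple[str, str, str | None]] | None = None,
    child_age_adjust: bool = True,
) -> pd.DataFrame:
    """Test MRS–outcome associations per cohort and meta-analyse.

    Returns a long table: one row per (outcome, cohort) plus one ``meta``
    row per outcome; FDR is computed across the meta-analysed outcomes
    only (the declared multiple-testing family).
    """
    if outcomes is None:
        outcomes = DEFAULT_OUTCOMES
    rows = []
    meta_rows = []
    for label, (column, kind, age_col) in outcomes.items():
        if not child_age_adjust:
            age_col = None
        effs, ses = [], []
        seen = False
        for cohort, score in scores.items():
            res = _fit_outcome(score, phenotypes[cohort], column, kind, age_col)
            if res is None:
                continue
            seen = True
            eff, se, p, n = res
            rows.append([label, cohort, kind, eff, se, p, n])
            effs.append(eff)
            ses.append(se)
        if not seen:
            continue
        m = ivw_fixed(effs, ses)
        meta_rows.append(
            [label, "meta", kind, m.fixed_effect, m.se, m.p, m.k, m.het_q, m.het_p]
        )
    if not meta_rows:
        raise ValueError("no outcome could be tested in any cohort")
    meta_df = pd.DataFrame(
        meta_rows,
        columns=["outcome", "cohort", "kind", "effect", "se", "p", "k", "het_q", "het_p"],
    )
    meta_df["fdr_p"] = bh_fdr(meta_df["p"].to_numpy())
    cohort_df = pd.DataFrame(
        rows, columns=["outcome", "cohort", "kind", "effect", "se", "p", "n"]
    )
    out = pd.concat([cohort_df, meta_df], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# descriptive cohort comparisons


def cohort_compare(
    phenotypes: Mapping[str, pd.DataFrame],
    fields: Sequence[tuple[str, str]],
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Table-1 style tests across cohorts.

    fields: (column, kind) with kind ``continuous`` (ANOVA F, or Welch t
    for two cohorts) or ``categorical`` (chi-square of the cohort ×
    category table; cohorts contributing an expected count < min_expected
    are excluded from that test and reported).
    """
    if len(phenotypes) < 2:
        raise ValueError("need ≥ 2 cohorts to compare")
    rows = []
    for column, kind in fields:
        excluded: list[str] = []
        have = {
            name: p[column].dropna()
            for name, p in phenotypes.items()
            if column in p.columns and p[column].notna().sum() > 0
        }
        if len(have) < 2:
            rows.append([column, kind, np.nan, "fewer than 2 cohorts observed", []])
            continue
        if kind == "continuous":
            groups = list(have.values())
            if len(groups) == 2:
                stat = ttest_ind(groups[0], groups[1], equal_var=False)
                rows.append([column, "t", float(stat.pvalue), "", []])
            else:
                stat = f_oneway(*groups)
                rows.append([column, "anova", float(stat.pvalue), "", []])
        elif kind == "categorical":
            counts = pd.DataFrame(
                {name: vals.value_counts() for name, vals in have.items()}
            ).fillna(0).T
            if counts.shape[1] < 2:
                rows.append([column, "chi2", np.nan, "single category", []])
                continue
            while counts.shape[0] >= 2:
                total = counts.to_numpy().sum()
                expected = np.outer(
                    counts.sum(axis=1), counts.sum(axis=0)
                ) / total
                bad = (expected < min_expected).any(axis=1)
                if not bad.any():
                    break
                worst = counts.index[int(np.argmax(bad))]
                excluded.append(worst)
                counts = counts.drop(index=worst)
            if counts.shape[0] < 2:
                rows.append([column, "chi2", np.nan, "all cohorts excluded", excluded])
                continue
            keep_cols = counts.columns[(counts.sum(axis=0) > 0)]
            res = chi2_contingency(counts[keep_cols].to_numpy())
            rows.append([column, "chi2", float(res.pvalue), "", excluded])
        else:
            raise ValueError(f"unknown field kind {kind!r}")
    return pd.DataFrame(rows, columns=["field", "test", "p", "note", "excluded_cohorts"])


def score_correlations(scores: Mapping[str, pd.Series], min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations between score vectors over shared,
    non-missing samples; pairs with < min_shared shared samples are NaN."""
    labels = list(scores)
    if len(labels) < 2:
        raise ValueError("need ≥ 2 scores")
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            joined = pd.concat([scores[a].rename("a"), scores[b].rename("b")], axis=1).dropna()
            if len(joined) < min_shared:
                out.loc[a, b] = out.loc[b, a] = np.nan
            else:
                out.loc[a, b] = out.loc[b, a] = joined["a"].corr(joined["b"])
    return out
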