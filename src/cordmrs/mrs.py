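"""Summary-statistics elastic net for methylation risk scores.

Individual-level discovery data are not needed: the score weights γ are
fit from (i) discovery EWAS summary statistics, converted per CpG to a
pseudo-correlation ``b_j = z_j/√(n_j + z_j²)`` with ``z_j = effect/SE``,
and (ii) a reference correlation matrix R of standardized β-values
(estimated here from the validation cohort). The solution minimizes

    f(γ) = γᵀ(R + λ2·I)γ − 2 bᵀγ + 2 λ1 ‖γ‖₁

by cyclic coordinate descent with the soft-threshold update

    γ_j ← S(b_j − Σ_{k≠j} R_jk γ_k, λ1) / (R_jj + λ2),
    S(x, λ) = sign(x)·max(|x| − λ, 0).

λ1 runs over a 50-point log-spaced path from the all-zero solution
downward; λ2 = α(1 − λ1) over a 10-value α grid in [0, 0.9]. The (λ1, λ2)
pair whose score is most significantly associated with the untransformed
smoking-history variable (0–3) in the validation cohort, adjusting for the
standard covariates, is selected (ties → sparser model, then larger λ1).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ewas import DEFAULT_COVARIATES, _covariate_matrix
from .io import MrsModel, ValidationError

__all__ = [
    "ReferencePanel",
    "TuningGrid",
    "standardize",
    "reference_correlation",
    "prepare_b",
    "soft_threshold",
    "elnet_summary",
    "elnet_objective",
    "lambda_path",
    "tune",
    "score_samples",
]


@dataclasses.dataclass
class ReferencePanel:
    """Correlation matrix of standardized β-values from a named cohort."""

    probe_ids: list[str]
    R: np.ndarray
    n_ref: int
    source: str = ""

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.probe_ids)
        if self.R.shape != (p, p):
            raise ValueError("R must be square and match probe_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")


@dataclasses.dataclass
class TuningGrid:
    """λ1 path × α grid; λ2 = α(1 − λ1)."""

    lambda1_values: np.ndarray
    alpha_values: np.ndarray

    def __post_init__(self) -> None:
        self.lambda1_values = np.asarray(self.lambda1_values, dtype=float)
        self.alpha_values = np.asarray(self.alpha_values, dtype=float)
        if np.any(np.diff(self.lambda1_values) >= 0):
            raise ValueError("lambda1 path must be strictly decreasing")
        if np.any((self.alpha_values < 0) | (self.alpha_values >= 1)):
            raise ValueError("alpha values must lie in [0, 1)")

    @classmethod
    def default(cls, b: np.ndarray, n_lambda: int = 50, n_alpha: int = 10) -> "TuningGrid":
        return cls(lambda_path(b, n_lambda), np.arange(n_alpha) / n_alpha)


# ---------------------------------------------------------------------------


def standardize(beta: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize each probe row to mean 0, SD 1 (ddof=1) across samples."""
    if beta.isna().any().any():
        raise ValidationError("standardize requires a complete matrix")
    means = beta.mean(axis=1)
    sds = beta.std(axis=1, ddof=1)
    zero = sds.index[sds <= 0]
    if len(zero):
        raise ValidationError(f"zero-variance probe {zero[0]!r}")
    z = beta.sub(means, axis=0).div(sds, axis=0)
    return z, means, sds


def reference_correlation(z: pd.DataFrame, source: str = "") -> ReferencePanel:
    """R = ZZᵀ/(n−1) over a standardized probes × samples matrix."""
    n = z.shape[1]
    if n < 3:
        raise ValueError("reference correlation needs ≥ 3 samples")
    R = (z.to_numpy() @ z.to_numpy().T) / (n - 1)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2
    return ReferencePanel(probe_ids=list(z.index), R=R, n_ref=n, source=source)


def prepare_b(
    sumstats: pd.DataFrame, probes: Sequence[str], raw: bool = False
) -> np.ndarray:
    """Map discovery (effect, SE, N) to the standardized-scale vector b.

    Default: pseudo-correlation b_j = z_j/√(n_j + z_j²), bounded in (−1, 1)
    and sign-preserving. ``raw=True`` passes the discovery coefficients
    through unchanged (sensitivity mode; only sensible when the discovery
    regression was run on standardized predictors).
    """
    ss = sumstats.set_index("probe_id")
    missing = [p for p in probes if p not in ss.index]
    if missing:
        raise ValidationError(f"probe {missing[0]!r} absent from summary statistics")
    sub = ss.loc[list(probes)]
    if raw:
        return sub["effect"].to_numpy(dtype=float)
    if (sub["n"] <= 1).any():
        raise ValidationError("discovery n must exceed 1")
    z = sub["effect"].to_numpy() / sub["se"].to_numpy()
    return z / np.sqrt(sub["n"].to_numpy() + z**2)


def soft_threshold(x: float | np.ndarray, lam: float) -> float | np.ndarray:
    """Proximal map of the L1 penalty: sign(x)·max(|x|−λ, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def elnet_objective(
    gamma: np.ndarray, b: np.ndarray, R: np.ndarray, lambda1: float, lambda2: float
) -> float:
    """f(γ) = γᵀ(R+λ2 I)γ − 2bᵀγ + 2λ1‖γ‖₁ (the solver's objective)."""
    return float(
        gamma @ R @ gamma
        + lambda2 * gamma @ gamma
        - 2 * b @ gamma
        + 2 * lambda1 * np.sum(np.abs(gamma))
    )


def _cd_python(R, b, gamma, r, lambda1, lambda2, tol, max_iter):
    """Reference implementation of the coordinate-descent loop."""
    p = b.size
    diag = np.diag(R).copy()
    denom = diag + lambda2
    n_sweeps = 0
    while n_sweeps < max_iter:
        active = np.flatnonzero((gamma != 0) | (np.abs(r) > lambda1))
        stable = False
        while n_sweeps < max_iter and not stable:
            n_sweeps += 1
            max_change = 0.0
            for j in active:
                gj = gamma[j]
                rho = r[j] + diag[j] * gj
                new = soft_threshold(rho, lambda1) / denom[j]
                if new != gj:
                    gamma[j] = new
                    r -= R[j] * (new - gj)  # R symmetric: row == column
                    change = abs(new - gj)
                    if change > max_change:
                        max_change = change
            stable = max_change < tol
        violations = (gamma == 0) & (np.abs(r) > lambda1 + tol)
        if not violations.any():
            return stable
    return False


try:  # optional compiled kernel; numerically identical to _cd_python
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _cd_numba(R, b, gamma, r, lambda1, lambda2, tol, max_iter):  # pragma: no cover
        p = b.size
        n_sweeps = 0
        active = np.empty(p, dtype=np.int64)
        while n_sweeps < max_iter:
            na = 0
            for j in range(p):
                if gamma[j] != 0.0 or abs(r[j]) > lambda1:
                    active[na] = j
                    na += 1
            stable = False
            while n_sweeps < max_iter and not stable:
                n_sweeps += 1
                max_change = 0.0
                for k in range(na):
                    j = active[k]
                    gj = gamma[j]
                    rho = r[j] + R[j, j] * gj
                    a = abs(rho) - lambda1
                    if a <= 0.0:
                        new = 0.0
                    else:
                        s = 1.0 if rho > 0 else -1.0
                        new = s * a / (R[j, j] + lambda2)
                    if new != gj:
                        d = new - gj
                        gamma[j] = new
                        for i in range(p):
                            r[i] -= R[j, i] * d
                        if abs(d) > max_change:
                            max_change = abs(d)
                stable = max_change < tol
            viol = False
            for j in range(p):
                if gamma[j] == 0.0 and abs(r[j]) > lambda1 + tol:
                    viol = True
                    break
            if not viol:
                return stable
        return False

    _cd_kernel = _cd_numba
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_python


def elnet_summary(
    b: np.ndarray,
    R: np.ndarray | ReferencePanel,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    warm_start: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Cyclic coordinate descent for the summary-statistics elastic net.

    Sweeps run over an active set (nonzero coordinates plus coordinates
    whose stationarity condition is violated), with full KKT verification
    before declaring convergence. Returns (γ, converged); a non-converged
    solve emits a warning and returns the last iterate.
    """
    if isinstance(R, ReferencePanel):
        R = R.R
    b = np.asarray(b, dtype=float)
    p = b.size
    if R.shape != (p, p):
        raise ValueError(f"dimension mismatch: |b|={p}, R is {R.shape}")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    R = np.ascontiguousarray(R, dtype=float)
    gamma = np.zeros(p) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
    r = b - R @ gamma if gamma.any() else b.copy()
    converged = bool(
        _cd_kernel(R, b, gamma, r, float(lambda1), float(lambda2), float(tol),
                   int(max_iter))
    )
    if not converged:
        import warnings

        warnings.warn(f"elastic net did not converge in {max_iter} sweeps")
    return gamma, converged


def lambda_path(
    b: np.ndarray, n_points: int = 50, floor_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced, strictly decreasing λ1 path from the all-zero solution
    (λ_max = max|b_j|) down to floor_ratio·λ_max."""
    b = np.asarray(b, dtype=float)
    lam_max = float(np.max(np.abs(b)))
    if lam_max == 0:
        raise ValueError("b is identically zero; no path exists")
    return np.geomspace(lam_max, floor_ratio * lam_max, n_points)


# ---------------------------------------------------------------------------
# tuning


def tune(
    b: np.ndarray,
    panel: ReferencePanel,
    validation,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    grid: TuningGrid | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    provenance: str = "",
) -> tuple[MrsModel, pd.DataFrame]:
    """Tune (λ1, λ2) on a validation cohort and package the fitted MRS.

    validation is a :class:`~cordmrs.simulate.CohortBundle` (or any object
    with ``beta``, ``phenotypes``, ``cell_props``). For every grid cell the
    fitted γ scores the validation samples and smoking history (0–3,
    untransformed) is regressed on score + covariates; the cell with the
    smallest two-sided score-term p wins. The returned trace records
    (lambda1, alpha, lambda2, n_nonzero, p, converged, selected) for all
    cells.

    max_iter caps the coordinate-descent sweeps per grid cell: when p
    exceeds the reference sample size, the λ2=0 cells are not strictly
    convex and can converge only slowly in the flat directions; the cap
    bounds the grid search while leaving well-posed cells fully converged
    (they finish in far fewer sweeps). Capped cells are marked
    ``converged=False`` in the trace.
    """
    if grid is None:
        grid = TuningGrid.default(b)
    probes = panel.probe_ids

    from .qc import impute_mean

    beta_v = validation.beta.loc[probes]
    beta_v, _ = impute_mean(beta_v)
    z, means, sds = standardize(beta_v)
    Z = z.to_numpy()  # p × n

    covs = _covariate_matrix(validation.phenotypes, validation.cell_props, covariates)
    hist = validation.phenotypes.set_index("sample_id")["smoking_history"]
    design = covs.join(hist.rename("__y__"), how="inner").dropna()
    samples = [s for s in beta_v.columns if s in design.index]
    design = design.loc[samples]
    col_idx = [list(beta_v.columns).index(s) for s in samples]
    Zv = Z[:, col_idx]
    y = design["__y__"].to_numpy(dtype=float)
    X_cov = sm.add_constant(design.drop(columns="__y__"), has_constant="add")

    import warnings as _warnings

    records = []
    best = None  # (p, nnz, -lambda1, idx, gamma)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        for alpha in grid.alpha_values:
            gamma = np.zeros_like(b)
            for lam1 in grid.lambda1_values:
                lam2 = alpha * (1 - lam1)
                gamma, converged = elnet_summary(
                    b, panel.R, lam1, lam2, tol=tol, max_iter=max_iter,
                    warm_start=gamma,
                )
                nz = np.flatnonzero(gamma)
                nnz = len(nz)
                if nnz == 0:
                    pval = np.nan
                else:
                    scores = Zv[nz].T @ gamma[nz]
                    X = X_cov.copy()
                    X.insert(1, "mrs", scores)
                    fit = sm.OLS(y, X).fit()
                    pval = float(fit.pvalues["mrs"])
                records.append([lam1, alpha, lam2, nnz, pval, converged, False,
                                gamma.copy()])
                if np.isfinite(pval):
                    key = (pval, nnz, -lam1)
                    if best is None or key < best[0]:
                        best = (key, len(records) - 1)
    if best is None:
        raise ValidationError("every grid cell produced an all-zero solution")
    sel = best[1]
    records[sel][6] = True
    trace = pd.DataFrame(
        [r[:7] for r in records],
        columns=["lambda1", "alpha", "lambda2", "n_nonzero", "p", "converged",
                 "selected"],
    )
    lam1, alpha, lam2, _, _, _, _, gamma = records[sel]
    nz = np.flatnonzero(gamma)
    model = MrsModel(
        probe_ids=[probes[j] for j in nz],
        weights=gamma[nz],
        lambda1=float(lam1),
        lambda2=float(lam2),
        means=means.to_numpy()[nz],
        sds=sds.to_numpy()[nz],
        provenance=provenance or f"tuned on {getattr(validation, 'name', 'validation')}",
    )
    return model, trace


def score_samples(
    model: MrsModel, beta: pd.DataFrame, frozen_standardization: bool = False
) -> tuple[pd.Series, int]:
    """Score a target cohort: Σ_j γ_j · standardized β_ij over the model
    CpGs present in the matrix.

    Standardization uses target-cohort means/SDs by default (the cohorts
    may come from different arrays); ``frozen_standardization=True`` uses
    the constants stored at fit time instead. Missing entries are filled
    with the probe mean before standardizing. Returns (scores, n_cpgs_used).
    """
    present = [p for p in model.probe_ids if p in beta.index]
    if not present:
        raise ValidationError("no model CpGs present in the target matrix")
    w = pd.Series(model.weights, index=model.probe_ids).loc[present]
    sub = beta.loc[present]
    from .qc import impute_mean

    sub, _ = impute_mean(sub)
    if frozen_standardization:
        means = pd.Series(model.means, index=model.probe_ids).loc[present]
        sds = pd.Series(model.sds, index=model.probe_ids).loc[present]
        z = sub.sub(means, axis=0).div(sds, axis=0)
    else:
        sds = sub.std(axis=1, ddof=1)
        usable = sds > 0
        if not usable.all():
            import warnings

            warnings.warn(
                f"{int((~usable).sum())} zero-variance model CpGs dropped at scoring"
            )
            sub, w, sds = sub.loc[usable], w[usable], sds[usable]
            if sub.shape[0] == 0:
                raise ValidationError("all overlapping model CpGs have zero variance")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sds, axis=0)
    scores = pd.Series(z.to_numpy().T @ w.to_numpy(), index=beta.columns, name="mrs")
    return scores, int(len(w))
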