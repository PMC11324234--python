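"""Sample/probe quality-control cascade and cell-type deconvolution.

The cascade order is fixed: sample exclusions (sex mismatch, duplicates)
→ masked-probe removal → missingness filters (samples first, then probes,
both strictly greater than the threshold) → per-probe mean imputation →
non-informative probe removal (every value hypomethylated β<0.1 or every
value hypermethylated β>0.9). Imputation requires the missingness filter
to have run, and the non-informative rule requires complete data, which
pins this order. Re-running the cascade on its own output is the identity.

Cell-type proportions for the 7 canonical cord-blood cell types are
estimated per sample by reference-based deconvolution: least squares of
the sample's β profile on reference mean-methylation profiles under
nonnegativity and sum-to-one constraints (a constrained quadratic
program, solved with SLSQP).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import CELL_TYPES, ValidationError

__all__ = [
    "QcReport",
    "filter_by_missingness",
    "impute_mean",
    "drop_masked",
    "drop_noninformative",
    "flag_sex_and_duplicates",
    "estimate_cell_proportions",
    "run_qc",
    "synthetic_cell_reference",
]


@dataclasses.dataclass
class QcReport:
    """Exclusions and imputation counts from one QC pass."""

    samples_dropped: dict[str, str] = dataclasses.field(default_factory=dict)
    probes_dropped: dict[str, str] = dataclasses.field(default_factory=dict)
    n_imputed: int = 0
    warnings: list[str] = dataclasses.field(default_factory=list)

    def merge(self, other: "QcReport") -> "QcReport":
        return QcReport(
            samples_dropped={**self.samples_dropped, **other.samples_dropped},
            probes_dropped={**self.probes_dropped, **other.probes_dropped},
            n_imputed=self.n_imputed + other.n_imputed,
            warnings=self.warnings + other.warnings,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def filter_by_missingness(
    beta: pd.DataFrame, sample_thresh: float = 0.10, probe_thresh: float = 0.10
) -> tuple[pd.DataFrame, QcReport]:
    """Drop samples with >sample_thresh missing probes, then probes with
    >probe_thresh missing samples (strict inequalities)."""
    for name, t in (("sample_thresh", sample_thresh), ("probe_thresh", probe_thresh)):
        if not 0 < t < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    report = QcReport()
    sample_miss = beta.isna().mean(axis=0)
    drop_samples = sample_miss.index[sample_miss > sample_thresh]
    report.samples_dropped.update({s: "missingness" for s in drop_samples})
    out = beta.drop(columns=drop_samples)
    if out.shape[1] == 0:
        raise ValidationError("missingness filter removed every sample")
    probe_miss = out.isna().mean(axis=1)
    drop_probes = probe_miss.index[probe_miss > probe_thresh]
    report.probes_dropped.update({p: "missingness" for p in drop_probes})
    out = out.drop(index=drop_probes)
    if out.shape[0] == 0:
        raise ValidationError("missingness filter removed every probe")
    return out, report


def impute_mean(beta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace each missing cell by its probe's mean over observed samples."""
    arr = beta.to_numpy(dtype=float, copy=True)
    miss = np.isnan(arr)
    n_missing = int(miss.sum())
    if n_missing == 0:
        return beta.copy(), 0
    all_missing = miss.all(axis=1)
    if all_missing.any():
        probe = beta.index[int(np.argmax(all_missing))]
        raise ValidationError(f"probe {probe!r} has no observed values to impute from")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(arr, axis=1)
    arr[miss] = np.broadcast_to(means[:, None], arr.shape)[miss]
    return pd.DataFrame(arr, index=beta.index, columns=beta.columns), n_missing


def drop_masked(
    beta: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, QcReport]:
    """Remove cross-reactive/SNP probes (manifest mask flag)."""
    mask = manifest.set_index("probe_id")["mask"]
    unknown = beta.index.difference(mask.index)
    if len(unknown):
        raise ValidationError(f"probe {unknown[0]!r} absent from manifest")
    masked = [p for p in beta.index if mask[p]]
    out = beta.drop(index=masked)
    if out.shape[0] == 0:
        raise ValidationError("mask filter removed every probe")
    return out, QcReport(probes_dropped={p: "masked" for p in masked})


def drop_noninformative(
    beta: pd.DataFrame, lo: float = 0.1, hi: float = 0.9
) -> tuple[pd.DataFrame, QcReport]:
    """Remove probes where every sample is hypomethylated (β<lo) or every
    sample hypermethylated (β>hi); strict comparisons."""
    if beta.isna().any().any():
        raise ValidationError("non-informative filter requires complete data")
    arr = beta.to_numpy()
    hypo = (arr < lo).all(axis=1)
    hyper = (arr > hi).all(axis=1)
    report = QcReport()
    for flag, reason in ((hypo, "hypomethylated"), (hyper, "hypermethylated")):
        report.probes_dropped.update({beta.index[j]: reason for j in np.flatnonzero(flag)})
    out = beta.drop(index=list(report.probes_dropped))
    if out.shape[0] == 0:
        raise ValidationError("non-informative filter removed every probe")
    return out, report


# ---------------------------------------------------------------------------
# sex inference and duplicate detection


def flag_sex_and_duplicates(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    reported_sex: Mapping[str, float] | pd.Series,
    dup_r: float = 0.99,
    sep_threshold: float = 0.1,
) -> QcReport:
    """Flag sex mismatches (2-means split of mean X-chromosome β; the
    higher-methylation cluster is called female) and duplicates
    (sample pairs with Pearson r > dup_r; later-ordered sample flagged).

    With no X probes or a single unseparated cluster the sex inference
    abstains with a warning rather than flagging anyone.
    """
    report = QcReport()
    reported = pd.Series(reported_sex)

    x_probes = manifest.loc[manifest["chromosome"].astype(str) == "X", "probe_id"]
    x_probes = beta.index.intersection(x_probes)
    if len(x_probes) == 0:
        report.warnings.append("no X-chromosome probes; sex inference skipped")
    else:
        mean_x = beta.loc[x_probes].mean(axis=0, skipna=True).to_numpy()
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(mean_x[:, None])
        centers = km.cluster_centers_.ravel()
        if abs(centers[0] - centers[1]) < sep_threshold:
            report.warnings.append(
                "X-methylation clusters not separated; sex inference abstains"
            )
        else:
            female_cluster = int(np.argmax(centers))
            inferred = (km.labels_ == female_cluster).astype(float)
            for sample, inf in zip(beta.columns, inferred):
                rep = reported.get(sample, np.nan)
                if not np.isnan(rep) and rep != inf:
                    report.samples_dropped[sample] = "sex_mismatch"

    # duplicates: correlation over probe-mean-imputed values
    filled, _ = impute_mean(beta)
    arr = filled.to_numpy()
    keep = arr.std(axis=1) > 0
    r = np.corrcoef(arr[keep].T)
    n = r.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if r[i, j] > dup_r:
                later = beta.columns[j]
                if later not in report.samples_dropped:
                    report.samples_dropped[later] = "duplicate"
    return report


# ---------------------------------------------------------------------------
# full cascade


def run_qc(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    reported_sex: Mapping[str, float] | pd.Series | None = None,
    sample_thresh: float = 0.10,
    probe_thresh: float = 0.10,
    lo: float = 0.1,
    hi: float = 0.9,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the full cascade in the fixed order; returns the cleaned,
    fully observed matrix and a consolidated report."""
    report = QcReport()
    out = beta
    if reported_sex is not None:
        flags = flag_sex_and_duplicates(out, manifest, reported_sex)
        report = report.merge(flags)
        out = out.drop(columns=list(flags.samples_dropped))
        if out.shape[1] == 0:
            raise ValidationError("sample exclusions removed every sample")
    out, rep = drop_masked(out, manifest)
    report = report.merge(rep)
    out, rep = filter_by_missingness(out, sample_thresh, probe_thresh)
    report = report.merge(rep)
    out, n_imp = impute_mean(out)
    report.n_imputed += n_imp
    out, rep = drop_noninformative(out, lo, hi)
    report = report.merge(rep)
    return out, report


# ---------------------------------------------------------------------------
# reference-based cell-type deconvolution


def estimate_cell_proportions(
    beta: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Estimate cord-blood cell proportions per sample.

    reference: DataFrame with ``probe_id`` column (or index) plus one
    mean-β column per cell type. Solves, per sample, ``min ‖A x − y‖²``
    subject to ``x ≥ 0`` and ``Σx = 1`` over the probes observed in both.
    Returns a table with sample_id, one column per cell type, and the
    residual norm of the fit.
    """
    ref = reference.copy()
    if "probe_id" in ref.columns:
        ref = ref.set_index("probe_id")
    cell_cols = [c for c in ref.columns if c in CELL_TYPES] or list(ref.columns)
    common = beta.index.intersection(ref.index)
    if len(common) < len(cell_cols):
        raise ValidationError(
            f"only {len(common)} reference probes present; need ≥ {len(cell_cols)}"
        )
    A_full = ref.loc[common, cell_cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A_full) < len(cell_cols):
        raise ValidationError("reference cell profiles are rank deficient")
    Y = beta.loc[common].to_numpy(dtype=float)

    k = len(cell_cols)
    x0 = np.full(k, 1.0 / k)
    constraints = [{"type": "eq", "fun": lambda x: x.sum() - 1.0,
                    "jac": lambda x: np.ones_like(x)}]
    bounds = [(0.0, 1.0)] * k
    rows = []
    for s_idx, sample in enumerate(beta.columns):
        y = Y[:, s_idx]
        obs = ~np.isnan(y)
        A, yo = A_full[obs], y[obs]
        AtA, Aty = A.T @ A, A.T @ yo

        def fun(x, AtA=AtA, Aty=Aty, yty=yo @ yo):
            return float(x @ AtA @ x - 2 * Aty @ x + yty)

        def jac(x, AtA=AtA, Aty=Aty):
            return 2 * (AtA @ x - Aty)

        res = minimize(
            fun, x0, jac=jac, bounds=bounds, constraints=constraints,
            method="SLSQP", options={"ftol": 1e-14, "maxiter": 500},
        )
        x = np.clip(res.x, 0.0, None)
        x /= x.sum()
        rows.append([sample, *x, float(np.linalg.norm(A @ x - yo))])
    return pd.DataFrame(rows, columns=["sample_id", *cell_cols, "residual_norm"])


def synthetic_cell_reference(
    n_marker_per_type: int = 10, seed: int = 0, noise_sd: float = 0.0
) -> pd.DataFrame:
    """A synthetic cord-blood cell reference (stand-in profile panel).

    Each cell type receives ``n_marker_per_type`` marker probes that are
    hypermethylated (β≈0.85) in that type and hypomethylated (β≈0.15)
    elsewhere, which makes the 7 profiles well separated and full rank.
    Purely synthetic: it emulates the *structure* of a flow-sorted
    reference panel, not any published profile values.
    """
    rng = np.random.default_rng(seed)
    k = len(CELL_TYPES)
    p = k * n_marker_per_type
    profiles = np.full((p, k), 0.15)
    for c in range(k):
        rows = slice(c * n_marker_per_type, (c + 1) * n_marker_per_type)
        profiles[rows, c] = 0.85
    if noise_sd > 0:
        profiles = np.clip(profiles + rng.normal(0, noise_sd, profiles.shape), 0.01, 0.99)
    ref = pd.DataFrame(profiles, columns=list(CELL_TYPES))
    ref.insert(0, "probe_id", [f"ref{j:04d}" for j in range(p)])
    return ref
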