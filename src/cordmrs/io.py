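"""Readers and writers for the tabular artifacts of the pipeline.

Conventions
-----------
* The β-value matrix is stored **probes × samples** (probe-major, the
  dominant array convention): first column ``probe_id``, header row of
  sample identifiers, values are methylation fractions in [0, 1].
* Missing values are encoded as empty cells or ``NA``; both are accepted
  on read and empty cells are written.
* Delimiter is inferred from the first line (tab wins over comma), so both
  ``.tsv`` and ``.csv`` artifacts round-trip.
* All readers validate rather than coerce: an out-of-range or malformed
  value raises :class:`ValidationError` naming the offending cell/row.

Fitted MRS models are serialized as versioned JSON (:func:`save_model` /
:func:`load_model`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "MrsModel",
    "read_beta",
    "write_beta",
    "read_sumstats",
    "write_sumstats",
    "read_phenotypes",
    "write_phenotypes",
    "read_manifest",
    "write_manifest",
    "read_cells",
    "write_cells",
    "save_model",
    "load_model",
]

CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran", "nRBC")

MODEL_FORMAT_VERSION = 1


class ValidationError(ValueError):
    """An input file violated a structural or range invariant."""


@dataclasses.dataclass
class MrsModel:
    """A fitted methylation risk score: CpGs, weights and fit metadata.

    ``weights`` are on the standardized-β scale; ``means``/``sds`` are the
    per-CpG standardization constants recorded at fit time so a score can
    optionally be computed with frozen constants.
    """

    probe_ids: list[str]
    weights: np.ndarray
    lambda1: float
    lambda2: float
    means: np.ndarray
    sds: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = len(self.probe_ids)
        if not (len(self.weights) == len(self.means) == len(self.sds) == n):
            raise ValidationError(
                f"model arrays disagree in length: {n} probes, "
                f"{len(self.weights)} weights, {len(self.means)} means, "
                f"{len(self.sds)} sds"
            )
        if np.any(self.sds <= 0):
            bad = self.probe_ids[int(np.argmax(self.sds <= 0))]
            raise ValidationError(f"non-positive standardization SD for probe {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MrsModel):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and np.allclose(self.weights, other.weights)
            and np.allclose(self.means, other.means)
            and np.allclose(self.sds, other.sds)
            and self.lambda1 == other.lambda1
            and self.lambda2 == other.lambda2
            and self.provenance == other.provenance
        )


# ---------------------------------------------------------------------------
# low-level parsing helpers


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


_NA_TOKENS = {"", "NA", "NaN", "nan"}


def _to_float(token: str, where: str) -> float:
    """Strict float parsing: locale commas, en-dashes etc. raise, never NaN."""
    if token in _NA_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"malformed numeric value {token!r} at {where}") from None


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate column ids in {path.name}: {dups}")
    return df


def _numeric_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Convert a string frame (index already set) to floats, strictly."""
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        cells = df[col].to_numpy()
        try:
            out[:, j] = [np.nan if c in _NA_TOKENS else float(c) for c in cells]
        except ValueError:
            # slow path to report coordinates
            for i, c in enumerate(cells):
                _to_float(c, f"row {df.index[i]!r}, column {col!r}")
            raise  # pragma: no cover - _to_float always raises first
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# β-value matrices


def read_beta(path: str | Path) -> pd.DataFrame:
    """Read a probes × samples β-value matrix.

    Returns a float DataFrame indexed by ``probe_id`` with sample-id
    columns; missing entries are NaN. Values outside [0, 1] are rejected
    with the probe/sample coordinates in the message.
    """
    path = Path(path)
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path.name}: expected probe_id column plus ≥1 sample")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "probe_id"
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].tolist()
        raise ValidationError(f"duplicate probe ids in {path.name}: {dups}")
    beta = _numeric_frame(raw, path)
    _check_beta_range(beta, path.name)
    return beta


def _check_beta_range(beta: pd.DataFrame, name: str) -> None:
    arr = beta.to_numpy()
    bad = (arr < 0) | (arr > 1)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{name}: β value {arr[i, j]!r} out of [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    """Write a β matrix; empty cells encode missing. Lossless to 10 digits."""
    path = Path(path)
    _check_beta_range(beta, path.name)
    sep = "\t" if path.suffix == ".tsv" else ","
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep, float_format="%.10g", na_rep="")


# ---------------------------------------------------------------------------
# summary statistics

SUMSTATS_COLS = ["probe_id", "effect", "se", "p", "n"]


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read discovery EWAS summary statistics (probe_id, effect, se, p, n)."""
    path = Path(path)
    df = _read_table(path)
    missing = [c for c in SUMSTATS_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    out = df[SUMSTATS_COLS].copy()
    for col in ("effect", "se", "p"):
        out[col] = [
            _to_float(v, f"row {i} column {col!r}") for i, v in enumerate(out[col])
        ]
    out["n"] = [
        int(_to_float(v, f"row {i} column 'n'")) for i, v in enumerate(out["n"])
    ]
    if out["probe_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate probe ids")
    bad_se = out.index[~(out["se"] > 0)]
    if len(bad_se):
        raise ValidationError(f"{path.name}: non-positive se at row {bad_se[0]}")
    bad_p = out.index[~((out["p"] > 0) & (out["p"] <= 1))]
    if len(bad_p):
        raise ValidationError(f"{path.name}: p outside (0, 1] at row {bad_p[0]}")
    if (out["n"] <= 1).any():
        raise ValidationError(f"{path.name}: discovery n must exceed 1")
    return out


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    sumstats[SUMSTATS_COLS].to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# phenotypes

_PHENO_REQUIRED = ["sample_id", "smoking_history"]
_PHENO_BINARY = ("current_smoker", "ever_smoker", "gdm")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table; enforces the smoking-history coding contract.

    smoking_history is the ordinal 0 never / 1 quit before pregnancy /
    2 quit during pregnancy / 3 current smoker; current_smoker must equal
    ``history == 3`` and ever_smoker ``history ∈ {1,2,3}`` wherever all are
    observed.
    """
    path = Path(path)
    df = _read_table(path)
    missing = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    out = df.copy()
    for col in out.columns:
        if col == "sample_id":
            continue
        out[col] = [
            _to_float(v, f"row {i} column {col!r}") for i, v in enumerate(out[col])
        ]
    if out["sample_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate sample ids")
    hist = out["smoking_history"]
    ok = hist.isna() | hist.isin([0, 1, 2, 3])
    if not ok.all():
        row = int(np.argmax(~ok.to_numpy()))
        raise ValidationError(
            f"{path.name}: smoking_history {hist.iloc[row]!r} not in "
            f"{{0,1,2,3}} at row {row}"
        )
    if "exposure_hours" in out.columns:
        neg = out["exposure_hours"] < 0
        if neg.any():
            raise ValidationError(
                f"{path.name}: negative exposure_hours at row {int(np.argmax(neg.to_numpy()))}"
            )
    for col, rule in (
        ("current_smoker", hist == 3),
        ("ever_smoker", hist.isin([1, 2, 3])),
    ):
        if col in out.columns:
            obs = out[col].notna() & hist.notna()
            mism = obs & (out[col] != rule.astype(float))
            if mism.any():
                row = int(np.argmax(mism.to_numpy()))
                raise ValidationError(
                    f"{path.name}: {col} inconsistent with smoking_history at row {row}"
                )
    return out


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    pheno.to_csv(path, sep=sep, index=False, float_format="%.10g", na_rep="")


# ---------------------------------------------------------------------------
# probe manifest

MANIFEST_COLS = ["probe_id", "chromosome", "position", "gene", "mask"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_table(path)
    missing = [c for c in MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    out = df[MANIFEST_COLS].copy()
    if out["probe_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate probe ids")
    out["position"] = [
        int(_to_float(v, f"row {i} column 'position'"))
        for i, v in enumerate(out["position"])
    ]
    if (out["position"] < 1).any():
        row = int(np.argmax((out["position"] < 1).to_numpy()))
        raise ValidationError(f"{path.name}: position < 1 at row {row}")
    mask_map = {"True": True, "False": False, "1": True, "0": False,
                "true": True, "false": False}
    try:
        out["mask"] = [mask_map[v] for v in out["mask"]]
    except KeyError as exc:
        raise ValidationError(f"{path.name}: non-boolean mask value {exc}") from None
    return out


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    manifest[MANIFEST_COLS].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# cell proportions


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read per-sample cord-blood cell proportions (7 canonical types)."""
    path = Path(path)
    df = _read_table(path)
    missing = [c for c in ("sample_id", *CELL_TYPES) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    out = df[["sample_id", *CELL_TYPES]].copy()
    for col in CELL_TYPES:
        out[col] = [
            _to_float(v, f"row {i} column {col!r}") for i, v in enumerate(out[col])
        ]
    props = out[list(CELL_TYPES)].to_numpy()
    if (props < 0).any():
        i = int(np.argwhere(props < 0)[0][0])
        raise ValidationError(f"{path.name}: negative proportion at row {i}")
    sums = props.sum(axis=1)
    off = np.abs(sums - 1) > 1e-6
    if off.any():
        i = int(np.argmax(off))
        raise ValidationError(
            f"{path.name}: proportions sum to {sums[i]:.8f} (≠1) at row {i}"
        )
    return out


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    cells.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# model serialization


def save_model(model: MrsModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "probe_ids": list(model.probe_ids),
        "weights": model.weights.tolist(),
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> MrsModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path.name}: truncated or invalid model JSON ({exc})")
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValidationError(f"{path.name}: not an MRS model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"{path.name}: unsupported model format version "
            f"{payload['format_version']!r}"
        )
    fields = ("probe_ids", "weights", "lambda1", "lambda2", "means", "sds")
    missing = [f for f in fields if f not in payload]
    if missing:
        raise ValidationError(f"{path.name}: model file missing fields {missing}")
    return MrsModel(
        probe_ids=list(payload["probe_ids"]),
        weights=np.asarray(payload["weights"], dtype=float),
        lambda1=float(payload["lambda1"]),
        lambda2=float(payload["lambda2"]),
        means=np.asarray(payload["means"], dtype=float),
        sds=np.asarray(payload["sds"], dtype=float),
        provenance=str(payload.get("provenance", "")),
    )
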