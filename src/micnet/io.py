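"""Reading, writing and cleaning of two-layer expression tables.

Two CSV dialects are supported, mirroring the common layouts of public
miRNA-seq and RPPA (reverse-phase protein array) exports for paired
tumor/normal cohorts:

* **dialect A (miRNA)** — features x samples; first column holds miRNA
  names, the header row holds TCGA-style sample barcodes. A barcode whose
  fourth dash-delimited field (the sample/tissue code) starts with ``11``
  denotes solid tissue normal; everything else is treated as tumor.
* **dialect B (protein)** — samples x features with two leading metadata
  columns: a class code (``0`` = tumor, ``1`` = normal) and the sample
  barcode; the header row holds protein names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionParseError",
    "read_mirna_table",
    "read_protein_table",
    "write_mirna_table",
    "write_protein_table",
    "zero_filter",
    "align_samples",
]

TUMOR = "tumor"
NORMAL = "normal"
_LAYERS = ("miRNA", "protein")
_CONDITIONS = (TUMOR, NORMAL)


class ExpressionParseError(ValueError):
    """Raised when an expression table violates its dialect contract."""


@dataclass
class ExpressionMatrix:
    """Samples x features expression values for one molecular layer.

    Parameters
    ----------
    layer
        ``"miRNA"`` or ``"protein"``.
    sample_ids
        Unique sample barcodes, one per row of ``values``.
    feature_ids
        Unique feature names, one per column of ``values``.
    values
        Non-negative expression levels, shape ``(n_samples, n_features)``.
    condition
        Per-sample label, ``"tumor"`` or ``"normal"``.
    """

    layer: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    condition: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(map(str, self.sample_ids))
        self.feature_ids = list(map(str, self.feature_ids))
        self.condition = list(self.condition)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"layer must be one of {_LAYERS}, got {self.layer!r}")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(self.condition) != n:
            raise ValueError("condition must hold one label per sample")
        bad = set(self.condition) - set(_CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample barcodes: {dupes}")
        if len(set(self.feature_ids)) != p:
            dupes = _duplicates(self.feature_ids)
            raise ValueError(f"duplicate feature names: {dupes}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def condition_counts(self) -> dict[str, int]:
        return {c: self.condition.count(c) for c in _CONDITIONS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            layer=self.layer,
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            condition=[self.condition[i] for i in idx],
        )

    def subset_features(self, features: list[str]) -> "ExpressionMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        cols = [pos[f] for f in features]
        return ExpressionMatrix(
            layer=self.layer,
            sample_ids=list(self.sample_ids),
            feature_ids=list(features),
            values=self.values[:, cols],
            condition=list(self.condition),
        )

    def restrict_condition(self, condition: str) -> "ExpressionMatrix":
        mask = np.array([c == condition for c in self.condition])
        return self.subset_samples(mask)


def _duplicates(items) -> list[str]:
    seen, dup = set(), []
    for it in items:
        if it in seen and it not in dup:
            dup.append(it)
        seen.add(it)
    return dup


def barcode_patient(barcode: str) -> str:
    """Patient portion of a TCGA barcode: the first three dash fields."""
    return "-".join(barcode.split("-")[:3])


def barcode_is_normal(barcode: str) -> bool:
    """True if the barcode's tissue field marks solid tissue normal (code 11)."""
    fields = barcode.split("-")
    return len(fields) >= 4 and fields[3].startswith("11")


# ---------------------------------------------------------------------------
# dialect A: miRNA, features x samples
# ---------------------------------------------------------------------------

def read_mirna_table(path) -> ExpressionMatrix:
    """Load a dialect-A (features x samples) miRNA table.

    The on-disk layout is transposed to samples x features. Condition is
    derived from the barcode tissue field: ``-11*`` is normal, else tumor.
    """
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ExpressionParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ExpressionParseError(f"{path}: no sample columns found in header row")
    values = df.to_numpy()
    bad = _first_non_numeric(df)
    if bad is not None:
        raise ExpressionParseError(
            f"{path}: non-numeric value {bad[2]!r} at feature {bad[0]!r}, sample {bad[1]!r}"
        )
    samples = [str(c) for c in df.columns]
    condition = [NORMAL if barcode_is_normal(s) else TUMOR for s in samples]
    return ExpressionMatrix(
        layer="miRNA",
        sample_ids=samples,
        feature_ids=[str(i) for i in df.index],
        values=values.T.astype(float),
        condition=condition,
    )


def write_mirna_table(m: ExpressionMatrix, path) -> None:
    """Write dialect A (features x samples) re-readable by :func:`read_mirna_table`."""
    df = pd.DataFrame(m.values.T, index=m.feature_ids, columns=m.sample_ids)
    df.to_csv(path, index_label="", float_format="%.17g")


# ---------------------------------------------------------------------------
# dialect B: protein, samples x features with class-code + barcode columns
# ---------------------------------------------------------------------------

def read_protein_table(path) -> ExpressionMatrix:
    """Load a dialect-B protein table (class code, barcode, then features).

    Class code ``0`` marks tumor samples and ``1`` marks normal tissue.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover
        raise ExpressionParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ExpressionParseError(
            f"{path}: expected class-code and barcode columns before features"
        )
    codes = df.iloc[:, 0]
    barcodes = [str(b) for b in df.iloc[:, 1]]
    bad_codes = sorted(set(codes) - {0, 1})
    if bad_codes:
        raise ExpressionParseError(f"{path}: class codes outside {{0,1}}: {bad_codes}")
    expr = df.iloc[:, 2:]
    bad = _first_non_numeric(expr)
    if bad is not None:
        raise ExpressionParseError(
            f"{path}: non-numeric value {bad[2]!r} at sample row {bad[0]!r}, protein {bad[1]!r}"
        )
    condition = [TUMOR if c == 0 else NORMAL for c in codes]
    return ExpressionMatrix(
        layer="protein",
        sample_ids=barcodes,
        feature_ids=[str(c) for c in expr.columns],
        values=expr.to_numpy(dtype=float),
        condition=condition,
    )


def write_protein_table(m: ExpressionMatrix, path) -> None:
    """Write dialect B re-readable by :func:`read_protein_table`."""
    out = pd.DataFrame(m.values, columns=m.feature_ids)
    out.insert(0, "barcode", m.sample_ids)
    out.insert(0, "class", [0 if c == TUMOR else 1 for c in m.condition])
    out.to_csv(path, index=False, float_format="%.17g")


def _first_non_numeric(df: pd.DataFrame):
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        mask = series.isna() & df[col].notna()
        if mask.any():
            row = df.index[mask.to_numpy().nonzero()[0][0]]
            return (row, col, df.loc[row, col])
        if df[col].isna().any():
            row = df.index[df[col].isna().to_numpy().nonzero()[0][0]]
            return (row, col, None)
    return None


# ---------------------------------------------------------------------------
# cleaning and cross-layer alignment
# ---------------------------------------------------------------------------

def zero_filter(m: ExpressionMatrix, mode: str = "any") -> ExpressionMatrix:
    """Drop features contaminated by zero expression values.

    Zero readings are treated as measurement noise. ``mode="any"`` (default)
    drops a feature if any sample reads exactly zero; ``mode="all"`` drops
    only features that are zero in every sample.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    zero = m.values == 0
    drop = zero.any(axis=0) if mode == "any" else zero.all(axis=0)
    keep = [f for f, d in zip(m.feature_ids, drop) if not d]
    if not keep:
        warnings.warn(
            f"zero_filter removed every {m.layer} feature; returning empty matrix",
            stacklevel=2,
        )
        return ExpressionMatrix(
            layer=m.layer,
            sample_ids=list(m.sample_ids),
            feature_ids=[],
            values=np.empty((m.n_samples, 0)),
            condition=list(m.condition),
        )
    return m.subset_features(keep)


def align_samples(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two layers to same-patient, same-condition sample pairs.

    Samples are matched on the patient portion of the barcode (first three
    dash-delimited fields). Cross-layer dependence can only be estimated on
    measurements from the same individual, so this runs before any
    cross-layer MIC. If a shared patient carries conflicting condition
    labels in the two layers, that is a data error, never silently resolved.
    """
    key_a = _patient_condition_index(a, "first layer")
    key_b = _patient_condition_index(b, "second layer")
    shared_patients = {p for p, _ in key_a} & {p for p, _ in key_b}
    for p in sorted(shared_patients):
        cond_a = {c for q, c in key_a if q == p}
        cond_b = {c for q, c in key_b if q == p}
        if cond_a != cond_b and not (cond_a & cond_b):
            raise ValueError(
                f"patient {p}: condition labels disagree between layers "
                f"({sorted(cond_a)} vs {sorted(cond_b)})"
            )
    shared = sorted(set(key_a) & set(key_b))
    if not shared:
        raise ValueError(
            "no samples share a patient identifier and condition across layers; "
            "for method development use the synthetic generator instead"
        )
    idx_a = [key_a[k] for k in shared]
    idx_b = [key_b[k] for k in shared]
    return a.subset_samples(idx_a), b.subset_samples(idx_b)


def _patient_condition_index(m: ExpressionMatrix, what: str) -> dict:
    index: dict[tuple[str, str], int] = {}
    for i, (s, c) in enumerate(zip(m.sample_ids, m.condition)):
        key = (barcode_patient(s), c)
        if key in index:
            # keep the first aliquot; duplicates within a layer are legal
            continue
        index[key] = i
    return index
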