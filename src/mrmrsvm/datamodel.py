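"""Core containers and tab-delimited I/O for expression cohorts.

An :class:`ExpressionMatrix` is a features-by-samples intensity table with
per-feature metadata (database-annotation flag, presence count) and a
normalization-stage marker that downstream transforms check as a
precondition.  A :class:`LabeledDataset` pairs a matrix with binary class
labels (e.g. estrogen-receptor status) and the empirical class prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "ExpressionMatrix",
    "LabeledDataset",
    "NormalizationParams",
    "LinearModel",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "filter_features",
    "impute_missing",
]

#: Normalization stages, in pipeline order.  ``raw`` and ``floored`` data are
#: nonnegative intensities; ``zscore`` and ``log_actb`` live on a signed scale.
STAGES = ("raw", "floored", "array_norm", "feature_norm", "zscore", "log_actb")

ANNOTATION_COLUMN = "annotated"


class FormatError(ValueError):
    """Malformed input file (duplicate ids, non-numeric cells, bad labels)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Features x samples intensity table with feature metadata.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row / column identifiers.
    values
        ``(n_features, n_samples)`` float array; ``NaN`` marks a missing
        measurement (distinct from zero intensity).
    annotated
        Per-feature flag: the probe carries a database accession.
    present_count
        Number of non-missing measurements per feature.
    stage
        One of :data:`STAGES`; transforms verify it as a precondition.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotated: np.ndarray | None = None
    present_count: np.ndarray | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.annotated is None:
            self.annotated = np.ones(self.n_features, dtype=bool)
        else:
            self.annotated = np.asarray(self.annotated, dtype=bool)
            if self.annotated.shape != (self.n_features,):
                raise ValueError("annotated must have one flag per feature")
        if self.present_count is None:
            self.present_count = np.sum(~np.isnan(self.values), axis=1).astype(int)
        else:
            self.present_count = np.asarray(self.present_count, dtype=int)
            if self.present_count.shape != (self.n_features,):
                raise ValueError("present_count must have one entry per feature")
        if np.any(self.present_count < 0) or np.any(self.present_count > self.n_samples):
            raise ValueError("present_count out of range 0..n_samples")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage in ("raw", "floored"):
            finite = self.values[~np.isnan(self.values)]
            if finite.size and np.any(finite < 0):
                raise ValueError(f"stage {self.stage!r} requires nonnegative intensities")

    # -- basic introspection -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage: str = "raw", **kw) -> "ExpressionMatrix":
        return cls(
            feature_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            stage=stage,
            **kw,
        )

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "ExpressionMatrix":
        """Copy of this matrix with new values (and optionally a new stage)."""
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=np.asarray(values, dtype=float),
            annotated=self.annotated.copy(),
            present_count=self.present_count.copy(),
            stage=self.stage if stage is None else stage,
        )

    def subset_features(self, keep: np.ndarray, stage: str | None = None) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ExpressionMatrix(
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
            annotated=self.annotated[idx],
            present_count=self.present_count[idx],
            stage=self.stage if stage is None else stage,
        )


@dataclass
class LabeledDataset:
    """Expression matrix plus binary class labels and the empirical prior."""

    matrix: ExpressionMatrix
    y: np.ndarray  # bool, True = positive class, aligned to matrix.sample_ids

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=bool)
        if self.y.shape != (self.matrix.n_samples,):
            raise ValueError("need exactly one label per sample")

    @classmethod
    def from_label_map(
        cls, matrix: ExpressionMatrix, labels: Mapping[str, str]
    ) -> "LabeledDataset":
        missing = [s for s in matrix.sample_ids if s not in labels]
        if missing:
            raise FormatError(f"samples missing from label table: {missing}")
        y = np.array([labels[s] == "positive" for s in matrix.sample_ids])
        return cls(matrix=matrix, y=y)

    @property
    def prior(self) -> dict[str, float]:
        """Empirical P(c): class counts divided by n_samples."""
        n = self.y.size
        pos = int(self.y.sum())
        return {"positive": pos / n, "negative": (n - pos) / n}

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def subset_samples(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        m = self.matrix
        sub = ExpressionMatrix(
            feature_ids=list(m.feature_ids),
            sample_ids=[m.sample_ids[i] for i in idx],
            values=m.values[:, idx],
            annotated=m.annotated.copy(),
            present_count=None,  # recomputed for the sample subset
            stage=m.stage,
        )
        return LabeledDataset(matrix=sub, y=self.y[idx])


@dataclass
class NormalizationParams:
    """Fitted per-feature statistics from the normalization chain.

    ``per_feature_sd`` is the population standard deviation (divisor n); the
    convention is recorded in ``sd_convention`` because z-score dialects
    differ.
    """

    floor: float = 0.1
    per_feature_mean: np.ndarray | None = None
    per_feature_sd: np.ndarray | None = None
    per_feature_median: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if self.per_feature_sd is not None and np.any(np.asarray(self.per_feature_sd) <= 0):
            raise ValueError("per-feature standard deviations must be > 0")

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else [float(x) for x in a]

        return json.dumps(
            {
                "floor": self.floor,
                "per_feature_mean": arr(self.per_feature_mean),
                "per_feature_sd": arr(self.per_feature_sd),
                "per_feature_median": arr(self.per_feature_median),
                "feature_ids": self.feature_ids,
                "sd_convention": self.sd_convention,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        conv = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            floor=d["floor"],
            per_feature_mean=conv(d["per_feature_mean"]),
            per_feature_sd=conv(d["per_feature_sd"]),
            per_feature_median=conv(d["per_feature_median"]),
            feature_ids=list(d["feature_ids"]),
            sd_convention=d.get("sd_convention", "population"),
        )


@dataclass
class LinearModel:
    """Linear sign classifier over a named feature subset.

    Predicts positive iff ``w . x + w0 >= 0``; the exact-zero tie goes to the
    positive class by convention.
    """

    features: list[str]
    weights: np.ndarray
    threshold: float
    training_stage: str = "zscore"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.features),):
            raise ValueError("need one weight per feature")

    def decision_values(self, x: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        """Raw scores ``w . x + w0`` for one or more samples.

        ``x`` maps feature id -> value(s); a DataFrame is read as
        features-in-rows indexed by feature id.
        """
        if isinstance(x, pd.DataFrame):
            x = {f: x.loc[f].to_numpy(dtype=float) for f in self.features if f in x.index}
        cols = []
        for f in self.features:
            if f not in x:
                raise KeyError(f"feature {f!r} missing from input")
            cols.append(np.atleast_1d(np.asarray(x[f], dtype=float)))
        X = np.column_stack(cols)
        return X @ self.weights + self.threshold

    def predict(self, x) -> np.ndarray:
        """Class labels: ``positive`` iff the decision value is >= 0."""
        s = self.decision_values(x)
        return np.where(s >= 0, "positive", "negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "weights": [float(w) for w in self.weights],
                "threshold": float(self.threshold),
                "stage_expected": self.training_stage,
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(
            features=list(d["features"]),
            weights=np.asarray(d["weights"], dtype=float),
            threshold=float(d["threshold"]),
            training_stage=d.get("stage_expected", "zscore"),
            provenance=d.get("provenance", ""),
        )


# ---------------------------------------------------------------------------
# File I/O


def read_expression_matrix(
    path, orientation: str = "features_in_rows", stage: str = "raw"
) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    First column holds feature ids and the header row sample ids (transposed
    when ``orientation="samples_in_rows"``).  Empty cells are missing values,
    recorded as NaN and excluded from ``present_count``.  An optional boolean
    column named ``annotated`` provides the database-annotation flag.
    """
    # pandas renames duplicate header fields (S1 -> S1.1); check them raw first
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "column id")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    annotated = None
    if ANNOTATION_COLUMN in df.columns:
        raw_flags = df.pop(ANNOTATION_COLUMN)
        truthy = {"1", "true", "True", "TRUE", "T", "yes"}
        falsy = {"0", "false", "False", "FALSE", "F", "no", ""}
        flags = []
        for fid, v in raw_flags.items():
            v = v.strip()
            if v in truthy:
                flags.append(True)
            elif v in falsy:
                flags.append(False)
            else:
                raise FormatError(f"non-boolean annotation flag {v!r} for feature {fid!r}")
        annotated = np.asarray(flags, dtype=bool)

    _check_unique(list(df.index), "feature id")
    _check_unique(list(df.columns), "sample id")

    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        cells = df[col].str.strip()
        nonempty = cells != ""
        parsed = pd.to_numeric(cells[nonempty], errors="coerce")
        bad = parsed[parsed.isna()]
        if len(bad):
            fid = bad.index[0]
            raise FormatError(
                f"non-numeric value {cells[fid]!r} at feature {fid!r}, sample {col!r}"
            )
        values[nonempty.to_numpy(), j] = parsed.to_numpy()

    return ExpressionMatrix(
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        values=values,
        annotated=annotated,
        stage=stage,
    )


def write_expression_matrix(m: ExpressionMatrix, path, include_annotation: bool = False) -> None:
    """Write a matrix as TSV; missing values become empty cells.

    Floats are written with 17 significant digits so a read/write round trip
    is bit-exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        header = ["feature_id"] + list(m.sample_ids)
        if include_annotation:
            header.append(ANNOTATION_COLUMN)
        fh.write("\t".join(header) + "\n")
        for i, fid in enumerate(m.feature_ids):
            row = [fid]
            for v in m.values[i]:
                row.append("" if math.isnan(v) else repr(float(v)))
            if include_annotation:
                row.append("1" if m.annotated[i] else "0")
            fh.write("\t".join(row) + "\n")


def read_labels(
    path,
    positive_label: str = "ER+",
    negative_label: str = "ER-",
    header: bool = False,
) -> dict[str, str]:
    """Read a 2-column sample_id / label TSV into ``{id: "positive"|"negative"}``.

    Label strings are matched exactly; anything else is rejected so silent
    case or whitespace mismatches cannot flip a class.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if header:
        lines = lines[1:]
    for ln, line in enumerate(lines, start=2 if header else 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"line {ln}: expected 2 tab-separated columns")
        sid, lab = parts[0].strip(), parts[1].strip()
        if sid in out:
            raise FormatError(f"duplicate sample id {sid!r} in label file")
        if lab == positive_label:
            out[sid] = "positive"
        elif lab == negative_label:
            out[sid] = "negative"
        else:
            raise FormatError(
                f"line {ln}: unknown label {lab!r} (expected "
                f"{positive_label!r} or {negative_label!r})"
            )
    return out


# ---------------------------------------------------------------------------
# Feature filtering and imputation


def default_min_present(n_samples: int) -> int:
    """Default presence cutoff: ceil(25% of samples), generalizing 44/176."""
    return math.ceil(0.25 * n_samples)


def filter_features(
    m: ExpressionMatrix,
    min_present: int | None = None,
    require_annotation: bool = True,
) -> ExpressionMatrix:
    """Keep features present in >= ``min_present`` samples (and annotated).

    "Present" means a non-missing measurement.  Feature order and the sample
    set are preserved; filtering twice with the same arguments is a no-op.
    """
    if min_present is None:
        min_present = default_min_present(m.n_samples)
    if min_present < 0:
        raise ValueError("min_present must be >= 0")
    keep = m.present_count >= min_present
    if require_annotation:
        keep &= m.annotated
    if not keep.any():
        raise ValueError(
            f"no features satisfy present_count >= {min_present}"
            + (" and annotation" if require_annotation else "")
        )
    return m.subset_features(keep)


def impute_missing(m: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Replace missing cells with the per-feature median over present samples.

    Returns the imputed matrix and the number of imputed cells.  Features with
    no present measurement cannot be imputed and raise.
    """
    values = m.values.copy()
    nan_mask = np.isnan(values)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        empty = np.flatnonzero(nan_mask.all(axis=1))
        if empty.size:
            raise ValueError(
                f"cannot impute features with no present values: "
                f"{[m.feature_ids[i] for i in empty[:5]]}"
            )
        med = np.nanmedian(values, axis=1)
        values[nan_mask] = np.broadcast_to(med[:, None], values.shape)[nan_mask]
    return m.with_values(values), n_imputed
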