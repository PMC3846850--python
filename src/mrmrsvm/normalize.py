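"""Microarray normalization chain and single-sample housekeeping variant.

The chain mirrors the standard GeneSpring-style preprocessing for one-color
Agilent intensity data:

    N1  floor_baseline       clip every intensity below a small floor (0.1)
    N2  normalize_per_array  divide each array (column) by its own median
    N3  normalize_per_feature  divide each feature (row) by its median
    N4  zscore               per-feature standardization to mean 0, sd 1

``zscore`` may also be applied standalone to an external cohort (always refit
on that cohort — transfer relies on the affine invariance of z-scores, never
on reusing training parameters).  ``exponentiate`` undoes a log transform for
cohorts distributed on log scale, and ``log_actb_normalize`` is the
single-sample alternative: log expression relative to a housekeeping gene,
requiring no cohort statistics at all.
"""

from __future__ import annotations

import math

import numpy as np

from .datamodel import ExpressionMatrix, NormalizationParams

__all__ = [
    "floor_baseline",
    "normalize_per_array",
    "normalize_per_feature",
    "zscore",
    "exponentiate",
    "log_actb_normalize",
    "normalize_chain",
]


def _require_stage(m: ExpressionMatrix, allowed: tuple[str, ...], op: str) -> None:
    if m.stage not in allowed:
        raise ValueError(
            f"{op} expects stage in {allowed}, got {m.stage!r}"
        )


def floor_baseline(m: ExpressionMatrix, floor: float = 0.1) -> ExpressionMatrix:
    """Replace every value below ``floor`` with ``floor`` (stage raw -> floored)."""
    _require_stage(m, ("raw",), "floor_baseline")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    values = m.values.copy()
    mask = values < floor  # NaN compares False, so missing cells stay missing
    values[mask] = floor
    return m.with_values(values, stage="floored")


def normalize_per_array(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its own 50th percentile (median).

    Medians use linear interpolation at even counts and ignore missing cells.
    After flooring every median is positive, so the division is safe; the
    post-condition (each column's median equals 1) is re-checked.
    """
    _require_stage(m, ("floored",), "normalize_per_array")
    med = np.nanmedian(m.values, axis=0)
    if np.any(~np.isfinite(med)) or np.any(med <= 0):
        bad = [m.sample_ids[j] for j in np.flatnonzero(~(med > 0))]
        raise ValueError(f"non-positive array median for samples {bad}")
    out = m.with_values(m.values / med[None, :], stage="array_norm")
    check = np.nanmedian(out.values, axis=0)
    if np.any(np.abs(check - 1.0) > 1e-12):
        raise AssertionError("per-array median not 1 after normalization")
    return out


def normalize_per_feature(m: ExpressionMatrix) -> tuple[ExpressionMatrix, np.ndarray]:
    """Divide each feature row by its median across samples.

    Returns the transformed matrix and the per-feature medians (stored into
    :class:`NormalizationParams` by :func:`normalize_chain`).
    """
    _require_stage(m, ("array_norm",), "normalize_per_feature")
    med = np.nanmedian(m.values, axis=1)
    bad = np.flatnonzero(~(med > 0))
    if bad.size:
        raise ValueError(
            f"non-positive feature median for {[m.feature_ids[i] for i in bad[:5]]}"
        )
    out = m.with_values(m.values / med[:, None], stage="feature_norm")
    return out, med


def zscore(
    m: ExpressionMatrix, allowed_stages: tuple[str, ...] | None = None
) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Standardize each feature to mean 0 and unit population variance.

    Uses the population standard deviation (divisor n).  May be applied to
    any pre-z-score stage: external cohorts are often z-scored directly.
    Constant features have undefined z-scores and must be filtered first.
    """
    if allowed_stages is None:
        allowed_stages = ("raw", "floored", "array_norm", "feature_norm")
    _require_stage(m, allowed_stages, "zscore")
    mu = np.nanmean(m.values, axis=1)
    sd = np.nanstd(m.values, axis=1)  # ddof=0: population convention
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            "constant features have undefined z-scores: "
            f"{[m.feature_ids[i] for i in bad[:10]]}"
        )
    out = m.with_values((m.values - mu[:, None]) / sd[:, None], stage="zscore")
    params = NormalizationParams(
        per_feature_mean=mu,
        per_feature_sd=sd,
        feature_ids=list(m.feature_ids),
    )
    return out, params


def exponentiate(m: ExpressionMatrix, base: float = math.e) -> ExpressionMatrix:
    """Map value -> base**value, undoing a log transform (stage stays raw).

    Needed before z-scoring a cohort that was deposited on log scale, so its
    dynamic range matches intensity-scale cohorts.
    """
    _require_stage(m, ("raw",), "exponentiate")
    if base <= 0:
        raise ValueError(f"base must be positive, got {base}")
    return m.with_values(np.power(base, m.values), stage="raw")


def log_actb_normalize(
    m: ExpressionMatrix,
    target_features: list[str],
    housekeeping_feature: str,
    base: float = math.e,
) -> ExpressionMatrix:
    """Per-sample log-ratio against a housekeeping gene (e.g. beta-actin).

    Output contains only ``target_features``; each value is
    ``log(g) - log(housekeeping)`` for that sample.  Because the housekeeping
    gene shares any global multiplicative factor on the sample, the ratio
    cancels it — this is the single-sample normalization that needs neither
    the full array nor a patient cohort.
    """
    _require_stage(m, ("raw",), "log_actb_normalize")
    if base <= 0 or base == 1:
        raise ValueError(f"log base must be positive and != 1, got {base}")
    hk = m.values[m.feature_index(housekeeping_feature)]
    idx = [m.feature_index(f) for f in target_features]
    tgt = m.values[idx]
    used = np.concatenate([tgt.ravel(), hk])
    if np.any(np.isnan(used)):
        raise ValueError("missing values in target or housekeeping features; impute first")
    if np.any(used <= 0):
        raise ValueError("log-ratio normalization requires strictly positive intensities")
    lb = math.log(base)
    values = (np.log(tgt) - np.log(hk)[None, :]) / lb
    out = m.subset_features(np.asarray(idx), stage="raw")
    return out.with_values(values, stage="log_actb")


def normalize_chain(
    m: ExpressionMatrix, floor: float = 0.1
) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Run the full N1 -> N4 chain and collect the fitted parameters."""
    m1 = floor_baseline(m, floor=floor)
    m2 = normalize_per_array(m1)
    m3, medians = normalize_per_feature(m2)
    m4, params = zscore(m3)
    params.floor = floor
    params.per_feature_median = medians
    return m4, params
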