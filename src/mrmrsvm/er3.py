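"""Fixed three-gene estrogen-receptor-status classifier.

The classifier is a published linear rule over cohort-level z-scores of three
probes — an anonymous transcript (probe A_32_P104334, GenBank AW972815),
GATA3 (A_23_P75056) and CA12 (A_23_P372234):

    score = -0.2466 * z_AW972815 + 2.2165 * z_GATA3 + 1.2934 * z_CA12 + w0

A tumor is called ER+ when the score is nonnegative.  The coefficients are
fixed; the intercept ``w0`` defaults to 0 on z-scored inputs and can be
overridden or refit on a labeled cohort (:func:`refit_threshold`), because
the published coefficients are known exactly while the intercept is not.

Cross-platform use: the three Agilent probes have fixed best-match
Affymetrix counterparts (230356_at, 209602_s_at, 203963_at).  Because the
classifier consumes z-scores refit on each target cohort, any per-probe
positive affine distortion between platforms cancels, which is what makes
the rule transferable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, LinearModel
from .normalize import exponentiate, zscore

__all__ = [
    "PROBE_AW972815",
    "PROBE_GATA3",
    "PROBE_CA12",
    "CANONICAL_PROBES",
    "COEFFICIENTS",
    "ProbeMap",
    "published_model",
    "three_gene_score",
    "map_probes",
    "classify_cohort",
    "affymetrix_probe_map",
    "refit_threshold",
]

PROBE_AW972815 = "A_32_P104334"
PROBE_GATA3 = "A_23_P75056"
PROBE_CA12 = "A_23_P372234"

CANONICAL_PROBES = (PROBE_AW972815, PROBE_GATA3, PROBE_CA12)
COEFFICIENTS = (-0.2466, 2.2165, 1.2934)

#: Housekeeping beta-actin probe used by the single-sample log-ratio variant.
ACTB_PROBE = "A_23_P135769"


@dataclass
class ProbeMap:
    """One-to-one mapping from a target platform's probe ids to canonical ids."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        targets = list(self.entries.values())
        if len(set(self.entries)) != len(self.entries) or len(set(targets)) != len(targets):
            raise ValueError("probe map must be one-to-one")

    @classmethod
    def identity(cls, probes=CANONICAL_PROBES) -> "ProbeMap":
        return cls({p: p for p in probes})

    @classmethod
    def from_tsv(cls, path) -> "ProbeMap":
        entries = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                src, dst = line.split("\t")[:2]
                entries[src.strip()] = dst.strip()
        return cls(entries)


def affymetrix_probe_map() -> ProbeMap:
    """Packaged Affymetrix -> Agilent best-match probe map (three entries)."""
    path = resources.files("mrmrsvm") / "resources" / "probe_map_affymetrix.tsv"
    return ProbeMap.from_tsv(path)


def published_model(threshold: float = 0.0) -> LinearModel:
    """The fixed three-gene rule as a :class:`LinearModel` over z-scores."""
    return LinearModel(
        features=list(CANONICAL_PROBES),
        weights=np.asarray(COEFFICIENTS),
        threshold=threshold,
        training_stage="zscore",
        provenance="published three-gene ER-status classifier",
    )


def three_gene_score(z_aw972815, z_gata3, z_ca12, threshold: float = 0.0):
    """Linear score over the three probes' z-scores (vectorized)."""
    w = COEFFICIENTS
    return (
        w[0] * np.asarray(z_aw972815, dtype=float)
        + w[1] * np.asarray(z_gata3, dtype=float)
        + w[2] * np.asarray(z_ca12, dtype=float)
        + threshold
    )


def map_probes(cohort: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Extract the mapped probes and rename them to the canonical ids."""
    missing = [p for p in probe_map.entries if p not in cohort.feature_ids]
    if missing:
        raise KeyError(f"cohort lacks mapped probes: {missing}")
    idx = np.asarray([cohort.feature_index(p) for p in probe_map.entries])
    sub = cohort.subset_features(idx)
    sub.feature_ids = [probe_map.entries[p] for p in probe_map.entries]
    return sub


def classify_cohort(
    cohort: ExpressionMatrix,
    probe_map: ProbeMap | None = None,
    exponentiate_base: float | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Apply the three-gene rule to a raw-intensity cohort.

    Pipeline: optional probe mapping -> optional exponentiation (for cohorts
    deposited on log scale) -> per-probe z-scores fitted on THIS cohort ->
    linear score -> call (``ER+`` iff score >= 0).  Only the three probes are
    z-scored; training-cohort statistics are never reused.

    Returns a DataFrame indexed by sample id with ``score`` and ``er_call``
    columns; positive/negative counts are in ``df.attrs["counts"]``.
    """
    if cohort.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    if probe_map is not None:
        cohort = map_probes(cohort, probe_map)
    missing = [p for p in CANONICAL_PROBES if p not in cohort.feature_ids]
    if missing:
        raise KeyError(f"cohort lacks required probes: {missing}")
    sub = cohort.subset_features(
        np.asarray([cohort.feature_index(p) for p in CANONICAL_PROBES])
    )
    if np.any(np.isnan(sub.values)):
        raise ValueError("missing values in classifier probes; impute first")
    if exponentiate_base is not None:
        sub = exponentiate(sub, base=exponentiate_base)
    if sub.stage != "zscore":
        sub, _ = zscore(sub)
    z = sub.values
    scores = three_gene_score(z[0], z[1], z[2], threshold=threshold)
    calls = np.where(scores >= 0, "ER+", "ER-")
    df = pd.DataFrame({"score": scores, "er_call": calls}, index=sub.sample_ids)
    df.index.name = "sample_id"
    df.attrs["counts"] = {
        "positive": int((calls == "ER+").sum()),
        "negative": int((calls == "ER-").sum()),
    }
    return df


def refit_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Intercept maximizing accuracy of ``score + w0 >= 0`` on a labeled cohort.

    Candidate cutoffs are midpoints between consecutive sorted scores (plus
    the two outer extremes); among equally accurate cutoffs the smallest is
    kept, making the refit deterministic.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=bool).ravel()
    if scores.size != y.size or scores.size == 0:
        raise ValueError("scores and labels must align and be non-empty")
    s = np.sort(np.unique(scores))
    cuts = np.concatenate(([s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]))
    best_acc, best_cut = -1.0, cuts[0]
    for c in cuts:
        acc = float(np.mean((scores >= c) == y))
        # strict > keeps the first (smallest) equally accurate cutoff
        if acc > best_acc:
            best_acc, best_cut = acc, c
    return float(-best_cut)
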