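"""Synthetic microarray-like cohorts with planted class signal.

The generator emulates the structure of a one-color expression cohort:
log-normal raw intensities over hundreds to tens of thousands of probes, a
minority of class-informative features whose log intensity shifts between
classes, groups of redundant probes tracking each informative one (the
duplicate-probe phenomenon mRMR's redundancy penalty exists for), a sea of
class-independent noise probes, a stable housekeeping gene, and per-cell
missingness.  The planted truth (which probes carry signal) is returned
alongside the cohort so recovery can be scored.

Defaults mirror the study conditions every downstream default was chosen
for: n = 200 samples, positive-class prior 112/176, 3 informative probes
with a 2-SD log-scale effect, 2 redundant probes per informative one,
989 noise probes, 1 housekeeping probe and 98% presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix, LabeledDataset
from .er3 import ProbeMap

__all__ = ["SyntheticConfig", "generate_cohort", "generate_platform_pair"]

HOUSEKEEPING_ID = "ACTB"


@dataclass
class SyntheticConfig:
    """Knobs of the cohort generator; identical config + seed => identical data.

    ``effect_size`` is the between-class shift of each informative feature's
    log intensity, in units of its within-class standard deviation (1 on log
    scale).  ``platform_*`` fields only matter for
    :func:`generate_platform_pair`.
    """

    n_samples: int = 200
    prior_positive: float = 112 / 176
    n_informative: int = 3
    effect_size: float = 2.0
    effect_signs: tuple[int, ...] | None = None  # +1 up in positives (default)
    n_redundant_per_informative: int = 2
    redundancy_noise_sd: float = 0.3
    n_noise: int = 989
    presence_rate: float = 0.98
    housekeeping: bool = True
    unannotated_fraction: float = 0.0
    informative_ids: tuple[str, ...] | None = None
    base_log_mean: float = 3.0
    base_log_sd: float = 0.5
    platform_gain_sd: float = 0.3
    platform_offset_sd: float = 0.5
    platform_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_positive < 1.0:
            raise ValueError("prior_positive must be strictly inside (0, 1)")
        if not 0.0 < self.presence_rate <= 1.0:
            raise ValueError("presence_rate must be in (0, 1]")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.informative_ids is not None and len(self.informative_ids) != self.n_informative:
            raise ValueError("informative_ids must name every informative feature")
        if self.effect_signs is not None and len(self.effect_signs) != self.n_informative:
            raise ValueError("effect_signs must have one entry per informative feature")

    @property
    def n_features(self) -> int:
        return (
            self.n_informative * (1 + self.n_redundant_per_informative)
            + self.n_noise
            + (1 if self.housekeeping else 0)
        )


def _feature_ids(cfg: SyntheticConfig) -> tuple[list[str], dict]:
    inf = (
        list(cfg.informative_ids)
        if cfg.informative_ids is not None
        else [f"INF{i:04d}" for i in range(cfg.n_informative)]
    )
    red: dict[str, list[str]] = {
        p: [f"{p}_dup{k}" for k in range(cfg.n_redundant_per_informative)] for p in inf
    }
    noise = [f"NOI{i:04d}" for i in range(cfg.n_noise)]
    ids = []
    for p in inf:  # parent immediately followed by its redundant copies
        ids.append(p)
        ids.extend(red[p])
    ids.extend(noise)
    truth = {
        "informative": inf,
        "redundant": red,
        "noise": noise,
        "housekeeping": HOUSEKEEPING_ID if cfg.housekeeping else None,
        "planted": inf + [r for rs in red.values() for r in rs],
    }
    if cfg.housekeeping:
        ids.append(HOUSEKEEPING_ID)
    return ids, truth


def _latent_log_matrix(
    cfg: SyntheticConfig, rng: np.random.Generator, y: np.ndarray
) -> tuple[np.ndarray, list[str], dict]:
    """Log-scale signal matrix (features x samples) and the planted truth."""
    ids, truth = _feature_ids(cfg)
    n = cfg.n_samples
    signs = (
        np.ones(cfg.n_informative)
        if cfg.effect_signs is None
        else np.asarray(cfg.effect_signs, dtype=float)
    )
    rows = []
    baselines = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=len(ids))
    b = iter(baselines)
    inf_rows = {}
    for j in range(cfg.n_informative):
        shift = signs[j] * cfg.effect_size * (y.astype(float) - 0.5)
        row = next(b) + shift + rng.normal(0.0, 1.0, size=n)
        inf_rows[truth["informative"][j]] = row
        rows.append(row)
        for _ in range(cfg.n_redundant_per_informative):
            next(b)  # redundant probes track the parent, not their own baseline
            rows.append(row + rng.normal(0.0, cfg.redundancy_noise_sd, size=n))
    for _ in range(cfg.n_noise):
        rows.append(next(b) + rng.normal(0.0, 1.0, size=n))
    if cfg.housekeeping:
        rows.append(cfg.base_log_mean + rng.normal(0.0, 0.1, size=n))
    return np.vstack(rows) if rows else np.empty((0, n)), ids, truth


def _draw_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    y = rng.random(cfg.n_samples) < cfg.prior_positive
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError(
            "degenerate label draw (<2 samples in a class); adjust prior/seed"
        )
    return y


def generate_cohort(cfg: SyntheticConfig) -> tuple[LabeledDataset, dict]:
    """Generate one raw-intensity labeled cohort plus its planted truth.

    Signals are planted on log2 scale (the field's log-intensity
    convention), then exponentiated to the nonnegative raw-intensity scale
    the normalization chain expects.  Missing cells are drawn per cell with
    probability ``1 - presence_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    y = _draw_labels(cfg, rng)
    L, ids, truth = _latent_log_matrix(cfg, rng, y)
    values = np.exp2(L)  # log2 is the field's log-intensity convention
    if cfg.presence_rate < 1.0:
        missing = rng.random(values.shape) >= cfg.presence_rate
        values = values.copy()
        values[missing] = np.nan
    annotated = np.ones(len(ids), dtype=bool)
    if cfg.unannotated_fraction > 0:
        n_un = int(round(cfg.unannotated_fraction * len(ids)))
        annotated[rng.choice(len(ids), size=n_un, replace=False)] = False
    matrix = ExpressionMatrix(
        feature_ids=ids,
        sample_ids=[f"S{i:04d}" for i in range(cfg.n_samples)],
        values=values,
        annotated=annotated,
        stage="raw",
    )
    return LabeledDataset(matrix=matrix, y=y), truth


def generate_platform_pair(
    cfg: SyntheticConfig,
) -> tuple[LabeledDataset, LabeledDataset, ProbeMap, dict]:
    """Two cohorts measuring the same samples on two distorted platforms.

    Both share the latent log-scale signal; platform A adds only measurement
    noise, platform B additionally applies a per-feature gain
    ``~ LogNormal(0, platform_gain_sd)`` and additive offset
    ``~ Normal(0, platform_offset_sd)`` on the raw-intensity scale, and
    renames every probe.  Returns (A, B, map from B ids to A ids, truth).
    Rare negative intensities after the offset are clipped to a small
    positive floor so both cohorts stay on the raw-intensity convention.
    """
    rng = np.random.default_rng(cfg.seed)
    y = _draw_labels(cfg, rng)
    L, ids, truth = _latent_log_matrix(cfg, rng, y)
    n_feat = len(ids)
    raw_a = np.exp2(L + rng.normal(0.0, cfg.platform_noise_sd, size=L.shape))
    gain = np.exp(rng.normal(0.0, cfg.platform_gain_sd, size=n_feat))
    offset = rng.normal(0.0, cfg.platform_offset_sd, size=n_feat)
    raw_b = gain[:, None] * np.exp2(
        L + rng.normal(0.0, cfg.platform_noise_sd, size=L.shape)
    ) + offset[:, None]
    np.clip(raw_b, 1e-3, None, out=raw_b)

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    mat_a = ExpressionMatrix(ids, samples, raw_a, stage="raw")
    ids_b = [f"B_{f}" for f in ids]
    mat_b = ExpressionMatrix(ids_b, samples, raw_b, stage="raw")
    probe_map = ProbeMap({b: a for b, a in zip(ids_b, ids)})
    return (
        LabeledDataset(matrix=mat_a, y=y),
        LabeledDataset(matrix=mat_b, y=y.copy()),
        probe_map,
        truth,
    )
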