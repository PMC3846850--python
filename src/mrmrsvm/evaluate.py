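"""End-to-end evaluation protocols on synthetic cohorts.

These drive the whole pipeline — generate a raw cohort, filter, impute,
normalize, fit the feature-selecting SVM — and score it against the planted
truth, or measure cross-platform call agreement for the fixed three-gene
classifier.  Both the test suite and the reproduction script use them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datamodel import LabeledDataset, filter_features, impute_missing
from .er3 import CANONICAL_PROBES, classify_cohort, map_probes
from .learner import FeatureSelectingSVM
from .normalize import normalize_chain
from .synthetic import SyntheticConfig, generate_cohort, generate_platform_pair

__all__ = [
    "prepare_cohort",
    "planted_recovery_trial",
    "null_cohort_trial",
    "crossplatform_trial",
]


def prepare_cohort(cfg: SyntheticConfig) -> tuple[LabeledDataset, dict]:
    """Generate a raw cohort and run it through filter -> impute -> N1..N4."""
    raw, truth = generate_cohort(cfg)
    mat = filter_features(raw.matrix, require_annotation=True)
    mat, _ = impute_missing(mat)
    mz, _ = normalize_chain(mat)
    return LabeledDataset(matrix=mz, y=raw.y), truth


def planted_recovery_trial(
    seed: int,
    cfg: SyntheticConfig | None = None,
    r_max: int = 18,
    k: int = 10,
    pool_size: int = 100,
) -> dict:
    """Fit on one synthetic cohort; score selection and held-out accuracy.

    The held-out cohort is generated from the same configuration with an
    independent seed and normalized independently (as a validation cohort
    would be); the fitted model is applied to its z-scores.
    """
    cfg = replace(cfg or SyntheticConfig(), seed=seed)
    train, truth = prepare_cohort(cfg)
    res = FeatureSelectingSVM(train, r_max=r_max, n_folds=k, pool_size=pool_size).fit(
        seed=seed
    )
    test, _ = prepare_cohort(replace(cfg, seed=seed + 10_000))
    pred = res.predict(test.matrix.to_frame()) == "positive"
    planted = set(truth["planted"])
    cv_mean, cv_sd = res.cv_accuracy
    return {
        "r_star": res.r_star,
        "selected": list(res.model.features),
        "n_planted_selected": len(planted & set(res.model.features)),
        "heldout_accuracy": float(np.mean(pred == test.y)),
        "cv_mean": cv_mean,
        "cv_sd": cv_sd,
    }


def null_cohort_trial(
    seed: int,
    cfg: SyntheticConfig | None = None,
    r_max: int = 10,
    k: int = 10,
    pool_size: int = 100,
) -> dict:
    """Fit on a cohort with no informative features (effect size 0).

    Under the null the CV accuracy should sit within binomial noise of the
    majority-class rate.
    """
    cfg = replace(cfg or SyntheticConfig(), seed=seed, effect_size=0.0)
    ds, _ = prepare_cohort(cfg)
    res = FeatureSelectingSVM(ds, r_max=r_max, n_folds=k, pool_size=pool_size).fit(
        seed=seed
    )
    majority = max(ds.prior.values())
    cv_mean, cv_sd = res.cv_accuracy
    # 3-sigma binomial band around the majority rate at the cohort size
    band = 3.0 * float(np.sqrt(majority * (1 - majority) / ds.n_samples))
    return {
        "cv_mean": cv_mean,
        "cv_sd": cv_sd,
        "majority_rate": majority,
        "binomial_3sd": band,
        "within_band": bool(abs(cv_mean - majority) <= band),
    }


def crossplatform_trial(seed: int, n_samples: int = 150, n_noise: int = 47) -> dict:
    """Three-gene classifier agreement across a simulated platform pair.

    The three canonical probes are planted as informative features (signs
    matching the classifier's coefficient signs) on two platforms that share
    the latent signal but differ by per-probe gain, offset and noise.
    """
    cfg = SyntheticConfig(
        n_samples=n_samples,
        n_informative=3,
        informative_ids=tuple(CANONICAL_PROBES),
        effect_signs=(-1, 1, 1),  # AW972815 down, GATA3 / CA12 up in positives
        n_redundant_per_informative=0,
        n_noise=n_noise,
        presence_rate=1.0,
        seed=seed,
    )
    ds_a, ds_b, probe_map, _ = generate_platform_pair(cfg)
    calls_a = classify_cohort(ds_a.matrix)
    calls_b = classify_cohort(map_probes(ds_b.matrix, probe_map))
    agree = float(np.mean(calls_a["er_call"].to_numpy() == calls_b["er_call"].to_numpy()))
    acc_a = float(np.mean((calls_a["er_call"].to_numpy() == "ER+") == ds_a.y))
    return {"agreement": agree, "accuracy_platform_a": acc_a}
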