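# mrmrsvm

Parsimonious linear classifiers of a binary clinical phenotype from
genome-wide expression data — built for the setting where tens of thousands
of microarray probes describe a few hundred tumors and the deliverable is a
rule a clinical lab could actually run, such as an estrogen-receptor (ER)
status call from a handful of transcripts.

The package provides, as a library and a CLI:

- **Normalization** — the standard one-color chain (floor at 0.1 → per-array
  median scaling → per-feature median centering → per-feature z-scores),
  plus exponentiation for log-scale cohorts and a single-sample
  `log g − log g_ACTB` housekeeping variant.
- **Relevance and ranking** — Parzen-window mutual information
  `I(G;C) = Σ_c P(c) ∫ p(g|c) log₂ [p(g|c)/p(g)] dg` (Gaussian kernels,
  Silverman bandwidths, 512-point quadrature, reported in bits) and greedy
  mRMR ranking with the difference criterion
  `I(f;C) − (1/t) Σ_{s∈selected} I(f;s)`, which demotes probes that
  duplicate already-selected ones.  Jaccard overlap quantifies ranking
  stability between cohorts.
- **Feature-selecting SVM** — a soft-margin linear SVM (C = 1) wrapped in
  nested cross-validation: per-fold mRMR ranking, an accuracy curve
  (a_r, σ_r) over model sizes r = 1..r_max, and the one-SD rule
  `r* = min { r : a_r + σ_r ≥ max_r' a_r' }` — the smallest model
  statistically indistinguishable from the best.
- **A fixed three-gene ER rule** — the published linear classifier
  `−0.2466·z(AW972815) + 2.2165·z(GATA3) + 1.2934·z(CA12) ≥ 0 ⇒ ER+`
  over cohort-level z-scores, with a packaged Agilent↔Affymetrix probe map;
  z-score refitting per cohort makes the call invariant to per-probe affine
  platform distortions.
- **Synthetic cohorts** — log2-normal intensity cohorts with planted
  informative probes, redundant duplicate-probe groups, noise probes, a
  housekeeping gene, missingness, and distorted platform pairs, so the whole
  pipeline is testable end to end with no downloads.

## Worked example

Fit the feature-selecting SVM on a synthetic cohort with three planted
informative probes (effect 2 SD on log2 scale) hidden among ~1,000 features:

```python
from mrmrsvm import (SyntheticConfig, generate_cohort, filter_features,
                     impute_missing, normalize_chain, LabeledDataset,
                     FeatureSelectingSVM)

cfg = SyntheticConfig(seed=17)              # n=200, 3 informative, 989 noise
raw, truth = generate_cohort(cfg)
mat = filter_features(raw.matrix)           # presence >= 25% and annotated
mat, _ = impute_missing(mat)
z, _ = normalize_chain(mat)                 # floor -> array -> feature -> z
cohort = LabeledDataset(matrix=z, y=raw.y)

res = FeatureSelectingSVM(cohort, r_max=10).fit(seed=17)
print(res.summary())
print("planted informative probes:", truth["informative"])
```

which prints:

```
Feature-selecting linear SVM
================================================================
samples: 200   features: 999   folds: 10   r_max: 10
prior positive: 0.6900
selected model size r* = 3 (one-SD rule)
CV accuracy at r*: 0.9700 +/- 0.0422

rank  probe                MI (bits)     mRMR    weight
----------------------------------------------------------------
   1  INF0002_dup1            0.4394   0.4394    2.1653
   2  INF0001                 0.4314   0.2232    2.8138
   3  INF0000                 0.3714   0.1041    2.4972
----------------------------------------------------------------
threshold (w0): +3.4162

planted informative probes: ['INF0000', 'INF0001', 'INF0002']
```

Reading it: the one-SD rule settled on three probes; the ranking found one
representative of each planted signal group (rank 1 is a redundant copy of
`INF0002` — indistinguishable from its parent by design), each probe's
relevance is its mutual information with the class in bits, the mRMR column
is the greedy criterion value at selection time (relevance minus mean
redundancy with earlier picks), and the weights/threshold define the fitted
linear rule on z-scored inputs.  Mean held-out fold accuracy at r* was 97%
± 4.2% (SD over the 10 folds).

The same pipeline from a shell:

```sh
mrmrsvm simulate --out-prefix sim --seed 17
mrmrsvm normalize --matrix sim_matrix.tsv --out sim_z.tsv
mrmrsvm train --matrix sim_z.tsv --labels sim_labels.tsv \
              --r-max 10 --seed 17 --out model.json
mrmrsvm predict --model model.json --matrix sim_z.tsv --out calls.tsv
```

and the fixed three-gene rule on an Affymetrix cohort deposited on log
scale:

```sh
mrmrsvm er3 --matrix cohort.tsv --platform affymetrix \
            --exponentiate-base 2 --out er_calls.tsv
```

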