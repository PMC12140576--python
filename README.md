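# connectofp

Functional connectome fingerprinting with tangent-space SPD geometry.

Functional connectomes (FCs) — matrices of pairwise Pearson correlations
between parcellated brain-region time courses — differ reproducibly between
individuals, enough to act as a "fingerprint" that identifies a subject
across scanning sessions. FCs are symmetric positive-semidefinite matrices
and therefore live on a curved manifold, so plain Euclidean comparisons
between them are biased. This package implements and compares three ways of
measuring FC distances for subject identification:

- **non-tangent**: the correlation distance `d = 1 − corr(vec(P_i), vec(P_j))`
  computed on the upper triangles of the raw FCs;
- **tangent**: each FC is first projected onto the flat space tangent to the
  SPD manifold at a reference point,
  `Q = logm(C_ref^{−1/2} P C_ref^{−1/2})`, with the log-Euclidean mean
  `C_ref = expm(N^{−1} Σ_i logm(P_i + λI))` as reference (λ = 1 by default),
  before the same correlation distance is applied;
- **geodesic**: the affine-invariant manifold distance
  `δ(P_1, P_2) = ‖logm(P_1^{−1/2} P_2 P_1^{−1/2})‖_F` after λI regularisation.

Fingerprinting is treated as binary classification of pair distances
(same-subject vs different-subject, positive call when `d < θ`), evaluated
with accuracy, ROC and precision–recall curves, their AUCs, and the
separability margin `Δ = min D_between − max D_within`. Experiment drivers
cover cross-condition reference choice, per-subnetwork fingerprinting,
bootstrap subsampling of recording length (windows of `2l+1` frames,
`⌊L/2l⌋` trials), database-style identification (k known FCs per subject,
nearest mean distance, 100 draws), session drift and within-session block
structure.

Because the analyses are validated on synthetic data, the package ships a
first-class cohort generator: subjects get idiosyncratic low-rank-plus-
diagonal correlation structure (weight `distinctiveness`), sessions perturb
it (weight `session_noise`), task conditions add a shared latent signal to
chosen regions, and frames are censored like motion scrubbing. It is aimed
at researchers studying individual variability of functional connectivity
who want a tested, deterministic reference implementation of the
tangent-space pipeline.

## Worked example

```python
from connectofp import (CohortConfig, ExperimentConfig, generate_cohort,
                        run_fingerprint, database_identification)

recordings = generate_cohort(CohortConfig(seed=0))  # 9 subjects x 10 sessions
res = run_fingerprint(recordings, ExperimentConfig(method="tangent"))
print(res.auc_roc, res.max_acc, round(res.delta, 3))
rate = database_identification(recordings, 1, ExperimentConfig(method="tangent"))
print(rate)
```

prints

```
1.0 1.0 0.424
1.0
```

i.e. on the default strongly fingerprinted cohort the tangent method
separates all 810 within-subject from all 7,200 between-subject pairs
(ROC-AUC 1, peak accuracy 1, positive margin Δ = 0.424), and identifies the
subject of an unknown FC from a single known FC per subject in 100/100
random draws.

The numbered scripts under `analysis/` run the full study on synthetic
cohorts — method comparison, reference-condition grid, subnetworks,
recording length, database size, drift and session blocks — writing tidy
tables under `results/`. For example `python analysis/06_recording_length.py`
shows the data-efficiency gap at 17-frame windows: tangent AUC 0.770 vs
non-tangent 0.646, both rising monotonically with window length.

A `connectofp` CLI (`simulate`, `fc`, `fingerprint`, `crossref`,
`subnetworks`, `subsample`, `identify`, `drift`, `blocks`) exposes the same
stages over plain-text recordings, masks and manifests; see
`connectofp --help`.

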