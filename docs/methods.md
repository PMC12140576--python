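# Methods

## The model

A functional connectome is the matrix `P` of pairwise zero-lag Pearson
correlations between `n` parcellated region time courses, computed after
censored frames are removed (kept frames are concatenated; zero-lag
correlation does not care about the gaps). `P` is symmetric positive
semidefinite with unit diagonal, an element of the elliptope inside the SPD
cone. Three distances between connectomes are implemented:

- **Correlation distance** (non-tangent): `1 − corr` of the two strictly
  upper-triangular vectors, taken in fixed row-major order. It lies in
  [0, 2] and is invariant to positive affine maps of either argument. The
  printed form of the distance omits the sample-size normalisation; we
  define the subtracted term as the standard Pearson coefficient, which is
  the only convention giving a unit diagonal upstream and the [0, 2] range
  here.
- **Tangent-space distance**: connectomes are projected onto the tangent
  space at a reference `C_ref` via `Q = logm(C_ref^{−1/2} P C_ref^{−1/2})`
  and compared with the same correlation distance there. The reference is
  the log-Euclidean mean of a chosen FC set. The space at the reference is
  flat, so Euclidean-style comparisons are unbiased.
- **Geodesic (affine-invariant) distance**
  `sqrt(Σ_k log² eig_k(P₂, P₁))` on the λ-regularised pair, computed from
  the generalized symmetric eigenproblem.

All matrix functions (log, exp, inverse square root) go through the
symmetric eigendecomposition — never a general Schur-based matrix function —
because every input is symmetric by invariant and the symmetric path is
stable and real. Outputs are re-symmetrised and FC diagonals pinned to
exactly 1 to stop floating-point drift from accumulating through the
pipeline.

### Regularisation and degenerate inputs

Short recordings (T < n) give rank-deficient FCs whose matrix log is
undefined. Two mechanisms keep the geometry computable:

- **λ-shift**: `C + λI` raises every eigenvalue by exactly λ. The default
  λ = 1 applies to the reference mean and the geodesic distance; λ ∈
  {0.1, 10} are supported configuration values. Inside the log-Euclidean
  mean the shift is applied to *each* input before its log (the only way
  the mean is defined for singular inputs; it reduces to the plain formula
  for PD inputs at λ = 0). A switch (`regularize_inputs=False`) instead
  takes raw logs and shifts the final mean, for strictly PD input sets.
- **Eigenvalue floor**: the whitened matrix `C_ref^{−1/2} P C_ref^{−1/2}`
  can still have (near-)zero eigenvalues. The projection floors its
  spectrum at `eigenvalue_floor` (default 1e−6) before the log and records
  the floor on each TangentFC. With floor 0 the projection is exactly
  invertible (`P = C_ref^{1/2} expm(Q) C_ref^{1/2}`), and a nonpositive
  eigenvalue is an error advising a floor or larger λ.

## Classification metrics

Ordered off-diagonal entries of the labeled distance matrix are split by
subject equality: an m-recording cohort yields `m² − m` ordered pairs (the
9×10 design: 810 intra, 7,200 inter; each unordered pair counted twice,
which doubles counts but leaves rates and AUCs unchanged). A pair is called
same-subject when `d < θ` (strict; boundary equality is a negative call).

- The threshold grid is the set of distinct pooled distances plus ±∞
  sentinels, giving exact curves rather than grid approximations.
- ROC: the curve (inter-CDF(θ), intra-CDF(θ)); trapezoidal area over this
  grid equals the Mann–Whitney statistic with half credit for ties, so
  identical class distributions score exactly 0.5. This tie convention is
  this package's explicit choice.
- PR: precision is held right-continuous and integrated stepwise
  (average precision), avoiding the over-optimism of trapezoidal PR
  interpolation under class imbalance; its chance floor is the intra-class
  prevalence. Precision at zero predicted positives is defined as 1.
- Δ = min(inter) − max(intra) is positive iff some θ separates perfectly
  (equivalently AUC = 1).

## Experiment drivers

All drivers rebuild the tangent reference in the same space as the FCs
being compared — restricted to the subnetwork, windowed to the bootstrap
segment, or limited to the identification database — since the projection
requires commensurate dimensions and a reference estimated from the data
actually available to the comparison.

- **Recording-length bootstrap**: per trial each recording independently
  contributes one window of `2l+1` post-censoring frames centred uniformly
  among positions with l-frame margins (no wraparound or clipping, so all
  windows have equal length); `⌊L/2l⌋` trials with `L` the shortest
  censored recording, so short windows get proportionally more trials.
  Independent window positions per recording are this package's reading of
  an ambiguous procedure (one shared position would correlate the windows).
- **Database identification**: k FCs per subject are drawn without
  replacement; the tangent reference uses the N·k database FCs only; a
  single target is drawn from the remainder and assigned by lowest mean
  distance to each subject's database FCs; 100 trials by default. Ties
  (probability zero under continuous distances) resolve to the lowest
  subject label for reproducibility.
- **Drift**: distances from each subject's first-session FC to each later
  session, pooled least-squares slope over lags, permutation p-value
  (999 permutations of lag order within subject). The permutation test is
  this package's choice of trend assessment.
- **Session blocks**: kept frames split into equal contiguous blocks
  (remainder truncated); within-subject block-pair distances compared
  same-session vs different-session by a two-sided Mann–Whitney test (again
  this package's choice of test).

## The synthetic cohort generator

The generator emulates the *structure* of a many-session precision-imaging
design, not any particular dataset. Latent covariances are low-rank-plus-
diagonal (`AAᵀ + I`, Gaussian factors, rank 5 by default) renormalised to
correlation form — guaranteeing strict positive definiteness and FC-like
block structure. Mixing happens in covariance space, then renormalises:

- subject structure: `normalize((1−δ)·Σ_shared + δ·Σ_subject)` with
  δ = `distinctiveness` (default 0.8);
- session covariance: `normalize((1−ρ)·Σ_subject-structure + ρ·Σ_session)`
  with ρ = `session_noise` (default 0.2), a fresh `Σ_session` per session;
- frames are i.i.d. zero-mean Gaussian draws from the session covariance
  (Cholesky), `T = 300` per session before censoring;
- task modulation adds a shared unit-variance latent signal, scaled by the
  condition's modulation strength, to the configured region subset;
- censoring removes `⌊0.28·T⌋` frames uniformly at random (0.28 being a
  typical motion-scrubbing fraction for resting-state data).

Mixing on covariances rather than time series gives direct control of the
identity and session-noise weights in exactly the space where the analysis
operates. Defaults (9 subjects × 10 sessions, 30 regions, 300 frames) are
desk-scale: distance behaviour is robust to parcellation granularity, and
the tests target pipeline properties, not any dataset's numeric values.
All randomness flows from one seed through named SeedSequence spawn keys
per (stage, subject, session, condition), so cohorts are bit-reproducible
and any single recording can be regenerated in isolation.

What the generator does *not* emulate: hemodynamics and autocorrelated
noise (frames are i.i.d.), spatial geometry of parcels, heavy-tailed motion
artifacts, real censoring's temporal clustering, and the empirical
distribution of between-subject FC variability. Passing tests therefore
demonstrate that the pipeline's statistical machinery behaves correctly
under a controlled generative model — chance level without identity signal,
perfect recovery with a strong one, tangent superiority at short recording
lengths — not that any particular real-data effect size is reproduced.

## Study conditions used in tests and drivers

- Strong regime (δ = 0.8, ρ = 0.2, T = 300): both methods saturate; used
  for perfect-recovery and determinism checks.
- Null regime (δ = 0): no identity signal; AUC is at chance across seeds.
- Moderate regime (δ = 0.3, ρ = 0.4): chosen for the method-comparison and
  data-efficiency analyses because neither method sits at the AUC ceiling
  there, making paired comparisons informative; with 50-frame recordings
  the tangent method's advantage is large and consistent across seeds.
- Bootstrap window half-widths l ∈ {8, 23, 75} (17/47/151 frames) span the
  short-to-long recording range at the default 216 kept frames.

## Numerical choices and limitations

- Symmetry tolerance 1e−8 on matrix-function inputs; FC asymmetry beyond
  1e−10 is an error rather than silently symmetrised away.
- Zero-variance regions are an error, not dropped: every FC must keep the
  full region set or downstream comparisons are meaningless.
- The correlation distance is not a metric (no triangle inequality); the
  geodesic distance is, and its sensitivity to λ is exposed rather than
  hidden (finite and continuous across the λ grid for singular inputs).
- The log-Euclidean mean is the only centroid implemented; Karcher-mean
  iteration is out of scope.
- Identification with very small per-subject session counts limits k; the
  driver refuses k at or above the smallest session count.
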