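# Methods

## The model

A subject is a T × N matrix of ROI time series (rows = time points,
columns = regions; defaults T = 130, N = 116 for an AAL parcellation).
Functional connectivity is the Pearson matrix `PC_ij = cov(L_i, L_j) /
(σ_i σ_j)`; it is symmetric with unit diagonal and entries in [−1, 1].
Downstream random walks need non-negative weights, so a `negative_policy`
maps signed correlations to weights: `absolute` (default, w = |PC|) keeps
anticorrelation topology; `clip` (w = max(PC, 0)) discards it.  No
sparsification is applied by default; a proportional threshold
(`keep_fraction`) is exposed for sensitivity analyses only.

### node2vec

The walk is second-order.  From current node v with predecessor t, the
probability of stepping to neighbor x is proportional to
`α_pq(t, x) · w_vx` with `α = 1/p` if x = t (return), 1 if x is adjacent
to t, and `1/q` otherwise.  The first step of a walk uses the static
weights alone.  Defaults: p = 0.1, q = 1.6 (strongly local walks),
walk length 10, 200 walks per node, 32 dimensions, window 10.  The walk
sampler is a vectorized cumulative-sum draw over the dense weight row —
behaviorally equivalent to alias sampling, verified against the analytic
transition distribution by Monte-Carlo (10⁵ draws per state, 3σ band).

The skip-gram uses an **exact softmax** over the node vocabulary rather
than negative sampling: with at most a few hundred ROIs the full gradient
is cheap, and exactness makes training deterministic and testable
(analytic vs central-difference gradients agree to < 10⁻⁵ relative
error).  Training is mini-batch gradient ascent on the mean context
log-likelihood (batch 128, learning rate 0.5 with linear decay, 5 epochs
by default).  A per-pair SGD loop at word2vec's classical 0.025 step is
prohibitively slow in pure numpy at these corpus sizes; the batch-mean
formulation with a correspondingly larger step trains the same objective
and satisfies the same contracts (final-epoch mean log-likelihood ≥ first
epoch; disconnected cliques separate in cosine similarity).

**Cross-subject comparability.** A node embedding is only identified up to
the optimization path, so all subjects share one seeded initializer, one
walk-RNG stage seed and a fixed node order: identical graphs produce
identical embeddings, and differences between subject feature vectors are
attributable to their connectivity, not to seed drift.  No Procrustes
alignment is applied.  Nodes absent from a corpus (possible under `clip`)
keep their initialization row and are flagged.  The subject feature vector
is the row-wise concatenation of the V × dim embedding in atlas order.

### Feature selection

All rankers consume standardized features (train-fold statistics only) and
return a true permutation, ties broken by ascending feature index.

* **LASSO** — objective `(1/2n)‖y − Xβ − β₀‖² + α‖β‖₁` (coordinate-descent
  convention), so all coefficients vanish exactly at
  `α_max = max_j |x_jᵀ(y − ȳ)|/n`; with a single standardized feature,
  `β = soft(xᵀy/n, α)`.  Ranking by |β| descending; zero-coefficient
  features follow, ordered by absolute marginal correlation.
* **SVM-RFE** — linear SVM at C = 1, squared-weight scores, eliminate the
  single worst feature, refit, repeat; ranking is the reversed elimination
  order.  An optional `step` (count or fraction) removes several features
  per round for large D; the cross-validated pipeline uses step = 0.2
  because 1-per-round elimination of ~10³ features in every fold is not
  tractable.
* **FSASL** (unsupervised) — alternating minimization of
  `‖WᵀX − WᵀXS‖² + α‖S‖₁ + β Σ_ij (‖Wᵀx_i − Wᵀx_j‖² P_ij + μ P_ij²) +
  γ‖W‖₂,₁` s.t. `S_ii = 0`, `P1 = 1, P ≥ 0`, `WᵀXXᵀW = I`.  The S step is
  a per-sample lasso in the projected space; the P step is a closed-form
  row-wise simplex projection of `−d²/(2μ)` with self-neighborhoods
  excluded; the W step is an L2,1-reweighted generalized eigenproblem with
  a small ridge on XXᵀ (rank-deficient when D > n).  The printed
  orthogonality constraint in the source formulation is dimensionally
  inconsistent (`WᵀXXᵀX = I`); the standard `WᵀXXᵀW = I` is implemented.
  Defaults α = β = γ = 1, μ = 0.5, d_out = 5.  The objective is
  non-increasing across sweeps (MM argument for the L2,1 reweighting;
  exact block minimizers elsewhere).
* **LLCFS** (unsupervised) — alternates a kNN graph in the z-weighted
  feature space, a cluster-indicator update, and per-sample kernel-ridge
  solves whose squared weights aggregate into `h_f`, giving the simplex
  minimizer `z_f = √h_f / Σ√h`.  The indicator update is seeded k-means on
  the weighted data: a relaxed eigenvector indicator (bottom of the local
  prediction-error matrix) proved unreliable, latching onto smooth noise
  directions.  Because the z update is multiplicative and concentrates
  exponentially, the default iteration count is small (4), which keeps
  pure-noise inputs from spuriously concentrating (no weight exceeds 0.5
  at D = 10) while a genuinely separating feature still dominates.
* **CFS** — greedy forward search maximizing
  `merit = k·r̄_cf / √(k + k(k−1)·r̄_ff)`; stops when no candidate improves
  the merit; remaining features appended by |r_cf|.

FSASL and LLCFS never see labels, but inside cross-validation they are
still fit on training folds only, so no test-set information can reach
them.

### Classifiers

* **RELM** — hidden weights and biases drawn once, uniform on [−1, 1]
  (sized for standardized inputs), logistic-sigmoid activation (the
  activation is not otherwise constrained by the method; sigmoid is the
  conventional choice).  Output weights solve the SPD system
  `(I/C + HᵀH) β = HᵀT` (never an explicit inverse); C = 1 and L = 1000
  hidden nodes by default.  Multi-class handled by one-hot targets and
  arg-max with ties to the lowest class index; binary tasks are the tested
  surface.
* **LSVM** — soft-margin linear SVM at fixed C = 1 (explicit, portable
  default), solved by libsvm; prediction by the sign of the decision
  function.

### Cross-validation protocol

Stratified k-fold (default 10 folds, 5 repetitions with re-drawn folds,
seeded).  Within each fold: standardization statistics and the feature
ranking are computed on the training split only and applied to the test
split; classifiers are trained on the top-k features for k = 1..k_max
(default 50).  The reported operating point is the k maximizing mean
accuracy (ties → smallest k).  Summary statistics (mean, std, max, min for
accuracy/sensitivity/specificity) are taken **across the fold ×
repetition values at that k** (std with ddof = 1); the F-measure is the
standard F1 computed from the pooled confusion counts at that k.  The
positive class is the disease-ward label of the pair (AD in AD-vs-HC and
AD-vs-MCI, MCI in HC-vs-MCI).  Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); undefined ratios are reported as NaN, never 0.
Stratification is used because with ~30 subjects per class unstratified
folds can degenerate to single-class test sets.

## The synthetic cohort

Each subject's rows are i.i.d. draws from a zero-mean multivariate normal.
The group-g correlation matrix is the identity plus a constant-correlation
block on the first `module_size` ROIs with off-diagonal
`base_correlation − g · effect_size / (n_groups − 1)` — monotone
hypoconnectivity along the label order, off-module structure identical
across groups.  If a construction is indefinite it is repaired by clipping
eigenvalues at 10⁻⁶ and rescaling to unit diagonal.  Defaults: 31 subjects
per group, 116 ROIs, 130 time points, base correlation 0.45, effect 0.5,
module of 10 ROIs (the validity constraint |base| + effect < 1 keeps every
group correlation inside (−1, 1)).

What the generator emulates: group-structured second-order statistics at
the cohort geometry — exactly the information Pearson connectivity can see.
What it does not emulate: hemodynamics, temporal autocorrelation, spatial
smoothness, site/motion artifacts, heavy tails, or subject-level
covariance heterogeneity within a group.  Passing tests therefore certify
the *pipeline* (correctness, no leakage, recoverable planted signal), not
clinical performance on real fMRI.

## Desk-scale study conditions

Two end-to-end experiments (in `fcembed.study`, used by the test suite and
`scripts/acceptance.py`) run the full pipeline on one CPU in minutes, with
node2vec scaled to dim = 8, 20 walks per node, window 4, 3 epochs, and CV
scaled to 2 repetitions with k ≤ 20 and a 256-node RELM; FSASL runs 3
sweeps and SVM-RFE uses step = 0.2 inside folds:

* **Null sentinel** — effect 0: labels are exchangeable, so the
  repeated-CV mean accuracy of every selector × classifier combination
  must fall inside the two-sided 99% binomial interval around 0.5
  (n = total test predictions at the chosen k).  This is the no-leakage
  certificate: per-fold ranking, per-fold standardization and seed
  handling would each inflate it if broken.  Note the reported statistic
  maximizes mean accuracy over k, so even under the null it sits slightly
  above 0.5; the band accounts for chance but not for this selection, so
  the statistic is mildly anti-conservative and on some seeds a
  combination can graze the band's upper edge without any leakage.  A
  genuine leak (ranking on all data) inflates accuracy far beyond the
  band, not by fractions of a percent.
* **Signal recovery** — effect 0.5 on a 10-ROI module: LASSO-ranked
  features reach mean accuracies well above 0.85 (LSVM) and 0.80 (RELM)
  across master seeds.

## Numerical conventions

* Seed fan-out: every stage derives generators from
  `SeedSequence([global_seed, stage_id, index])`; subject order and
  parallelism cannot change results.  The embedding stage shares one stage
  seed across subjects (comparability, above).
* Degenerate inputs: zero-variance ROI columns are rejected by name;
  isolated nodes warn and emit single-node walks; empty corpora return the
  flagged initialization; single-class label vectors are rejected by both
  classifiers and the supervised rankers.
* Ties: rankings break ties by ascending feature index; arg-max prediction
  breaks ties toward the lowest class index; the k sweep breaks accuracy
  ties toward the smallest k.
* Tolerances: Pearson oracle 10⁻¹²; skip-gram gradient check 10⁻⁵
  (relative); RELM normal-equation residual 10⁻⁸; LASSO OLS limit 10⁻⁶;
  FSASL objective monotonicity 10⁻⁸ (relative).

## Known limitations

* The Gaussian generator cannot probe robustness to non-stationarity or
  artifacts; conclusions about real rs-fMRI require real cohorts.
* Skip-gram embeddings remain rotation-non-identifiable across *different*
  graphs; the shared-initializer convention makes them comparable in
  practice but is a convention, not an invariance proof.
* FSASL's inner lasso and eigen-solves dominate pipeline cost at large D;
  the exposed sweep/step controls trade fidelity for time.
* Multiclass (3-way) classification is supported by the RELM one-hot path
  but is untested territory; the evaluated protocol is binary pairs.
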