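# Methods

This note records the model, its assumptions, the defaults that matter and
the design decisions taken where the procedure was genuinely open.

## Model overview

Input is a genes × samples log2 expression matrix `X`, a frozen genes × LV
loading matrix `Z` (a pathway/cell-type-aligned prior of the
PLIER/MultiPLIER family), and a hub-gene set `G*`. The diagnostic pipeline
is

```
standardize genes → B = (ZᵀZ + λI)⁻¹ZᵀX → B̃ = diag(α̂)B → f_θ → Deep-Sets
relation scores → s(x) = r_case − r_control → calibrated probability
```

`Z` is never refit: its role is to constrain the representation to a
biologically aligned subspace so that tens of labelled samples suffice and
attributions stay interpretable at the pathway level.

### Gene standardization (pre-projection)

Genes are z-scored with training-derived means and population (1/n) SDs
before projection; query samples always reuse the stored statistics, so no
information leaks from the prediction set into the scaling. Zero-variance
genes are dropped and recorded. The projection's input scaling is not
dictated by the model itself; z-scoring was chosen because it puts
microarray-like data and synthetic cohorts on one scale and is standard
practice before projecting onto a fixed prior. This is a package
convention, stated here once.

### Ridge projection

`B` solves the ridge system per sample. Default `λ = 1.0` on standardized
genes, exposed as `--ridge-lambda`. The value is not critical: on the
reduced synthetic benchmark (300 genes, 20 LVs) held-out AUC moves by less
than 0.02 across λ ∈ {0.1, 1, 10} (asserted in the test suite). `λ = 0` is
allowed when `ZᵀZ` is invertible; a singular system raises an error
advising `λ > 0`.

### Hub-gene gate

`α_ℓ` is the mean absolute loading of the hub genes on LV ℓ. Two
normalisations are provided — `max` (entries in [0,1], default, the primary
form) and `l1` (simplex) — because the formula admits both and
neither is canonical. The gate is computed once
from `Z` and `G*` when the model is fitted, stored with it, and never
re-derived from data at inference. Note a structural consequence: LVs with
no hub-gene loading get weight 0 under either normalisation, so their gated
activities are identically zero and they contribute nothing to the score or
to attributions.

### Relation network

* Encoder: `L → 128` (ReLU, dropout 0.3) `→ 64` (ReLU); the 64-unit layer
  is the embedding (`d = 64`). The reference architecture fixes the two
  hidden widths but not `d`; taking the last hidden layer as the embedding
  is the natural reading.
* Similarity: Hadamard product of query and support embeddings.
* Set head: `φ` is a 64→64→64 ReLU perceptron, `ρ` is 64→32→1; widths are
  package choices (the architecture is only described as "small MLPs").
  Aggregation over each class's support set is `sum` (the written form) by
  default with `mean` available, since inference-time support sizes can
  differ from the training shot count. Attention-style aggregators are out
  of scope.
* Permutation invariance of `r_{q,c}` is exact at the bit level in eval
  mode: per-(query, class) the `φ` outputs are summed in canonical
  (lexicographic) row order, so the floating-point reduction cannot depend
  on support-list order.
* Initialisation: uniform fan-in scaling from the run's seed. The output
  layer of `ρ` is scaled by 0.05 with zero bias so that a freshly
  initialised model scores both classes nearly alike — the initial episode
  loss sits at the ln 2 no-information baseline — while gradients remain
  nonzero.
* The forward/backward passes are implemented directly on numpy arrays (a
  minimal dense-layer engine with explicit gradients and Adam); the
  networks are small enough that this is simpler and faster here than a
  full autodiff framework, and the backward pass is verified against
  central finite differences in the test suite.

### Episodic training

2-way, K=5 support and 5 queries per class per episode, drawn without
replacement; loss is the mean over queries of the temperature-softmax
cross-entropy (the mean rather than the sum keeps the loss magnitude
independent of the query count; this is a pure gradient rescaling absorbed
by the learning rate). Optimiser: Adam, lr 1e-3, L2 weight decay 1e-4
(package defaults, exposed in `TrainConfig`). At most
1000 episodes (one optimiser step per episode); every 10 episodes the
validation AUC is computed (full training set as support, eval mode) and
the best checkpoint kept; training stops after 10 consecutive checks
without improvement. "Stagnation for 10 episodes" is ambiguous between
episodes and checks; it is interpreted as 10 validation checkpoints.

### Inference

The stored labelled training features act as the support reference. Two
strategies:

* `kshot_ensemble` (default): average relation scores over M = 20 seeded
  draws of K support samples per class, so the sum-aggregator sees the
  support-set size it was trained with;
* `full_set`: a single pass with the entire reference as support.

On the synthetic benchmark both strategies agree on ≥ 95 % of hard labels.
Because the sum aggregation makes score magnitude grow with support size,
scores from different strategies live on different scales; calibration must
therefore be fitted on scores produced by the same strategy used at
prediction time (the bundled pipeline does this). When a query's sample id
also appears in the reference, that column is excluded from its support, so
training samples can be scored without self-comparison.
`s(x) = r_case − r_control` is used as the raw risk score; for a two-score
softmax head at τ = 1 this difference is the binary log-odds.

### Calibration, evaluation, explanation

* Platt scaling (logistic fit on the score) and isotonic regression are
  compared by cross-validated Brier score on seeded stratified folds; the
  winner is refit on all data; ties go to Platt as the simpler map. With
  fewer than two distinct scores isotonic is degenerate and Platt is used
  with a warning.
* AUC is the tie-corrected Mann–Whitney rank statistic (ties count ½).
* Decision curves report `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` on a default
  grid of 99 thresholds (0.01–0.99) against treat-all and treat-none.
* Attribution uses complete-permutation Shapley values over the gated
  latent inputs with background-mean imputation and antithetic permutation
  pairs. Each permutation telescopes, so
  `base + Σ_ℓ attribution_ℓ = s(x)` holds exactly (up to ~1e-14 rounding),
  which the additive scorecard requires; default 128 permutations.
* Gene scorecard: each LV's attribution is shared among hub genes in
  proportion to `|Z_gℓ|`; LVs unloaded by any hub gene pool into an
  "other" term so the additive identity is preserved. No single loading-based aggregation formula is canonical;
  proportional absolute-loading shares are this package's choice. Points: the training cohort's range of summed positive gene
  contributions maps linearly onto [0, 100]; new samples outside the range
  clip and are flagged. The points → probability chart interpolates the
  training samples' calibrated probabilities sorted by points, forced
  non-decreasing; how such charts are binned is underdetermined, and this
  lookup is an explicit approximation.

## Consensus feature selection

* **LASSO**: L1-penalised logistic deviance along a geometric λ path from
  just above λ_max (where the first coefficient enters) down to
  λ_max/100, 10-fold cross-validated; rules `lambda_min` (default) and
  `lambda_1se` are both offered, as both are in common use. Fits
  delegate to liblinear (tol 1e-3); the path bottom stops at 1 % of λ_max
  because fits below that are effectively unpenalised and the solver's
  cost grows sharply on separable data.
* **SVM-RFE**: linear soft-margin SVM (C = 1 default, unspecified
  upstream), ranking by `w_j²`, eliminating one feature per round
  (classical RFE, configurable); every visited subset is scored by seeded
  stratified 5-fold accuracy and the maximum wins, smaller subsets winning
  ties (matching "highest accuracy at nine genes" selection behaviour).
* **Random forest**: 500 CART trees with Gini splitting and √p features
  per split, fitted on explicit bootstrap samples so OOB membership is
  controlled by the package. OOB error comes from majority-vote OOB
  predictions; MDI is the node-impurity decrease weighted by `n_u/n`,
  summed over nodes splitting on the feature and averaged over trees; the
  count-scale equivalent (no 1/n, as reported by R's randomForest as
  MeanDecreaseGini) is also computed, and the default selection rule
  — MeanDecreaseGini > 3 — applies to that scale, since the normalised MDI
  is bounded well below 3. A scale-free alternative (MDI ≥ 5 % of the
  maximum) is provided. Permutation importance permutes each feature's OOB
  values per tree and reports the error difference `e_perm − e_orig`
  (ratio form in diagnostics).
* **Consensus**: set intersection of the three selected lists, reported in
  the LASSO list's order, followed by a per-gene AUC screen that passes
  genes with direction-aware AUC strictly greater than 0.7.

## Synthetic cohorts

`make_loading_matrix` builds block-sparse nonnegative loadings: each LV
loads 20 consecutive genes plus a 2-gene overlap into the next block, with
|N(0,1)| magnitudes scaled to mean 0.5. `make_dataset` draws latent
activities N(0,1), adds the effect size δ to the disease LVs of case
samples, and sets `X = ZB + N(0, σ)`. Defaults — 1000 genes, 50 LVs, 3
disease LVs, δ = 1.5 SD, σ = 1, 40 samples/class, 4 hub genes (the
top-loading genes exclusive to disease LVs, mirroring a compact validated
panel) — define the standard benchmark. The end-to-end benchmark generates
72 samples/class and splits 40 train / 32 held-out per class; the training
40 are further split 75/25 for early stopping. The training-dynamics and
λ-robustness tests run a reduced cohort (300 genes, 20 LVs) to keep the
suite fast.

What the generator does **not** emulate: microarray heteroskedasticity,
probe-level artefacts, batch effects, non-Gaussian counts, or correlated
noise between genes outside the latent structure. Passing benchmarks
therefore demonstrates correctness of the machinery and sensible behaviour
under the assumed generative process, not clinical performance on real
cohorts.

## Numerical conventions and degenerate inputs

* Median collapse of duplicate gene rows: even counts take the mean of the
  two central values; collapsing is idempotent.
* Matrix round-trips use 17-significant-digit decimal text and round-trip
  parsing, so written artifacts reload bit-exactly.
* Ties in `argmax` class assignment resolve to the control class (first
  index); ties in calibration method selection resolve to Platt.
* Degenerate point scale (all training samples with equal summed positive
  contributions) yields zero points for all samples rather than an error.
* All stochastic components (episode sampling, dropout, bootstraps, CV
  folds, permutations) draw from explicit seeded generators; a fitted
  model archives its configuration, seed, gate, standardization statistics
  and training log in a single versioned `.npz` (named arrays + JSON
  metadata).

## Known limitations

Two-way classification only; no transductive or semi-supervised inference;
case-sensitive symbol matching without alias resolution; the scorecard's
points → probability chart is an interpolation, not a refit calibration;
`full_set` and `kshot_ensemble` scores are not on a common scale (by
construction of the sum aggregator).
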