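# Methods

## Problem and model

The package classifies tumor samples into cancer types from gene-level somatic
copy-number aberration (CNA) profiles and turns the trained classifier into
compact, per-type *CNA signatures* — signed gene lists separating
duplication-associated from deletion-associated genes. Input profiles are
GISTIC-style five-level discrete calls per gene: −2 (deep loss), −1 (shallow
loss), 0 (diploid), +1 (low-level gain), +2 (high-level amplification).

Because CNA profiles of one cancer type are heterogeneous, classification is
framed as multiple-instance learning (MIL): an *instance* is one patient's
profile x_k ∈ {−2..2}^D, a *bag* is a set of K instances of one cancer type,
and the label attaches to the bag. The model composes three learned maps:

1. **Instance embedder** f_ψ: h_k = W₂ relu(W₁ x_k + b₁) + b₂, mapping each
   instance independently to an M-dimensional embedding. One hidden affine +
   ReLU layer is the smallest architecture that still captures nonlinear
   interactions among gene calls.
2. **Gated attention pooling**: per-instance scores
   e_k = wᵀ[tanh(V h_k) ⊙ σ(U h_k)] with V, U ∈ R^{L×M}, w ∈ R^L and σ the
   logistic sigmoid; a = softmax(e) and the bag embedding is the convex
   combination z = Σ_k a_k h_k. The tanh branch carries signed evidence, the
   sigmoid gate modulates it; the construction is permutation-invariant and
   puts strictly positive weight on every instance.
3. **Bag classifier** g_φ: softmax(W_c z + b_c) over the C cancer types.

Training minimizes the multinomial bag negative log-likelihood
−log p[label], averaged over bags. The log is clamped at ε = 10⁻¹² for
numerical safety; argmax ties resolve to the lowest class index.

The network is small and its architecture fixed, so the forward pass, the
analytic reverse-mode gradients and the Adam optimizer are implemented
directly on numpy arrays. Gradient correctness is pinned against central
finite differences (≤10⁻⁴ relative error) in both the test suite and the
acceptance script, and the gated-attention arithmetic against an independent
scalar-by-scalar oracle (≤10⁻¹⁰).

## Feature selection

Before MIL training, recursive feature elimination with cross-validation
(RFECV) reduces the gene set. Per round the estimator is fitted on the
current features, features are ranked by per-feature importance — sum over
classes of absolute coefficients for the multinomial logistic model, impurity
importance for the random-forest option — and the lowest
⌈step_fraction · remaining⌉ are dropped; the mean stratified-CV score of
every evaluated set is recorded. The selection is the evaluated set with
maximal mean CV score, **ties broken toward fewer features**.

Defaults: multinomial logistic regression, balanced accuracy (robust to the
order-of-magnitude class-size imbalance typical of pan-cancer cohorts),
5 folds, step_fraction 0.1, min_features 1. Estimator fitting and scoring go
through scikit-learn; the schedule, ranking convention, score path and
tie-break are this package's contract.

A consequence worth stating: when planted (or biological) signal is redundant
— neighbouring genes on one aberrant segment are perfectly collinear — the CV
score saturates once a small sufficient subset remains, and the parsimony
tie-break then correctly discards the redundant genes. RFECV here recovers a
*minimal discriminative* set, not the full extent of every aberrant region;
the tests therefore assert that true signal genes outlast noise genes in
elimination order and that the selection is drawn from signal genes, rather
than that every planted gene is kept. Region-level completeness is the job of
the signature stage, which scores all genes.

## Instance predictions and signatures

After training, each instance i of a bag receives its attention weight w_i
and a class-probability vector p_i obtained by running the full model on the
singleton bag {x_i} (the minimal mechanism consistent with the architecture —
for K = 1 attention is the identity, so p_i is a pure instance prediction).
The normalized weighted score is

    p̂_{i,k} = (w_i / Σ_j w_j) · p_{i,k},

which sums to one over the instances and classes of a bag; the predicted
class ĉ_i = argmax_k p̂_{i,k} coincides with argmax_k p_{i,k}. Instance
accuracy is the fraction of samples with ĉ_i equal to the true class.

The signature score of gene g for class k is

    s_{g,k} = mean over {i : ĉ_i = k} of  p̂_{i,k} · x_{i,g},

normalized per class by the maximal absolute score (or to unit L1 norm).
This projection is linear in the instance predictions, and the factor
x_{i,g} makes it sign-preserving: gains contribute positive score, losses
negative, so the signature splits naturally into duplication and deletion
genes. A gradient-times-input attribution (∂ log p_k/∂x · x, averaged with
the same weights) is exposed behind the same contract as an alternative
interpretation. The signature of a class is its top-N genes by |s| (default
N = 50; deterministic tie-break by gene id); the union across classes is the
pipeline's signature gene set.

## Comparison metrics

Frequency profiles count, per gene, the fraction of cohort samples with any
gain (call ≥ +1) and any loss (call ≤ −1); a flag restricts to high-level
events (±2). Arm-level profiles are unweighted means of per-gene values over
the genes annotated to each chromosome arm (0-based half-open coordinates,
BED convention); the arm statistic that is rank-correlated between profiles
is the net score, mean gain minus mean loss, with Spearman ρ computed by
scipy over the shared arms (≥3 required, average ranks for ties). Gene-level
overlap of two signatures is the Jaccard index of their gene sets.

## Synthetic cohorts

The simulator generates the study conditions for all tests: a multi-class
cohort of five-level calls where each class owns disjoint, contiguous planted
blocks (mimicking segmental CNAs, so arm aggregation is meaningful), carried
per sample with probability *penetrance*; carried calls have magnitude 2 with
probability *high_level_fraction*, else 1, signed per block. Background noise
plants random nonzero calls per gene at *background_rate*; planted values
overwrite noise, since a locus has a single observed state. Classes may split
into subtypes with their own block sets; a subtype's blocks are carried
jointly (one penetrance draw per sample), modelling co-occurring events such
as a 1p/19q co-deletion. A gene annotation is auto-generated by placing genes
uniformly on simulated chromosomes with the p/q split at the midpoint.

Default conditions (3 classes × 40 samples, 500 genes, 2 blocks of 10 genes
per class, penetrance 0.9, high-level fraction 0.3, background 0.02) give
cohorts that are separable but not trivially so: ~10% of samples miss a given
block and ~5% at penetrance 0.95 carry none of their class's blocks and are
irreducibly ambiguous. What the simulator does **not** model: allele-specific
or continuous log-ratio data, purity/ploidy effects, gene-length or
GC-related artefacts, correlated noise along the genome, and overlapping
signal between classes. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted structure, not performance on
real tumor cohorts.

## Training procedure and defaults

Bags are homogeneous. Two construction modes: *epoch_partition* (shuffle each
class, chunk into bags of K = 10; a remainder ≥ 2 stays as a smaller bag, a
singleton is dropped for the epoch) and *resample* (default for training:
per class, 8 bags of K distinct samples per epoch — with *equal_bags*
balancing every class gets identical exposure regardless of size). Bags are
regenerated each epoch from epoch-derived seeds. Optimizer: Adam
(lr 10⁻³, β = 0.9/0.999) with decoupled weight decay 10⁻⁴ on weight matrices
only; plain gradient descent is available for diagnostics. The classifier
head initializes at zero so a fresh model predicts exactly the uniform
distribution (first-epoch loss ≤ log C); embedder and attention weights use
He-scaled Gaussians. Early stopping monitors bag NLL on a held-out fraction
(default 15% of the training cohort, stratified), patience 10, and the
returned parameters are the best-validation ones. Everything is seeded: one
global seed is hashed with stage tags (SHA-256, reduced below 2³¹) to give
each stage an independent, reproducible stream, and reruns with an identical
configuration are byte-identical.

Model sizes: the library defaults are M = 128, L = 64. The test suite and
the acceptance script use M = 64, L = 32 on 500-gene cohorts (and smaller for
pipeline smoke tests) — ample capacity for the planted structure while
keeping the default runs fast on one CPU; results were insensitive to these
widths.

## Numerical choices and degenerate inputs

- softmax/sigmoid use max-shift and branch-stable forms; no overflow at
  |score| ~ 10³.
- ReLU subgradient at exactly 0 is 0.
- A class with a single sample is kept whole in the training split and
  excluded from bagging, with a logged warning.
- Stratified splitting sends ⌊n · fraction⌋ samples per class to the test
  side, at least 1 whenever n ≥ 2.
- Signature projection with no instance assigned to a class returns a zero
  vector with a warning rather than failing.
- Matrices reject non-integer, out-of-range and duplicate entries at
  construction, naming the offending cell; missing values are rejected, not
  imputed.

## Known limitations

- Instance probabilities come from singleton-bag classification; other
  attribution mechanisms (e.g. attention rollout over larger bags) are out of
  scope beyond the provided gradient×input variant.
- The MIL training loop is single-threaded numpy; it is sized for
  thousands-of-genes cohorts, not for whole-exome matrices with >10⁵
  features.
- Real-data headline figures from pan-cancer atlases (overall accuracy,
  selected-feature counts, cross-study concordances) depend on those cohorts
  and on unstated hyperparameters and are not reproduced here; the package
  reproduces the method and verifies it on simulated ground truth.
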