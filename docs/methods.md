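# Methods

## The prediction problem

Given a pair of anti-cancer drugs and a cancer cell line, predict whether
the combination is synergistic.  Continuous synergy measurements (Loewe
scores or ComboScores) are binarized at a strict threshold of 30: a sample
is positive iff its score exceeds 30.  The model is a binary classifier
evaluated with threshold-free ranking metrics (AUROC, AUPRC) and F1.

## Model

The pipeline has three phases.

**Initialization.**  Each entity type is encoded into a common
d-dimensional feature space:

* *Drugs.*  SMILES strings are parsed into heavy-atom molecular graphs
  (RDKit) with a fixed 75-length atom featurization (element, degree,
  implicit valence, formal charge, radical electrons, hybridization,
  aromaticity, hydrogen count).  A stack of multi-head graph-transformer
  layers refines atom features:

      a'_i = act( W1 a_i + Σ_{j∈N(i)} α_ij W2 a_j ),
      α_ij = softmax_j( (W3 a_i)ᵀ (W4 a_j) / √d_head ),

  with attention restricted to bonded neighbours, per-head weighted sums
  averaged across heads, and isolated atoms receiving only their own
  linear term.  The drug vector is the columnwise maximum over refined
  atom features (invariant to atom ordering and molecule size).
* *Cell lines.*  Raw expression is log2(x+1)-transformed and z-scored per
  gene (population standard deviation; constant genes map to zeros), then
  passed through a one-layer MLP: c' = act(W5 c + b5).
* *Diseases.*  Precomputed language-model embeddings of indication terms
  are consumed as-is and projected by their own one-layer MLP.

**Refinement.**  A dual-relationship hypergraph is built over all nodes
(drugs, then cell lines, then diseases — the stacking order of the
feature matrix).  Hyperedges are (i) order-3 *triplets*, one per unique
unordered synergistic (drug, drug, cell line) combination from the
*training fold only* (weight 1), and (ii) order-2 *indication* edges, one
per (drug, disease) pair, weighted by the interaction-weight
hyperparameter.  Weight 0 exactly reproduces the disease-free ablation.
No cell-line–disease edges are built.  With incidence H, hyperedge
weights W_e, weighted node degrees D and hyperedge cardinalities E, one
refinement layer computes

    C = act( D⁻¹ H W_e E⁻¹ Hᵀ X W6 ),
    X' = X + sigmoid( C W7ᵀ + b7 ) ⊙ X.

The normalized operator is row-stochastic wherever a node has positive
degree (constant features are fixed points); zero-degree nodes receive a
zero convolved row and pass through on the residual path.  The gate bias
b7 is initialized to −5 (equilibrium bias initialization), so
sigmoid ≈ 0.0067 and every layer starts as a near-identity map — this is
what lets deep stacks avoid over-smoothing, which we verify directly: 8
unrestricted averaging layers collapse node-feature variance by more than
10× while 8 gated layers at EBI retain over half of it.  The printed form
of the gate leaves ambiguous whether the gate multiplies the input or the
convolved features; the package implements the input-carrier form by
default and the convolved-carrier form behind a flag (both are identity
maps at EBI).

**Consolidation.**  A triplet (i, j, k) is scored by concatenating the
three refined rows in sample orientation and applying an MLP with a
sigmoid output.  The scoring head defaults to one ReLU hidden layer
rather than a single affine layer: an affine function of the
concatenation is *additive* in the three embeddings and provably cannot
rank a purely multiplicative drug–drug–cell interaction (any additive
approximation of a centered trilinear form has zero correlation with it),
so a literal single-layer head caps at chance AUROC on interaction-driven
synergy.  The literal head remains available (`predictor_hidden=()`).

## Training

Binary cross-entropy (probabilities clipped at 1e−7 when evaluated in
probability space; the training path uses the logit formulation
softplus(z) − y·z) minimized with AdamW (decoupled weight decay; biases
and gate biases exempt).  The training fold is augmented with the
drug-swapped twin of every sample (pairwise symmetric permutation
augmentation); validation and test are scored once, in stored
orientation.  The first scoring layer's two drug slots are initialized
identically, so the head starts exchange-symmetric; training without
augmentation lets the slots drift apart, and an optional mode
(`paired_orientation_batches`) places both orientations of a sample in
the same minibatch, which provably keeps the learned function exactly
exchange-symmetric but constrains optimization to the symmetric manifold
and converges noticeably more slowly (see Limitations).  Dropout is
applied to node features entering each refinement layer (training only),
early stopping monitors validation AUROC, and the best-epoch parameters
are checkpointed.  Runs are bit-reproducible given the seed.

### Hyperparameters

Full-scale defaults follow the tuned values for large screening cohorts:
learning rate 2e−4, weight decay 1e−2, 4 attention heads, 3 refinement
layers, interaction weight 0.02, batch 256, dropout 0.2.

`desk_scale_config()` is the package's configuration for desk-size
cohorts (~2000 samples, ~20 drugs), used by the benchmark tests and the
acceptance script: common dimension 32, 2 refinement layers, predictor
hidden width 128, batch 32, learning rate 2e−3 with cosine decay to a
0.1× floor over at most 200 epochs, weight decay 0.1 (the strongest value
of the usual search grid — small cohorts need the extra regularization),
early-stop patience 20.  The learning rate is ten times the full-scale
value because an epoch here is only ~90 optimizer steps; at 2e−4 the
optimizer cannot traverse the loss landscape within the epoch budget (we
verified validation AUROC stays near chance).

## Evaluation protocol

The data is split 90/10 into a cross-validation pool and a held-out test
set, the pool then undergoes 5-fold cross-validation under five
stratification strategies: random, cline (validation cell lines unseen in
training), drugcomb (unordered pairs disjoint), drugsingle (exactly one
validation drug held out; samples with two held-out drugs are discarded,
shrinking the data), and drugdouble (both drugs held out).  The initial
test split is drawn at the same grouping unit as the strategy so held-out
entities cannot leak into the test set.  Fold membership is assigned by
hashing unit identifiers with the seed and dealing the hash-ordered units
round-robin — stable under sample reordering and evenly balanced.  For
drugsingle, a sample whose two drugs fall in different fold groups
legitimately appears in the validation sets of both folds; exact-once
validation coverage holds only for the random/cline/drugcomb modes.

AUROC uses the rank definition with half-credit ties; AUPRC is the
step-interpolated area (average precision); F1 is computed at probability
0.5 by default.  Cross-validation reports per-fold and mean/std metrics;
the test set is scored with the best-validation fold's model.

## Synthetic benchmark cohort

The generator emits all five input tables with a planted signal

    score(i, j, k) ∝ signal_strength · (u_i ⊙ u_j)ᵀ v_k + ε,

where u (drugs) and v (cell lines) are 4-dimensional standard-normal
latent traits and ε is Gaussian measurement noise with sd 0.25 — kept
well below the planted-signal scale (sd ≈ 2 at strength 1) so that the
`label_noise` knob is the dominant corruption and the planted ranking
stays recoverable.  Raw scores are affinely mapped so a configurable
fraction (default 0.30) exceeds the threshold of 30; label noise reflects
a random subset of scores across the threshold, keeping scores and labels
mutually consistent.  Expression is the cell-line latent lifted through
random gene loadings on a log2 scale (the reader-side transform recovers
it, up to noise); disease embeddings are clustered latents under a random
linear lift; indications are sampled where drug and disease latents
align, so drugs sharing an indication have correlated traits; each
disease keeps at least its best-matching drug so the emitted tables are
self-consistent.  Default conditions: 20 drugs, 12 cell lines, 8
diseases, 60 genes, 32-dimensional disease embeddings, 2000 samples,
signal strength 1.0, label noise 0.05.

What the generator deliberately does *not* emulate: drug latents are tied
to molecule identity only (molecules are drawn from a fixed vocabulary of
~130 parseable drug-like SMILES and act as distinct tokens), so synthetic
performance certifies the learning machinery — encoders, hypergraph
refinement, training — not chemical generalization; there is no
dose–response structure, no Loewe additivity, and expression covariance
is low-rank.  Under the drugdouble strategy the trained model can exploit
only cell-line marginals, which is why leave-both-drugs-out performance
drops toward (but above) chance — the same qualitative ordering seen on
real screening data.

`oracle_scores` returns the noiseless planted values; their AUROC against
the generated labels (≈ 0.92 at the default 5% label noise) upper-bounds
what any model can achieve on the same cohort.

## Numerical choices

* All computation in float64 on a small reverse-mode autodiff core
  (`hypersyn._autodiff`), validated against central finite differences.
* Attention softmax subtracts the per-node per-head maximum before
  exponentiation; the logistic function is evaluated in its stable
  branch-split form; training loss uses the logit formulation.
* 1/0 in degree normalization is defined as 0 (zero-degree rows of the
  operator are zero).
* Triplet deduplication key: (min(drug_a, drug_b), max(…), cell_line).
* Strict inequality at the binarization threshold: a score of exactly 30
  is negative.
* Expression z-scoring uses the population (divide-by-N) standard
  deviation; constant genes map to zeros.
* Glorot-uniform weight initialization; zero biases except the gate bias
  (−5) and the symmetric drug-slot copy in the scoring head.

## Known limitations

* Orientation symmetry through augmentation alone is approximate: on the
  benchmark cohort the correlation between the two orientations' scores
  of held-out triplets is ≈ 0.97 at the desk-scale convergence budget,
  approaching 1 only with substantially longer training.  Exact symmetry
  is available via `paired_orientation_batches` (with the symmetric slot
  initialization it is preserved by construction), but restricting
  optimization to the symmetric manifold slows plateau escape enough
  that, at the desk-scale budget, ranking quality suffers; the default
  therefore prefers free optimization.
* The atom featurization mirrors the common convolutional-featurizer
  layout but bit-compatibility with any external library is not promised
  (the scheme id is recorded in graph dumps).
* Fold-level metric variance on 2000-sample cohorts is a few points of
  AUROC; single-fold results should not be over-interpreted.
* Hyperedges are built from training-fold positives only; a configuration
  flag admits all training triplets for sensitivity analysis, but
  validation/test triplets never enter the hypergraph.
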