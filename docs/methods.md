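# Methods

## Model

Expression data are a non-negative matrix V of N genes × M samples
(genes in rows throughout). The factorization family approximates
V ≈ W·H with non-negative W (N × C) and H (C × M), minimizing the
Frobenius objective E(W, H) = ‖V − WH‖²_F. C is the number of metagenes
and is chosen by the user (typically swept over a small range and judged
by the validity indices). Cluster membership is read off the factors by
argmax: sample *j* joins metagene argmax_i h_ij, gene *i* joins metagene
argmax_j w_ij; ties go to the lowest index so that reports are
reproducible. Signed baseline factors (SVD/PCA/ICA) use the same rule on
magnitudes, the minimal analogue of the H-rule for factors that carry
sign; how partitions should be derived from orthogonal factors is
genuinely open, and K-means in component space would be a reasonable
alternative.

### The three factorization variants

* **NMF** — standard Frobenius multiplicative updates
  W ← W∘(VHᵀ)/(WHHᵀ), H ← H∘(WᵀV)/(WᵀWH), denominators stabilized with
  ε = 1e−12. The objective trace is non-increasing.
* **SparseNMF** — per iteration: multiplicative W update, W columns
  rescaled to unit Euclidean norm, then every column of H solved by
  ridge-penalized least squares min ½‖V_j − WH_j‖² + ½λ‖H_j‖² and
  negative coordinates clipped to zero. This is deliberately a
  *solve-then-clip* scheme, not a true non-negativity-constrained solve;
  the clip is what produces exact zeros in H.
* **BiSparseNMF** — two mirrored half-steps per iteration. H-side:
  exactly the SparseNMF step with penalty λ₁ (`sparsity_h`). W-side:
  multiplicative H update, H rows rescaled to unit norm, then every row
  W_i solved against W_i·H ≈ V_i by the same ridge-and-clip scheme on Hᵀ
  with penalty λ₂ (`sparsity_w`). The recorded objective is ‖V − WH‖²_F
  after each full iteration.

λ₁ and λ₂ are ridge penalty *weights*, not target sparseness levels: the
executable algorithm penalizes squared norms, and the sparseness that
actually results is data-dependent, so every result reports the achieved
mean Hoyer sparseness, (√n − ‖v‖₁/‖v‖₂)/(√n − 1), of H rows and W columns
as a diagnostic. The index convention is λ₁ ↔ H (sample side), λ₂ ↔ W
(gene side), matching which subproblem each penalty enters. In the
W-side half-step the *rows* of H are rescaled (unit-norm metagene
profiles), mirroring the unit-norm W columns of the H-side step.

**A known property of ridge-and-clip:** the achieved sparseness of H is
*not* monotone in λ. Zeros arise only from clipping negative coordinates
of the unconstrained ridge solution; shrinkage reduces sign flips, and as
λ → ∞ the solution tends to WᵀV/λ, which is entrywise positive (W and V
are non-negative and multiplicative updates never create exact zeros in
W) and therefore dense. Empirically the mean Hoyer sparseness of H
*decreases* over λ ∈ {0, 0.1, 1, 10} on both random and block-structured
inputs. Descriptions of this penalty as enforcing "more and more sparse"
H reflect the ℓ0 (point-count) regularization that motivated it, not the
ridge surrogate actually iterated; users who need controlled sparseness
should treat λ as a smoothing/conditioning knob and read the reported
Hoyer diagnostic.

### Numerical choices

* Initialization: W, H entries uniform on (0, 1], then the setup rescale;
  all randomness flows through explicit seeds.
* Convergence: stop when the relative objective change drops below
  tol = 1e−5, or at max_iter = 2000. Near an *exact* rank-C
  factorization the alternating scheme's tail convergence is sublinear,
  so demonstrations of the exact-recovery limit use a much larger
  iteration budget.
* Degenerate components (an all-zero metagene column of W or row of H)
  are reinitialized from uniform noise once; a recurrence raises a
  warning suggesting a smaller C.
* The ridge system (AᵀA + λI) is solved directly; it can be singular only
  at λ = 0 with a rank-deficient design, in which case the error suggests
  a positive penalty.
* λ defaults to 0.1 on both sides in the benchmark and CLI: on data with
  O(1) entries this is 10 % of the unit gram diagonal — large enough to
  condition the solves, small enough not to distort the fit.

## Validity indices

All pairwise indices run on the original data matrix (samples as items
for sample partitions), not in the reduced factor space, so that every
method is scored on equal footing; the distance metric defaults to
Euclidean and may be switched to correlation distance.

* **Homogeneity** — mean Pearson correlation between each item and its
  cluster centroid; a constant profile (item or centroid) contributes 0.
  Needs ≥ 2 features.
* **Separation** — minimum single-linkage distance between any two
  clusters.
* **Dunn index** — minimum between-cluster distance over maximum cluster
  diameter, in [0, +∞]; singletons have diameter 0, an all-singleton
  partition maps to +∞.
* **Average silhouette width** — mean of s(i) = (b−a)/max(a, b);
  singleton clusters and coincident points contribute 0.
* **Cophenetic compliance (Pearson)** — the partition's comembership
  matrix, coded 0 = same cluster / 1 = different, correlated with the
  observed dissimilarities over the N(N−1)/2 pairs. The 0/1 coding makes
  good partitions correlate *positively* with distances, so higher is
  better, consistent with the other indices.
* **Normalized Hubert gamma** — Pearson correlation between pairwise
  distances and the distances between the centroids of the clusters
  containing each pair (0 for same-cluster pairs).
* **GAP statistic** — Tibshirani form: W_k is the total within-cluster
  sum of pairwise squared distances over 2n_r (equal to the within-cluster
  sum of squares about centroids); B reference datasets are drawn
  uniformly over each feature's observed range and clustered with the
  same procedure (K-means by default); Gap(K) = mean_b log W*_kb − log W_k.
  Report tables negate it so that *lower is better*, and the log notes the
  convention. Op-level default B = 50; the benchmark uses B = 20 per cell
  so that a full sweep stays fast.
* **Adjusted Rand index** — Hubert–Arabie form on the pair-count
  contingency. It is ≈ 0 in expectation for independent partitions and
  *can be negative* (the crossing 4-item example gives −0.5); no clamping
  to [0, 1] is applied.
* **Accuracy** — best injective cluster → class matching (exhaustive for
  small K, optimal assignment on the contingency table otherwise),
  correct count over N. Unmatched clusters count all members as errors;
  consequently accuracy can fall *below* the majority-class share for
  multi-cluster predictions — only the all-in-one-cluster prediction is
  guaranteed exactly the majority fraction.

## Voting consensus

Partitions from several methods over the same samples and the same K are
combined by plurality vote after aligning every partition to a reference
by optimal cluster matching. The reference is the input with the highest
average silhouette width on the data — an internal criterion, so voting
stays fully unsupervised — and per-item ties fall back to the reference's
assignment (so two partitions that disagree everywhere return the
reference). The consensus is invariant to the order of the non-reference
inputs.

## Enrichment

Gene clusters are tested against user-supplied GMT gene sets with the
exact upper-tail hypergeometric probability P(X ≥ k) of the observed
overlap; GO terms and pathways are treated uniformly as "terms". The
universe is the intersection of the matrix's genes with the genes
appearing anywhere in the annotation collection, logged per run. Counts
of significant terms use strict p < α (default 0.05) with no
multiple-testing correction, matching the raw-count reporting convention;
Benjamini–Hochberg adjustment and the conservative EASE-style variant
(tail evaluated at k − 1) are opt-in flags. The per-term weighted score is
q × (−log10 p) with q the cluster's proportion of significant terms —
the proportion enters as a single cluster-level multiplier.

## Synthetic data

`generate_planted_factors` (defaults N = 200, M = 40, K = 3, σ = 0.1,
10 % gene overlap) emulates the metagene model directly: block-sparse W0
(dominant loading U(0.5, 1.5), overlap genes add U(0.2, 0.6) on the next
metagene), block-structured H0 (in-block U(0.8, 1.2) against a U(0, 0.1)
baseline), V = W0·H0 + N(0, σ²) clipped at zero. Clipping (rather than
shifting) keeps V non-negative without changing the block contrast. The
default size keeps a full 3-method × 3-K × 20-replicate sweep under a
minute. σ = 0.1 is 10 % of the block contrast — clearly recoverable;
σ = 1 swamps it. What the generator does *not* emulate: heavy-tailed
platform intensity distributions, gene–gene correlation beyond the block
structure, batch effects, or missingness — so passing recovery tests
show correctness of the machinery, not performance on real arrays.

`generate_gaussian_clusters` gives an Iris-like table (K well-separated
isotropic Gaussian groups, few features). `generate_annotation_fixture`
draws GMT terms of size U{10..40}; a designated subset samples each
member from a chosen gene cluster with probability equal to
`enrichment_strength` (0 = null fixture, 1 = cluster-exclusive terms).

## Benchmark protocol

Each method × K × replicate cell gets a deterministic seed
(`seed_schedule`: cell index = method×100000 + K×1000 + replicate, offset
by the base seed, mod 2³¹−1), so any cell can be re-run in isolation and
a full sweep is reproducible bit-for-bit. Defaults mirror the standard
protocol: 20 replicates, K = 2..5 (2..4 for 3-class fixtures). Failures
are isolated per cell: the cell is logged and left missing, the sweep
continues. With labels present, adjusted Rand and accuracy rows are
added; with a GMT present, gene partitions from a designated replicate
(default the first) are enriched and a method × cluster count table of
significant terms is emitted.

## Known limitations

* KL-divergence NMF (Brunet's variant) is out of scope; the Frobenius
  objective is the one stated by the model definition.
* No model-order selection beyond the K sweep; no soft/fuzzy membership;
  no consensus across differing K.
* The enrichment layer does no GO-DAG propagation; term structure beyond
  the GMT file's flat sets is ignored.
* The λ penalties do not guarantee increased sparseness (see above);
  they are surrogates for the point-count penalty that motivated them.
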