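# Methods

`pathorm` predicts associations between pathogenic RNA-methylation (RM) sites
(m⁶A, m⁷G) and diseases. A site is "pathogenic" when a disease-associated
genetic variant creates or destroys the modification site; the prediction
problem is link prediction on a bipartite site–disease network, supported by
site–site and disease–disease similarity learned from multiple feature views.

## Feature views

Sites carry three views: a nucleotide-chemical-property (NCP) encoding — three
binary properties per base, A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1),
concatenated 5′→3′ — an accumulated nucleotide frequency (ANF) profile —
position *i* receives the prefix frequency of its own base, count(seq[i] in
seq[1..i])/i — and a semantic embedding matrix. Diseases carry a binary GO
feature matrix and a semantic embedding. The semantic matrices are *inputs*:
in practice they come from pretrained sequence/biomedical language models,
which this package deliberately does not run; any numeric embedding with one
row per entity works. The NCP table is one fixed bijective choice among the
3-bit encodings in use in the sequence-feature literature; any bijection
carries the same information, so one is pinned for reproducibility. By
default only the reference sequence feeds the encoders; `use_alt=True`
concatenates reference and alternative encodings.

## Multi-view affinity learning

For each entity type, the per-view matrices A⁽ⁱ⁾ (entities × features,
entities unit-L2-normalised per view and used transposed so columns are
entities) are jointly factored through self-expression:

    min_{C,E}  Σᵢ [ β‖C⁽ⁱ⁾‖★ + (1−β)‖C⁽ⁱ⁾‖₁ + λ_E‖E⁽ⁱ⁾‖₁ ]
             + Σ_{i≠j} ‖C⁽ⁱ⁾ − C⁽ʲ⁾‖_F²
    s.t.  A⁽ⁱ⁾ = A⁽ⁱ⁾C⁽ⁱ⁾ + E⁽ⁱ⁾,  diag(C⁽ⁱ⁾) = 0 .

The idealised model constrains A = AC exactly. Run to convergence on noisy
data, that constraint forces the coefficients to reproduce the noise and the
block structure of C collapses (we measured within/between coefficient ratios
near 1 at 5 % feature noise). The sparse corruption term E is the standard
remedy from robust subspace clustering and is an *exact* penalty: on clean
data the optimum has E = 0 and the hard constraint holds (observed relative
self-expression residual ~2·10⁻⁷ on noiseless fixtures), while on noisy data
E soft-thresholds the corruption away from C.

Solver: inexact augmented Lagrangian in the LRR style with splits J
(singular-value thresholding for the nuclear norm) and S (soft thresholding
for the L1 norm), a closed-form shrinkage for E, a ridge-type linear solve
for C with the diagonal projected to zero after each solve, multiplier
ascent, and the penalty schedule μ ← min(ρμ, μ_max). Views are updated
Jacobi-style within a sweep (each view sees the previous sweep's partners),
which preserves symmetry exactly: identical views yield identical
coefficients at every iterate.

Parameters (``MvSolverConfig``): β = 0.5 (unitless balance of low-rankness
vs sparsity; midpoint as neutral prior, exposed), λ_E = 2.0 (unitless thanks
to the unit-norm preprocessing; chosen so the absorbed residual matches the
injected corruption level on development fixtures), μ₀ = 10⁻², ρ = 1.1,
μ_max = 10⁶, tol = 10⁻⁶ on the maximum relative residual, max_iter = 500.

The ``SolveTrace.objective`` list records the merit function — the relaxed
objective with E eliminated, Σᵢ β‖C⁽ⁱ⁾‖★ + (1−β)‖C⁽ⁱ⁾‖₁ + λ_E‖A⁽ⁱ⁾−A⁽ⁱ⁾C⁽ⁱ⁾‖₁
plus the consensus term — for *accepted* sweeps only: a sweep that increases
the merit is executed (multiplier ascent is not monotone) but counted in
``n_rejected`` rather than appended, so the recorded trace is non-increasing
by construction.

Fusion: elementwise mean of the per-view C, symmetrisation (|C|+|Cᵀ|)/2,
zero diagonal, and min-max scaling of the off-diagonal entries to [0,1] so a
single similarity threshold downstream is well defined. If all off-diagonal
entries are equal, nonzero values map to 1 and zeros stay 0.

## Heterogeneous graph

Thresholding at τ (strictly greater; equality drops the edge, a determinism
convention) turns the fused affinities into binary blocks C̃_SS and C̃_DD,
assembled with the association block X_SD into

    X = [[C̃_SS, X_SD], [X_SDᵀ, C̃_DD]] ∈ {0,1}^{(m+n)×(m+n)} .

During cross-validation X_SD is built from *training* positives only — the
held-out fold never contributes edges. Node features H⁽⁰⁾ stack the site and
disease semantic embeddings, zero-padded to a common width (a seeded random
projection is available as ``pad_mode=learned_projection``). τ has no
universal value: the min-max scaling concentrates most off-diagonal mass near
zero, so for the synthetic benchmark τ = 0.1 was chosen from edge statistics
(within-cluster edge precision ≈ 1.0 at site-block recall ≈ 0.35 and
disease-block recall ≈ 0.98); at τ = 0.5 the site block is nearly empty.

## Graph autoencoder

Three message-passing encoders are implemented in dense NumPy with
hand-derived gradients (the graphs here are hundreds of nodes, so explicit
linear algebra is simpler, dependency-free and exactly reproducible):

* GCN: H′ = act(D̂^{−1/2}(X+I)D̂^{−1/2} H W + b) — renormalised adjacency
  with self-loops;
* GraphSAGE: H′ = act(H W₁ + mean-of-neighbours · W₂ + b); an isolated
  node's neighbour mean is the zero vector;
* GIN: H′ = act(MLP((1+ε_GIN)H_v + Σ_{u∈N(v)} H_u)) with ε_GIN = 0; the
  2-layer MLP applies batch normalisation (learnable scale/shift, full-batch
  statistics) before its internal ReLU. The normalisation is part of the
  canonical GIN and is load-bearing here: the raw sum aggregation over dense
  similarity blocks saturates the decoder (|logits| > 100 at initialisation)
  and no training budget recovers the gap. Training is full-batch, so the
  statistics are deterministic and identical between training and scoring.

The encoder stacks three layers (deeper stacks over-smooth; the default is
fixed at 3) with ReLU between layers and a linear final layer so latent
coordinates may take either sign. The decoder scores pair (i,j) as
σ(⟨h_sᵢ, h_dⱼ⟩). The loss is a weighted cross-entropy over the labelled
pairs, with the positive term weighted |Ω⁻|/|Ω⁺| and the whole sum scaled by
1/(m·n); scores are clamped to [10⁻⁷, 1−10⁻⁷] inside the logs (the loss is
undefined at 0/1), while gradients are those of the unclamped loss, the
numerically stable convention.

Adversarial training follows the fast gradient method: after the clean
forward/backward pass, the loss gradient g at a target layer embedding H⁽ˡ⁾
is renormalised to r_adv = ε·g/‖g‖₂ (one global L2 norm; ‖r_adv‖₂ = ε
exactly; a zero gradient skips the step), the forward pass is re-run from the
perturbed layer with earlier layers reused, and one Adam step is taken on the
sum of clean and adversarial losses. Default target layer is the first;
ε = 0.1 for training (a small perturbation relative to unit-scale
embeddings), exposed in ``AdvConfig``.

Optimisation: Xavier-uniform initialisation, Adam (lr 10⁻³), hidden width
64, 500 epochs — the budget at which all three encoders reach their loss
plateau at the benchmark scale. Divergence (non-finite loss) aborts with the
epoch index.

## Negative sampling

Guilt-by-association: dissimilar sites rarely share disease pathways, so for
each positive (sᵢ, dⱼ) the sampler walks candidates (s_k, dⱼ) in order of
ascending similarity C_SS[sᵢ, s_k] (ties broken by ascending site index),
taking ⌈ratio⌉ per positive, never selecting a pair twice, and trimming the
final selection to ratio·|Ω⁺|. An exhausted candidate column raises an error
reporting the shortfall. A seeded uniform sampler over the remaining pairs
serves as the ablation control.

## Evaluation protocols

10-fold CV partitions the *pairs* (seeded shuffle, contiguous chunks). Per
fold, test negatives are drawn by the configured sampler at ratio 1
(balanced) or 10 (imbalanced); training negatives are drawn uniformly at 1:1
from the remaining pool, excluding all test pairs. The uniform training draw
is a feasibility requirement, not merely a choice: GBA candidates live in the
positive's disease column, and at the benchmark scale a heavily annotated
disease's column is fully consumed by its positives plus 1:10 test negatives.
LODOCV withholds one disease's entire column (from the graph and the loss),
trains with GBA negatives at 1:1 (excluding the held-out column), scores all
sites against the disease and computes one AUC with its validated sites as
positives; diseases without positives are skipped with a warning.

Metrics: AUC is the tie-aware Mann–Whitney statistic (ties credit ½ —
asserted against exhaustive pair enumeration); AUPR is step-integrated
precision–recall area (scikit-learn's average precision); ACC, Precision,
Recall, Specificity and F1 use a fixed 0.5 threshold. Single-class test sets
report AUC/AUPR as NaN markers, never 0. Folds are aggregated as mean ± sd
(per-fold averaging, not pooled predictions). Method comparisons use the
two-sided paired Wilcoxon signed-rank test; identical vectors return p = 1.

## Interpretation

Given a per-sequence attention matrix (an input — producing one requires the
upstream language model), each position's importance is its off-diagonal row
sum, min-max scaled to [0,1]; an all-equal profile maps to the neutral 0.5.
The scores are scale-invariant. High-importance windows can be exported as
FASTA for external motif tools; motif discovery itself is out of scope.

## Synthetic data

The generator plants the structure every stage assumes: site clusters share
a consensus host sequence (per-site per-position mutation rate = noise_sd)
and a semantic centroid; sites and diseases carry rank-r latent factors
aligned with the clusters (cluster c's centroid is 2·e_c); a pair's
ground-truth association probability is σ(⟨u_s, v_d⟩) and the top `pos_count`
pairs become the validated positives. The disease GO view is a thresholded
noisy cluster indicator. Because the truth is a logistic low-rank bilinear
model — the decoder's own family — parameter recovery is well posed and
tests measure implementation correctness rather than model misspecification.

Benchmark defaults: m = 80 sites, n = 50 diseases, 4 clusters, 300
positives, rank-4 factors, window 21 nt, semantic widths 16, GO width 20,
noise_sd = 0.1. This trains in seconds per fold on one CPU. The
`simulate_clustered_views` fixture used for the affinity solver gives each
cluster an exactly orthogonal subspace per view (disjoint blocks of a random
orthonormal frame), so noiseless self-expression is exact by construction.

What the generator does *not* emulate: real motif grammars, genome context,
transcriptome-wide methylation landscapes, the long-tailed disease ontology,
or embeddings from actual language models. Passing tests therefore
demonstrate that the algorithms recover structure they can represent, not
that the method attains any particular accuracy on curated RM–disease data.

## Numerical choices and degenerate inputs

* Threshold equality at τ drops the edge (strict >).
* Min-max scaling with all-equal off-diagonals: nonzero → 1, zero → 0.
* All-equal attention profiles → 0.5 everywhere.
* Zero data matrices solve to C = 0 with objective 0.
* FGM with zero gradient returns a zero perturbation and a skip flag.
* Score clamp 10⁻⁷ inside the cross-entropy; decoder output clipped away
  from exact 0/1 at 10⁻¹².
* A global seed fans out to per-stage seeds via a CRC32-based hash, so a
  stage rerun in isolation reproduces its in-pipeline behaviour.

## Known limitations

* Dense O((m+n)²) adjacency and O(m³) affinity solves: fine for hundreds of
  entities, not for tens of thousands.
* The GBA sampler is undefined when a disease column cannot supply the
  requested negatives; the CV driver avoids this by sampling training
  negatives uniformly, but extreme ratios on small site sets can still
  exhaust test columns.
* λ_E is a fixed default, not estimated from the data; heteroscedastic or
  heavy-tailed feature noise would warrant per-view tuning.
* Attention matrices must arrive pre-collapsed across heads/layers.
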