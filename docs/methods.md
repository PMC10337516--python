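# Methods

## Problem setting

`ehrgan` targets clinical prediction from tabular EHR-like data when only a
small fraction of records carry an outcome label (the *label rate*,
stratified per class). Instead of discarding the unlabeled majority, the
method exploits the geometric structure of the cohort: records that are
close in feature space are likely to share an outcome. The pipeline has four
stages.

1. **Graph conversion.** Records, one-hot encoded and min-max scaled to
   [0, 1], are linked to their k nearest neighbours under Euclidean
   distance. Each candidate edge (union of the directed k-NN relations) is
   weighted by the Jaccard coefficient of the endpoints' neighbour sets,
   `w_ij = |N_k(i) ∩ N_k(j)| / |N_k(i) ∪ N_k(j)|`. Edges at or below a
   configurable lower bound (default 0, i.e. only zero-weight edges) are
   removed; isolated nodes are reported as noise and dropped.
2. **Graph embedding.** The weighted graph is embedded by stochastic
   optimization of LINE-family proximity objectives with negative sampling
   (edges drawn ∝ weight via an alias table; noise nodes ∝ degree^0.75).
   Default output dimension is ⌈d/2⌉, half the processed feature width.
3. **Adversarial semisupervised training.** A generator maps Gaussian noise
   to the real-sample space; an (M+1)-way discriminator assigns samples to
   the M outcome classes or a fake class. The discriminator loss sums a
   Wasserstein critic term with gradient penalty, a supervised
   cross-entropy over the real classes on labeled samples, an unsupervised
   real-vs-fake term weighted by λ0, a conditional-entropy regularizer on
   unlabeled samples, and a pull-away term (mean squared pairwise cosine
   similarity of last-hidden-layer features of fakes). The generator
   minimizes the negated critic score plus the same pull-away term, pushing
   generated samples into — and spreading them across — the low-density gap
   between classes.
4. **Evaluation.** The trained discriminator's softmax, renormalized over
   the M real classes, is the classifier. The generator is audited by
   dimension-wise probability (per-feature Bernoulli success, real vs
   synthetic) and dimension-wise prediction (per-feature F1 of logistic
   classifiers trained on real vs synthetic data), and by a k-NN
   attribute-disclosure attack.

## Numerical machinery

No deep-learning framework is used; `ehrgan.autodiff` is a compact
reverse-mode automatic-differentiation engine over numpy arrays whose
vector-Jacobian products are themselves expressed as graph operations, so a
backward pass run with `create_graph=True` is differentiable. This is what
the gradient penalty needs: `(‖∇_x s(x̂)‖ − 1)²` is formed from a
first-order gradient and then differentiated again with respect to the
critic parameters. Gradient correctness is pinned by finite-difference
tests at 1e-4 tolerance (observed agreement ~1e-10).

The critic score of the (M+1)-way softmax discriminator is the real-vs-fake
log-odds `s(x) = logsumexp(real logits) − fake logit`; interpolation points
for the penalty are uniform per-sample mixes of paired real and fake rows,
with λ_gp = 10.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 10 | neighbourhood size of the record graph |
| `lower_bound` | 0.0 | Jaccard weight at/below which edges are pruned |
| `dim` | ⌈d/2⌉ | embedding width |
| `order` | second | LINE proximity order (`first`/`second`/`both`) |
| `z_dim` | 100 | generator noise width |
| `gen_layers`, `disc_layers` | (128, 128) | hidden widths |
| `λ0, λ_ent, λ_pt` | 1.0 | weights of the unsupervised, entropy and pull-away terms |
| `λ_gp` | 10 | gradient-penalty weight |
| `lr`, `adam_beta1` | 0.003, 0.5 | Adam step size and first-moment coefficient |
| `batch` | 128 | minibatch size (labeled, unlabeled, fake batches each) |
| `max_epochs` | 200 | training ceiling; early stop when the moving-average discriminator loss changes < 1e-4 for 10 epochs |
| `label_rate` | 0.1 | visible-label fraction per class |

"Momentum 0.5" in the Adam configuration is read as β₁ = 0.5. Batch
normalization sits in the generator only by default: BN inside a
gradient-penalized critic conflicts with the per-sample penalty; a flag
(`batchnorm_in_disc`) restores it.

## Design choices where the design was open

- **GAN input space.** The discriminator can consume embeddings alone
  (`embedding_only`) or the concatenation `[X_i ∥ emb_i]`
  (`concat_features`, default). The concat mode is the default because the
  fidelity and disclosure audits evaluate generated samples *per original
  feature*, which requires the generator to emit feature coordinates; the
  first d columns of a generated sample are that feature view.
- **Entropy and pull-away terms.** The entropy regularizer is the mean
  conditional entropy of the renormalized class distribution on unlabeled
  samples (bounded by [0, ln M]); the pull-away term is the mean squared
  pairwise cosine similarity of last-layer features (bounded by [0, 1]). The
  pull-away value enters both the discriminator and the generator losses,
  each computed on its own step's fake batch; both values are logged
  per epoch (`loss_pt`, `loss_pt_gen`) so the loss-assembly identities can
  be re-checked from the history.
- **Candidate edges.** Union (not intersection) of directed k-NN relations,
  to avoid fragmenting the graph into disconnected components.
- **Supervised-only ablation.** `GanConfig(supervised_only=True)` trains the
  same discriminator on labeled cross-entropy alone (no generator, no
  unsupervised terms), providing the comparison arm for the semisupervised
  gain.
- **Degenerate metrics.** Single-class truth makes AUC undefined: it is
  flagged, not fabricated. In the disclosure attack, a repeat with no
  positive estimates reports precision 0 with a flag.
- **Frontier nodes** are defined as nodes adjacent to at least one node of a
  different predicted class — an adjacency-based reconstruction of the
  cluster-border notion; treat downstream uses accordingly.

## What the synthetic generators emulate — and what they do not

`generate_mixed_ehr` draws records class-first with feature-wise
independence given the class (mixed 2–4-level categoricals plus Gaussian
numericals, 70/30 outcome imbalance, d = 17 after encoding — the dimensional
range of preprocessed registry cohorts). Class-conditional independence is
deliberate: it makes dimension-wise probability/prediction ground truth
analytically known; a Gaussian-copula switch (`correlated=True`) provides
harder fixtures. `generate_gaussian_mixture` places class means `separation`
apart along unit directions with unit spherical noise — the standard
semisupervised test bed. `generate_bernoulli_table` gives exact marginal
ground truth for fidelity audits.

None of these reproduce real EHR pathologies: missingness, code hierarchy,
temporal structure, label noise, or feature dependence beyond the copula
switch. Passing tests therefore demonstrate correctness of the machinery
and recovery of planted structure, not clinical performance.

## Problem sizes used in the checked properties

The shipped property checks run the full pipeline at n = 600–2000 records,
width 10–17, 80–100 training epochs, 5 seeds — sizes at which the planted
structure is comfortably resolvable and a full run takes tens of seconds.
Observed behaviour at these sizes: test AUC ≈ 0.97–0.99 on the
separation-3 mixture at a 10% label rate (within 0.02 of both the
supervised-only ablation and label propagation on the same graph);
dimension-wise probability correlation ≈ 0.95–0.98 with mean absolute
deviation ≈ 0.04–0.06 after 100 epochs on a Bernoulli table with marginals
spanning 0.1–0.9.

## Known limitations

- The Wasserstein critic of a softmax (M+1)-way discriminator is a
  pragmatic construction (real-vs-fake log-odds); it is not a 1-Lipschitz
  potential in any proven sense beyond what the gradient penalty enforces.
- The Jaccard k-NN degree is largely scale-invariant within homogeneous
  regions: two equally coherent clusters at different spatial scales get
  similar weighted degrees. What the weighting reliably separates is
  coherent-cluster membership from isolation (the basis of noise pruning),
  and the degree-density test checks exactly that contrast.
- Exact k-NN only (O(n²) distances, chunked); adequate to ~60k records,
  not beyond.
- Transductive protocol: test records participate in the graph and
  embedding (never in training labels); embedding unseen records requires
  rebuilding.
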