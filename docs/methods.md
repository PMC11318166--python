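# Methods

## The problem

A binary QSAR/QSPR model outputs a probability of activity for any molecule,
but its reliability varies across chemical space: it is trustworthy inside its
applicability domain and can fail systematically on structural classes it never
learned. `chematlas` makes this failure structure *visible*: it places every
compound on a fixed 2D map where structural neighbors are spatial neighbors,
paints each point with a per-compound loss, and lets the user interrogate any
map region with the standard classification statistics.

## The parametric t-SNE projector

Molecules are standardized (largest organic fragment, charge neutralization,
canonical serialization) and encoded as 2048-bit binary extended-connectivity
fingerprints with radius 3. Structural dissimilarity between two molecules is
the Jaccard distance on fingerprint bits, `d = 1 − |A∩B| / |A∪B|`.

Classic t-SNE builds, for each point *i*, a conditional Gaussian neighbor
distribution over the other points,

    p_{j|i} ∝ exp(−d_ij² / 2σ_i²),

where the bandwidth σ_i is calibrated per point by bisection so that the
perplexity `2^H(p_{·|i})` (H = Shannon entropy in bits) equals a target — a
smooth effective-neighbor count. Conditionals are symmetrized into a joint
distribution `p_ij = (p_{j|i} + p_{i|j}) / 2n`. In the 2D map the analogous
distribution uses a Student-t kernel with one degree of freedom,
`q_ij ∝ (1 + ‖y_i − y_j‖²)^{−1}`, whose heavy tail counteracts crowding. The
map is fit by minimizing `KL(P‖Q) = Σ p_ij log(p_ij / q_ij)`.

In the *parametric* variant the map coordinates are not free variables but the
output of a feed-forward network `f: {0,1}^2048 → ℝ²`. Training optimizes the
network weights; afterwards the weights are frozen, so projection of any
molecule — including ones never seen in training — is a pure feed-forward pass:
deterministic across calls, processes, and save/load round trips. Compounds
sharing a scaffold land in the same fixed region of the map, which is what
makes region-level statements ("the model fails in this corner") stable and
reusable.

### Network and optimization

* Architecture: 2048 → 500 → 500 → 2000 → 2, ReLU hidden activations, linear
  output; the raw network outputs are the map coordinates (no post-scaling).
  Dimensions are configurable. This wide-bottleneck shape follows the
  parametric t-SNE lineage; nothing in the analytics depends on it.
* The network and its gradients are implemented directly in numpy. The
  gradient of the KL loss with respect to the output coordinates is the
  standard t-SNE gradient
  `∂C/∂y_i = 4 Σ_j (p_ij − q_ij)(1 + ‖y_i − y_j‖²)^{−1}(y_i − y_j)`,
  backpropagated through the layers; updates use Adam (β₁=0.9, β₂=0.999) with
  a fixed learning rate, default 1e−3.
* Minibatch training: neighbor distributions are computed *within* each
  shuffled batch (default 512), keeping the pairwise work quadratic in the
  batch size rather than the library size. At least two minibatches are
  required; a trailing remainder smaller than a batch is dropped from that
  epoch (reshuffling covers all points across epochs).
* Perplexity default 30 (the community default), entropy tolerance 1e−5, at
  most 50 bisection steps. A row of identical distances makes the perplexity
  unreachable; the uniform row is returned with a warning.
* All randomness (weight initialization — fan-in-scaled uniform,
  `±√(6/fan_in)` — and epoch shuffling) flows from one integer seed, making
  retraining bit-reproducible. Training itself is still seed-dependent: a
  different seed yields a different but equally valid map.
* Numerical guards: `q_ij` floored at 1e−12 inside the loss and gradient;
  a non-finite loss aborts with a diagnostic rather than training through NaNs.
* Model files are versioned NumPy archives (named weight arrays + a JSON
  metadata block recording seed, perplexity, epochs, loss trace); corruption
  and version mismatch raise explicit errors.

## Per-compound loss and region analytics

With ground truth `y ∈ {0,1}` and predicted activity probability `p`, the
per-compound binary cross-entropy is

    Loss = −[y·ln(p) + (1−y)·ln(1−p)],

with `p` clamped to `[1e−7, 1−1e−7]` so that a confidently wrong prediction
gets a large but finite loss (keeping color scales usable). The natural
logarithm is the machine-learning convention. High loss marks confident wrong
predictions; low loss marks confident correct ones.

Any rectangle or simple polygon on the map selects a compound subset (boundary
inclusive; polygons via shapely, which matches even-odd ray casting for
non-self-intersecting shapes). For the subset the package reports:

* confusion counts at a decision threshold (default 0.5; a probability exactly
  at the threshold counts as a positive call),
* sensitivity, specificity, accuracy, balanced accuracy, F1, Matthews
  correlation coefficient, and AUC-ROC,
* the ROC curve (descending threshold sweep, trapezoidal AUC — equal to the
  tie-corrected pairwise concordance probability),
* per-class Gaussian KDE curves of the predicted probabilities (Scott's rule
  bandwidth, 512-point grid on [0,1]; classes with fewer than two distinct
  values fall back to fixed-width single kernels of width 0.05).

Degenerate selections never crash: an empty region yields an n=0 report, and
any zero-denominator statistic becomes an explicit `null` with a flag string
(MCC is reported as 0 by convention, flagged). A region covering the whole map
reproduces the global report exactly.

## Model cliffs

A *model cliff* is a pair of compounds that (1) are structurally similar —
fingerprint Tanimoto ≥ 0.6 by default, (2) have opposite ground-truth
activity, and (3) receive the same predicted class, so the model misses the
activity change and exactly one member carries a high loss. Similarity is
defined structurally rather than by map proximity: proximity on the map is the
*visualization* of similarity, not its definition, though the map distance is
reported for cross-reference. Pairs are ranked by the summed loss of their
members, surfacing the most confidently-wrong contrasts first. The pair scan
is exact (full upper triangle), adequate to tens of thousands of compounds.

Both thresholds are configurable; no published quantification of "similar" or
"proximate" exists for this task, so the defaults are this package's choices.

## The synthetic study system

The generator emulates the *structure* of a realistic validation exercise — a
screening library with scaffold clusters, ~30% actives, and a classifier that
is good on most structural classes but systematically wrong on one — without
any external data:

* **Library**: up to five hard-coded, chemically distinct cores (benzene,
  pyridine, cyclohexane, a fused bicyclic, an open chain), each decorated at
  two positions with substituents sampled from a 14-fragment alphabet. Because
  the cores are disjoint, within-scaffold fingerprint similarity exceeds
  between-scaffold similarity by construction (the gap is asserted > 0.1 in
  tests). Default 50 molecules per scaffold; the standard study uses 3
  scaffolds (150 molecules).
* **Labels**: exactly `round(0.3 · n)` actives per scaffold (matching the
  roughly one-third active fraction typical of curated binary endpoint sets),
  assigned by seeded permutation.
* **Classifier**: probabilities are `sigmoid(z)` with `z` Gaussian in logit
  space, sd 0.8. Calibrated scaffolds center `z` at ±1.5 on the correct side
  (correct-side rate ≈ 0.97); in a miscalibrated scaffold the *actives* are
  centered at −1.0 — the wrong side — creating a systematic false-negative
  pocket, while its inactives stay calibrated.
* **Cliff planting**: a homolog pair (ethyl vs propyl on the same core, same
  second substituent; Tanimoto ≥ 0.6 on every template) with opposite labels,
  the active member predicted inactive at p=0.02 and the inactive member at
  p=0.45, so the planted pair carries the maximal summed loss.

What passing tests on this system do and do not show: they demonstrate that
the pipeline recovers known cluster structure, localizes a known failure
region, and surfaces a known undetected activity change. They do not
demonstrate performance on real medicinal-chemistry series, on activity
landscapes with potency gradients, or on assay noise correlated with
structure — none of which the generator emulates.

## Study sizes and defaults used in the shipped checks

The test suite and the acceptance script train on the 3-scaffold, 150-molecule
library with batch size 75 (two minibatches per epoch), perplexity 30, and 150
epochs — sizes at which a full run of the pipeline completes in well under a
minute on a single CPU while leaving a comfortable margin on every asserted
property (scaffold silhouette ≈ 0.4–0.5 against the 0.3 bar; the KL loss
roughly halves from the first to the last epoch). Unit tests use a smaller
network (64-unit hidden layers) where only determinism or monotonicity is at
stake.

## Known limitations

* Training quality is seed- and size-dependent; the silhouette bound is a
  property of the well-separated synthetic clusters, not a general guarantee.
* Minibatch affinities approximate the full joint distribution; very small
  batches relative to perplexity distort neighborhoods (hence the
  `perplexity < batch_size` invariant).
* Column-role detection is heuristic. A column of short strings that happen to
  parse as SMILES, or two [0,1] columns with uninformative names, require the
  user to rename columns (ambiguities are fatal, never guessed silently).
* Only binary endpoints are supported; regression endpoints and multi-class
  models are out of scope, as is tautomer canonicalization during
  standardization (largest-fragment + neutralization only, which keeps
  standardization deterministic and idempotent).
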