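# chematlas

Deterministic 2D chemical maps for the visual validation of binary QSAR/QSPR
models.

A binary activity model is rarely uniformly good: it fails on the structural
classes it never learned, and a single global AUC hides where. `chematlas`
trains a **parametric t-SNE** projector — a feed-forward network
`f: {0,1}^2048 → ℝ²` that minimizes the Kullback–Leibler divergence
`KL(P‖Q) = Σ p_ij log(p_ij/q_ij)` between fingerprint-space neighbor
distributions (Gaussian kernels on Jaccard distances, perplexity-calibrated
per point) and map-space neighbor distributions (Student-t kernel,
`q_ij ∝ (1+‖y_i−y_j‖²)^{−1}`). Because the mapping is a trained network with
frozen weights, projecting a molecule is deterministic and new compounds land
in fixed, nameable regions of the map — scaffold clusters stay put.

On top of the map, for a dataset carrying ground truth `y ∈ {0,1}` and a
model's predicted activity probability `p`, the package computes:

* the per-compound binary cross-entropy `Loss = −[y ln p + (1−y) ln(1−p)]`,
  which is high exactly where the model is confidently wrong;
* for any rectangular or polygonal map region: confusion counts, sensitivity,
  specificity, accuracy, balanced accuracy, F1, Matthews correlation
  coefficient, AUC-ROC, the ROC curve, and per-class KDE curves of `p`;
* **model cliffs**: pairs of structurally similar compounds (Tanimoto ≥ 0.6)
  with opposite activity that the model assigns the same class — undetected
  activity changes, ranked by summed loss.

Input CSVs are classified automatically by column content into one of three
operating modes: `STRUCTURE_ONLY` (just SMILES), `PROPERTIES_ONLY` (SMILES
plus annotation columns), or `FULL` (SMILES + binary ground truth + predicted
probability, unlocking the validation analytics).

A synthetic-data module generates scaffold-clustered SMILES libraries and
simulated classifier outputs with controllable calibration and localized
failure regions, so the entire pipeline is testable without external data.

## Worked example

Generate a 3-scaffold library (150 molecules, 30% actives) whose simulated
classifier is systematically wrong on scaffold 1, train the projector, project,
and validate:

```sh
chematlas gen-data --out data --seed 1 --n-scaffolds 3 --per-scaffold 50 --miscalibrated 1
chematlas train --input data/full.csv --model map.npz --seed 1 \
    --batch-size 75 --epochs 150
# -> trained on 150 molecules, final KL loss 0.3238 -> map.npz
chematlas project --input data/full.csv --model map.npz --out projected.csv \
    --plot map.svg --color loss
# -> projected 150 molecules -> projected.csv
chematlas validate --input projected.csv --out report/
```

The same pipeline from Python, asking whether the bad scaffold is visible as a
degraded map region:

```python
import numpy as np
from chematlas import *

spec = SyntheticSpec(n_scaffolds=3, per_scaffold=50, seed=1,
                     miscalibrated_scaffolds=frozenset({1}))
frame = generate_dataset(spec)
X = fingerprint_matrix(standardize_all(frame.smiles))
model = train(X, TrainingConfig(perplexity=30, batch_size=75, epochs=150, seed=1))
Y = project(model, X)

y, p = frame.ground_truth.to_numpy(), frame.probability.to_numpy()
print("global balanced accuracy:", region_report(Y, y, p).metrics.balanced_accuracy)
for s in range(3):
    m = frame.scaffold_id.to_numpy() == s
    reg = RegionSelection.rectangle(Y[m,0].min(), Y[m,0].max(), Y[m,1].min(), Y[m,1].max())
    print(f"scaffold {s} region balanced accuracy:",
          region_report(Y, y, p, region=reg).metrics.balanced_accuracy)
```

prints

```
global balanced accuracy: 0.7920634920634921
scaffold 0 region balanced accuracy: 0.9380952380952381
scaffold 1 region balanced accuracy: 0.5333333333333333
scaffold 2 region balanced accuracy: 0.9047619047619048
```

The global number (0.79) looks acceptable, but the map localizes the damage:
the miscalibrated scaffold's region scores barely above chance (0.53) while
the other two regions exceed 0.90 — exactly the failure structure the
simulation planted, recovered from coordinates and probabilities alone.
Hunting cliffs on the same table (`chematlas cliffs --input projected.csv
--out cliffs.csv`) writes a CSV of similar-but-oppositely-labeled pairs the
model fails to distinguish, ranked by summed loss.

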