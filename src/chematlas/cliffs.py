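"""Model-cliff mining: similar structures, opposite activity, one shared prediction.

An activity cliff is a pair of structurally similar compounds whose measured
activities differ; a *model* cliff is such a pair whose difference the model
under investigation fails to detect -- both members receive the same predicted
class, so exactly one of them is misclassified and carries a high
cross-entropy loss.  On the 2D map these pairs show up as proximate points
with contrasting colors, which is why the map distance is reported alongside
the structural (Tanimoto) similarity.

Similarity is defined structurally, as fingerprint Tanimoto above a threshold;
map proximity is the visualization of that similarity, not its definition.
Pairs are ranked by the summed loss of their members so the most
confidently-wrong contrasts surface first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import DEFAULT_THRESHOLD, loss_vector

DEFAULT_SIMILARITY_THRESHOLD = 0.6


@dataclass
class CliffPair:
    index_i: int
    index_j: int
    tanimoto: float
    map_distance: float
    y_i: int
    y_j: int
    p_i: float
    p_j: float
    predicted_class_i: int
    predicted_class_j: int
    loss_i: float
    loss_j: float

    @property
    def combined_loss(self) -> float:
        return self.loss_i + self.loss_j


def pairwise_tanimoto(
    fingerprints: np.ndarray, threshold: float
) -> list[tuple[int, int, float]]:
    """All unordered row pairs with Tanimoto similarity >= threshold (exact)."""
    X = (np.asarray(fingerprints) != 0).astype(np.float64)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)  # two empty vectors: identical
    iu = np.triu_indices(len(X), k=1)
    keep = sim[iu] >= threshold
    return [
        (int(i), int(j), float(s))
        for i, j, s in zip(iu[0][keep], iu[1][keep], sim[iu][keep])
    ]


def find_model_cliffs(
    y: np.ndarray,
    p: np.ndarray,
    fingerprints: np.ndarray,
    xy: np.ndarray | None = None,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[CliffPair]:
    """Mine model cliffs from a FULL-mode table.

    A pair qualifies when (1) fingerprint Tanimoto >= ``similarity_threshold``,
    (2) the ground truths differ, and (3) the predicted classes at the decision
    ``threshold`` are equal -- the model misses the activity change.  Output is
    ranked by descending combined loss (ties by index order), deterministic
    given the inputs.
    """
    y = np.asarray(y, dtype=np.int64)
    p = np.asarray(p, dtype=np.float64)
    if fingerprints is None:
        raise ValueError("fingerprints are required for cliff mining")
    fingerprints = np.asarray(fingerprints)
    if len(fingerprints) != len(y) or len(p) != len(y):
        raise ValueError("y, p and fingerprints must be aligned")
    losses = loss_vector(y, p)
    pred = (p >= threshold).astype(np.int64)
    pairs: list[CliffPair] = []
    for i, j, sim in pairwise_tanimoto(fingerprints, similarity_threshold):
        if y[i] == y[j] or pred[i] != pred[j]:
            continue
        if xy is not None:
            d = float(np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]))
        else:
            d = float("nan")
        pairs.append(
            CliffPair(
                index_i=i, index_j=j, tanimoto=sim, map_distance=d,
                y_i=int(y[i]), y_j=int(y[j]), p_i=float(p[i]), p_j=float(p[j]),
                predicted_class_i=int(pred[i]), predicted_class_j=int(pred[j]),
                loss_i=float(losses[i]), loss_j=float(losses[j]),
            )
        )
    pairs.sort(key=lambda c: (-c.combined_loss, c.index_i, c.index_j))
    return pairs


def cliffs_to_frame(pairs: list[CliffPair], smiles: list[str] | None = None) -> pd.DataFrame:
    """Ranked cliff report as a table, ready for CSV export."""
    rows = []
    for c in pairs:
        row = {
            "index_i": c.index_i, "index_j": c.index_j,
            "tanimoto": c.tanimoto, "map_distance": c.map_distance,
            "y_i": c.y_i, "y_j": c.y_j, "p_i": c.p_i, "p_j": c.p_j,
            "loss_i": c.loss_i, "loss_j": c.loss_j,
            "combined_loss": c.combined_loss,
        }
        if smiles is not None:
            row = {"smiles_i": smiles[c.index_i], "smiles_j": smiles[c.index_j], **row}
        rows.append(row)
    return pd.DataFrame(rows)
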