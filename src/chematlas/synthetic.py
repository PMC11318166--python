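"""Synthetic fixtures: scaffold-clustered SMILES libraries and a simulated classifier.

Real benchmark sets for visual model validation -- e.g. an estrogen-receptor
binder collection with a few thousand compounds, roughly 30% actives, and a
model that is accurate on steroid-like scaffolds but systematically wrong on
another structural class -- are external data.  This module emulates their
*structure* at desk scale:

* :func:`generate_library` enumerates substituted analogs of a handful of
  chemically distinct core templates (aromatic rings, saturated rings, a fused
  bicyclic, an open chain), so that within-scaffold fingerprint similarity
  exceeds between-scaffold similarity by construction;
* :func:`simulate_classifier` draws predicted probabilities from a
  logit-space Gaussian centered on the correct class for calibrated scaffolds
  and, for designated miscalibrated scaffolds, centers actives on the wrong
  side of 0.5 -- a systematic false-negative region that shows up on the map
  as a pocket of high loss.

Everything is driven by a single seed; identical specs produce identical
libraries and probabilities.  What this generator does NOT emulate: realistic
medicinal-chemistry series, activity landscapes with potency gradients, or
assay noise correlated with structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigError

#: core templates with two substitution slots; chemically distinct ring/chain
#: systems so scaffold clusters are separable by construction
DEFAULT_TEMPLATES: tuple[str, ...] = (
    "{a}c1ccc({b})cc1",        # benzene
    "{a}c1ccc({b})nc1",        # pyridine
    "{a}C1CCC({b})CC1",        # cyclohexane
    "{a}C1CCC2CC({b})CCC2C1",  # fused bicyclic (steroid-like core in miniature)
    "{a}CCCCC{b}",             # open chain (non-cyclic class)
)

#: substituents valid both as a SMILES prefix and inside a branch
DEFAULT_ALPHABET: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
    "F", "Cl", "Br", "CO", "CC(=O)",
)

_CALIBRATED_LOGIT = 1.5
_MISCALIBRATED_LOGIT = -1.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic screening library + classifier simulation."""

    n_scaffolds: int = 5
    per_scaffold: int = 50
    substituent_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    active_fraction: float | Sequence[float] = 0.3
    miscalibrated_scaffolds: frozenset[int] = field(default_factory=frozenset)
    noise_sd: float = 0.8
    seed: int = 0
    templates: tuple[str, ...] = DEFAULT_TEMPLATES

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.n_scaffolds > len(self.templates):
            raise ConfigError(
                f"n_scaffolds must be in [1, {len(self.templates)}] for the given templates"
            )
        if self.per_scaffold < 1:
            raise ConfigError("per_scaffold must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        fracs = self.active_fractions
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigError("active_fraction values must lie in [0, 1]")
        for frag in self.substituent_alphabet:
            for tmpl in self.templates[: self.n_scaffolds]:
                smi = tmpl.format(a=frag, b=frag)
                if Chem.MolFromSmiles(smi) is None:
                    raise ConfigError(
                        f"substituent {frag!r} yields invalid SMILES {smi!r} "
                        f"in template {tmpl!r}"
                    )

    @property
    def active_fractions(self) -> list[float]:
        if isinstance(self.active_fraction, (int, float)):
            return [float(self.active_fraction)] * self.n_scaffolds
        fracs = [float(f) for f in self.active_fraction]
        if len(fracs) != self.n_scaffolds:
            raise ConfigError("active_fraction list must have one entry per scaffold")
        return fracs


def generate_library(spec: SyntheticSpec) -> list[tuple[str, int]]:
    """Sample a scaffold-clustered SMILES library: (smiles, scaffold_id) pairs.

    Each scaffold's template is decorated with two substituents drawn uniformly
    from the alphabet.  All outputs are valid SMILES; duplicates may occur in
    small alphabets and are kept (callers may deduplicate and log).
    """
    rng = np.random.default_rng(spec.seed)
    library: list[tuple[str, int]] = []
    alphabet = list(spec.substituent_alphabet)
    for scaffold_id in range(spec.n_scaffolds):
        tmpl = spec.templates[scaffold_id]
        for _ in range(spec.per_scaffold):
            a, b = rng.choice(alphabet, size=2)
            smi = tmpl.format(a=a, b=b)
            library.append((smi, scaffold_id))
    return library


def assign_labels(scaffold_ids: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Binary activity labels with the spec's exact per-scaffold active fraction.

    The number of actives per scaffold is round(fraction * size); which members
    are active is a seeded permutation, so labels are reproducible.
    """
    scaffold_ids = np.asarray(scaffold_ids)
    rng = np.random.default_rng(spec.seed + 1)
    y = np.zeros(len(scaffold_ids), dtype=np.int64)
    for s, frac in enumerate(spec.active_fractions):
        idx = np.flatnonzero(scaffold_ids == s)
        n_active = int(round(frac * idx.size))
        y[rng.permutation(idx)[:n_active]] = 1
    return y


def simulate_classifier(
    y: np.ndarray, scaffold_ids: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    """Simulated predicted probabilities with controllable calibration.

    Calibrated scaffolds: logit centered at +/-1.5 on the correct side of 0.5
    (with the default noise_sd=0.8 the prediction is on the correct side with
    probability ~0.97).  Miscalibrated scaffolds: actives are centered at
    logit -1.0 -- the wrong side -- creating a systematic false-negative
    region; inactives remain calibrated.
    """
    y = np.asarray(y, dtype=np.int64)
    scaffold_ids = np.asarray(scaffold_ids)
    if len(y) != len(scaffold_ids):
        raise ValueError("y and scaffold_ids must be aligned")
    rng = np.random.default_rng(spec.seed + 2)
    center = _CALIBRATED_LOGIT * (2.0 * y - 1.0)
    bad = np.isin(scaffold_ids, list(spec.miscalibrated_scaffolds)) & (y == 1)
    center[bad] = _MISCALIBRATED_LOGIT
    z = center + spec.noise_sd * rng.standard_normal(len(y))
    return 1.0 / (1.0 + np.exp(-z))


def generate_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Library + labels + simulated predictions as one FULL-shape table."""
    lib = generate_library(spec)
    frame = pd.DataFrame(lib, columns=["smiles", "scaffold_id"])
    frame["ground_truth"] = assign_labels(frame["scaffold_id"].to_numpy(), spec)
    frame["probability"] = simulate_classifier(
        frame["ground_truth"].to_numpy(), frame["scaffold_id"].to_numpy(), spec
    )
    return frame


def plant_model_cliff(
    frame: pd.DataFrame,
    scaffold_id: int = 0,
    p_active: float = 0.02,
    p_inactive: float = 0.45,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Append a same-scaffold pair with opposite labels, both predicted inactive.

    The pair is a homolog pair (ethyl vs propyl substituent on the same core
    with the same second substituent), giving highly similar fingerprints; the
    active member predicted inactive with high confidence is the planted model
    cliff.  Returns the augmented frame and the pair's row positions.
    """
    tmpl = DEFAULT_TEMPLATES[scaffold_id]
    rows = pd.DataFrame(
        {
            "smiles": [tmpl.format(a="CC", b="CC"), tmpl.format(a="CC", b="CCC")],
            "scaffold_id": [scaffold_id, scaffold_id],
            "ground_truth": [0, 1],
            "probability": [p_inactive, p_active],
        }
    )
    out = pd.concat([frame, rows], ignore_index=True)
    return out, (len(out) - 2, len(out) - 1)


def write_example_csvs(outdir: str | Path, spec: SyntheticSpec | None = None) -> dict[str, Path]:
    """Write the three dataset shapes (structure-only, properties-only, full).

    ``structure.csv`` carries only SMILES; ``properties.csv`` adds the scaffold
    annotation and an unbounded numeric property but no prediction pair;
    ``full.csv`` adds binary ground truth and predicted probabilities.
    """
    spec = spec or SyntheticSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = generate_dataset(spec)
    rng = np.random.default_rng(spec.seed + 3)
    paths = {}

    structure = frame[["smiles"]]
    properties = frame[["smiles", "scaffold_id"]].copy()
    properties["logS"] = rng.normal(-3.0, 2.0, len(frame)).round(3)  # unbounded numeric
    full = frame[["smiles", "scaffold_id", "ground_truth", "probability"]]

    for name, table in (("structure", structure), ("properties", properties), ("full", full)):
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        paths[name] = path
    return paths
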