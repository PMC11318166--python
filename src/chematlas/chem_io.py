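"""Dataset ingestion: molecule standardization, ECFP fingerprints, CSV mode detection.

A dataset enters the pipeline as a CSV with one column of SMILES strings and,
optionally, a binary ground-truth column and a predicted-probability column.
Column roles are inferred heuristically from the values; the combination of
assigned roles determines the operating mode:

* ``STRUCTURE_ONLY`` -- the table carries nothing but structures,
* ``PROPERTIES_ONLY`` -- extra categorical/numeric annotation columns exist but
  not a (ground truth, probability) pair,
* ``FULL`` -- both a binary ground-truth column and a probability column are
  present, enabling model-validation analytics.

Molecules are standardized before fingerprinting: the largest organic fragment
is kept (counter-ions of salts are stripped), charges are neutralized where
possible, and the structure is re-serialized canonically.  Standardization is
idempotent and representation-invariant, which is what makes fingerprints --
and therefore map coordinates -- a function of the molecular graph alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import AmbiguousColumnError, InvalidMoleculeError, NoStructureColumnError

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_BITS = 2048
DEFAULT_RADIUS = 3
SMILES_PARSE_THRESHOLD = 0.8

#: accepted spellings of binary ground-truth values
_BINARY_ALIASES = {
    "0": 0.0, "1": 1.0,
    "0.0": 0.0, "1.0": 1.0,
    "true": 1.0, "false": 0.0,
    "active": 1.0, "inactive": 0.0,
}

_PROB_NAME_RE = re.compile(r"prob|score|pred", re.IGNORECASE)
_TRUTH_NAME_RE = re.compile(r"truth|label|activ|class|^y$", re.IGNORECASE)


class Mode(Enum):
    STRUCTURE_ONLY = "STRUCTURE_ONLY"
    PROPERTIES_ONLY = "PROPERTIES_ONLY"
    FULL = "FULL"


@dataclass
class MoleculeRecord:
    """A standardized molecule; ``fingerprint`` is filled in by :func:`compute_ecfp`."""

    input_smiles: str
    canonical_smiles: str | None
    valid: bool
    reason: str | None = None
    fingerprint: np.ndarray | None = None


@dataclass
class DatasetTable:
    """A parsed CSV with inferred column roles and operating mode."""

    frame: pd.DataFrame
    column_roles: dict[str, str]
    mode: Mode
    drop_log: list[dict] = field(default_factory=list)

    @property
    def smiles_column(self) -> str:
        return next(c for c, r in self.column_roles.items() if r == "smiles")

    def column_for(self, role: str) -> str | None:
        for c, r in self.column_roles.items():
            if r == role:
                return c
        return None


_largest_fragment = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def standardize_molecule(smiles: str) -> MoleculeRecord:
    """Standardize a SMILES string into a canonical molecule record.

    Keeps the largest organic fragment (stripping salt counter-ions),
    neutralizes charges where chemically possible, and serializes the result
    canonically.  Unparseable input yields a retained record with
    ``valid=False`` and a reason so callers can drop-and-log.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return MoleculeRecord(str(smiles), None, False, reason="empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return MoleculeRecord(smiles, None, False, reason="SMILES parse failure")
    try:
        mol = _largest_fragment.choose(mol)
        mol = _uncharger.uncharge(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        return MoleculeRecord(smiles, None, False, reason=f"standardization failure: {exc}")
    return MoleculeRecord(smiles, canonical, True)


_fp_generators: dict[tuple[int, int], object] = {}


def _morgan_generator(n_bits: int, radius: int):
    key = (n_bits, radius)
    if key not in _fp_generators:
        _fp_generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _fp_generators[key]


def compute_ecfp(
    record: MoleculeRecord, n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS
) -> np.ndarray:
    """Binary extended-connectivity fingerprint of a standardized molecule.

    Identical canonical structures map to identical bit vectors; the vector is
    stored on the record and returned as a ``uint8`` array of length ``n_bits``.
    """
    if not record.valid or record.canonical_smiles is None:
        raise InvalidMoleculeError(
            f"cannot fingerprint invalid record ({record.input_smiles!r}: {record.reason})"
        )
    mol = Chem.MolFromSmiles(record.canonical_smiles)
    if mol is None:  # pragma: no cover - canonical SMILES always re-parse
        raise InvalidMoleculeError(f"canonical SMILES failed to re-parse: {record.canonical_smiles!r}")
    fp = _morgan_generator(n_bits, radius).GetFingerprintAsNumPy(mol).astype(np.uint8)
    record.fingerprint = fp
    return fp


def standardize_all(
    smiles: Iterable[str], n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS
) -> list[MoleculeRecord]:
    """Standardize and fingerprint a SMILES collection; invalid records keep valid=False."""
    records = []
    for s in smiles:
        rec = standardize_molecule(s)
        if rec.valid:
            compute_ecfp(rec, n_bits=n_bits, radius=radius)
        records.append(rec)
    return records


def fingerprint_matrix(records: Sequence[MoleculeRecord]) -> np.ndarray:
    """Stack the fingerprints of valid records into an (n, n_bits) uint8 matrix."""
    rows = [r.fingerprint for r in records if r.valid and r.fingerprint is not None]
    if not rows:
        raise InvalidMoleculeError("no valid fingerprinted records")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# CSV column-role heuristics


def _smiles_parse_rate(values: pd.Series) -> float:
    vals = values.dropna().astype(str)
    vals = vals[vals.str.strip() != ""]
    if len(vals) == 0:
        return 0.0
    ok = sum(Chem.MolFromSmiles(v) is not None for v in vals)
    return ok / len(vals)


def _coerce_numeric(values: pd.Series) -> pd.Series | None:
    """Map a column to floats via the binary alias table, else plain float coercion."""
    vals = values.dropna()
    if len(vals) == 0:
        return None
    as_str = vals.astype(str).str.strip().str.lower()
    if as_str.isin(_BINARY_ALIASES).all():
        return as_str.map(_BINARY_ALIASES)
    out = pd.to_numeric(vals, errors="coerce")
    if out.isna().any():
        return None
    return out.astype(float)


def detect_mode(
    table: pd.DataFrame | str | Path,
    smiles_threshold: float = SMILES_PARSE_THRESHOLD,
) -> DatasetTable:
    """Infer column roles and the operating mode of a dataset.

    The SMILES column is the one whose non-empty values parse at the highest
    rate (which must exceed ``smiles_threshold``).  Among the remaining
    columns, a binary-valued column becomes ground truth and a non-binary
    numeric column confined to [0, 1] becomes the predicted probability; a
    binary column is never taken for a probability.  Ties are broken by column
    name (``prob|score|pred`` for probabilities, ``truth|label|activ|class|y``
    for ground truth); unresolved ties are fatal.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if table.shape[0] < 1:
        raise NoStructureColumnError("CSV has a header but no data rows")

    rates = {c: _smiles_parse_rate(table[c]) for c in table.columns}
    passing = {c: r for c, r in rates.items() if r >= smiles_threshold}
    if not passing:
        raise NoStructureColumnError(
            f"no structure column: best SMILES parse rate "
            f"{max(rates.values()):.2f} below threshold {smiles_threshold}"
        )
    best = max(passing.values())
    best_cols = [c for c, r in passing.items() if r == best]
    if len(best_cols) > 1:
        raise AmbiguousColumnError(f"columns tie for the SMILES role: {best_cols}")
    smiles_col = best_cols[0]

    roles: dict[str, str] = {smiles_col: "smiles"}
    binary_cands, prob_cands = [], []
    for c in table.columns:
        if c == smiles_col:
            continue
        coerced = _coerce_numeric(table[c])
        if coerced is None:
            roles[c] = "ignored" if table[c].dropna().empty else "category"
        elif set(np.unique(coerced)) <= {0.0, 1.0}:
            binary_cands.append(c)
        elif coerced.between(0.0, 1.0).all():
            prob_cands.append(c)
        else:
            roles[c] = "numeric"

    def _resolve(cands: list[str], name_re: re.Pattern, role: str, fallback: str) -> None:
        if not cands:
            return
        chosen = cands
        if len(chosen) > 1:
            named = [c for c in chosen if name_re.search(str(c))]
            if len(named) != 1:
                raise AmbiguousColumnError(f"columns tie for the {role} role: {chosen}")
            chosen = named
        roles[chosen[0]] = role
        for c in cands:
            roles.setdefault(c, fallback)

    _resolve(binary_cands, _TRUTH_NAME_RE, "ground_truth", "category")
    _resolve(prob_cands, _PROB_NAME_RE, "probability", "numeric")

    assigned = set(roles.values())
    if {"ground_truth", "probability"} <= assigned:
        mode = Mode.FULL
    elif assigned <= {"smiles", "ignored"}:
        mode = Mode.STRUCTURE_ONLY
    else:
        mode = Mode.PROPERTIES_ONLY
    return DatasetTable(frame=table, column_roles=roles, mode=mode)


def standardize_table(dataset: DatasetTable) -> tuple[DatasetTable, list[MoleculeRecord]]:
    """Standardize every row's SMILES, dropping and logging failures.

    Returns a new :class:`DatasetTable` whose frame keeps only valid rows
    (original indices preserved, canonical SMILES substituted) plus the list
    of valid records with fingerprints attached, aligned with the frame rows.
    """
    col = dataset.smiles_column
    records = standardize_all(dataset.frame[col].astype(str))
    keep_mask = np.array([r.valid for r in records], dtype=bool)
    drop_log = [
        {"row": int(i), "smiles": r.input_smiles, "reason": r.reason}
        for i, r in zip(dataset.frame.index, records)
        if not r.valid
    ]
    frame = dataset.frame.loc[keep_mask].copy()
    kept = [r for r in records if r.valid]
    frame[col] = [r.canonical_smiles for r in kept]
    return (
        DatasetTable(frame=frame, column_roles=dict(dataset.column_roles),
                     mode=dataset.mode, drop_log=drop_log),
        kept,
    )
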