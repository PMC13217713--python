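"""Loading and normalisation of molecule-only and drug–target datasets.

Tabular inputs (CSV/TSV with a header row) are validated into typed
records: every molecule is canonicalised to isomeric SMILES with RDKit,
missing endpoint cells become entries of an explicit boolean
observation mask (never numeric sentinels), and protein sequences are
restricted to the 20 standard amino acids.  Rows that fail validation
are dropped and counted, not raised — mirroring the usual silent
sanitisation step of benchmark preprocessing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord", "DTIRecord", "canonicalize_smiles",
    "load_molecule_table", "load_dti_table", "STANDARD_AA",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class MoleculeRecord:
    """One compound with a (possibly partially observed) endpoint vector."""

    smiles: str
    labels: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.labels.shape != self.observed.shape:
            raise ValueError("labels and observed mask must have equal length")


@dataclass
class DTIRecord:
    """One ligand–protein pair with a continuous affinity."""

    smiles: str
    protein: str
    affinity: float

    def __post_init__(self):
        if not self.protein:
            raise ValueError("protein sequence must be non-empty")
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


def canonicalize_smiles(raw: str) -> str:
    """Return the canonical isomeric SMILES for ``raw``.

    Stereo descriptors are retained; the output is a fixed point of the
    canonicalisation (idempotent).  Unparsable input raises
    :class:`SmilesParseError` naming the offending string.
    """
    if not raw or not isinstance(raw, str):
        raise SmilesParseError(f"empty or non-string SMILES: {raw!r}")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {raw!r}")
    return Chem.MolToSmiles(mol, isomericSmiles=True, canonical=True)


def _sniff_rows(path: str, delimiter: str | None):
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            try:
                delimiter = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
            except csv.Error:
                delimiter = ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: no header row")
        return list(reader), reader.fieldnames


def _require_columns(fieldnames, wanted, path):
    missing = [c for c in wanted if c not in fieldnames]
    if missing:
        raise KeyError(f"{path}: missing column(s) {missing}; have {fieldnames}")


def load_molecule_table(
    path: str,
    smiles_col: str,
    endpoint_cols,
    classification: bool = True,
    delimiter: str | None = None,
):
    """Read a molecule table into records with explicit observation masks.

    Empty cells become ``observed=False``; rows whose SMILES fails to
    parse, or (for classification) whose observed cells are not 0/1,
    are dropped with a logged count.  Duplicate SMILES are retained as
    distinct records.

    Returns ``(records, n_dropped)``.
    """
    endpoint_cols = list(endpoint_cols)
    rows, fieldnames = _sniff_rows(path, delimiter)
    _require_columns(fieldnames, [smiles_col] + endpoint_cols, path)

    records, dropped = [], 0
    for row in rows:
        try:
            smi = canonicalize_smiles(row[smiles_col].strip())
        except SmilesParseError:
            dropped += 1
            continue
        labels = np.zeros(len(endpoint_cols))
        observed = np.zeros(len(endpoint_cols), dtype=bool)
        ok = True
        for k, col in enumerate(endpoint_cols):
            cell = (row[col] or "").strip()
            if cell == "":
                continue
            try:
                val = float(cell)
            except ValueError:
                ok = False
                break
            if classification and val not in (0.0, 1.0):
                ok = False
                break
            labels[k] = val
            observed[k] = True
        if not ok:
            dropped += 1
            continue
        records.append(MoleculeRecord(smiles=smi, labels=labels, observed=observed))

    if dropped:
        logger.warning("%s: dropped %d invalid row(s) of %d", path, dropped, len(rows))
    if not records:
        raise ValueError(f"{path}: no valid rows")
    return records, dropped


def load_dti_table(
    path: str,
    smiles_col: str,
    protein_col: str,
    affinity_col: str,
    delimiter: str | None = None,
):
    """Read ligand–protein–affinity triples.

    Protein sequences are uppercased; rows with residues outside the 20
    standard amino acids, unparsable SMILES, or non-finite affinities
    are dropped with a logged count.  Returns ``(records, n_dropped)``.
    """
    rows, fieldnames = _sniff_rows(path, delimiter)
    _require_columns(fieldnames, [smiles_col, protein_col, affinity_col], path)

    records, dropped = [], 0
    for row in rows:
        try:
            smi = canonicalize_smiles(row[smiles_col].strip())
        except SmilesParseError:
            dropped += 1
            continue
        protein = (row[protein_col] or "").strip().upper()
        if not protein or not set(protein) <= STANDARD_AA:
            dropped += 1
            continue
        try:
            affinity = float((row[affinity_col] or "").strip())
        except ValueError:
            dropped += 1
            continue
        if not np.isfinite(affinity):
            dropped += 1
            continue
        records.append(DTIRecord(smiles=smi, protein=protein, affinity=affinity))

    if dropped:
        logger.warning("%s: dropped %d invalid row(s) of %d", path, dropped, len(rows))
    if not records:
        raise ValueError(f"{path}: no valid rows")
    return records, dropped
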