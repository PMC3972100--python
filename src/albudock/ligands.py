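"""Ligand ingestion and the octanol/water logP descriptor.

Reads SDF files, SMILES lists, or precomputed score tables into
:class:`LigandRecord` objects and computes a Wildman–Crippen
atomic-contribution logP for each molecule.  Ligands read from a score
table may carry a precomputed logP, which is passed through untouched so
descriptors from other software can be injected.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import math

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

logger = logging.getLogger(__name__)

#: Column names a score table must provide (per-site score columns are
#: named ``<pdbid>:<site>`` and are discovered dynamically).
SCORE_TABLE_REQUIRED = ("ligand_id",)
SCORE_TABLE_OPTIONAL = ("logp", "hsa_percent")


@dataclass
class LigandRecord:
    """A compound with structure, descriptors, and curated %HSA evidence.

    ``hsa_percent_values`` holds ``(value, source_label)`` pairs so that
    multi-source literature values can be averaged or flagged downstream.
    """

    ligand_id: str
    mol: Optional[Chem.Mol] = None
    smiles: Optional[str] = None
    logp: Optional[float] = None
    hsa_percent_values: list[tuple[float, str]] = field(default_factory=list)
    stereo_note: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise ValueError("ligand_id must be non-empty")
        for value, _src in self.hsa_percent_values:
            if not 0.0 <= value <= 100.0:
                raise ValueError(
                    f"{self.ligand_id}: %HSA value {value} outside [0, 100]"
                )
        if self.logp is not None and not math.isfinite(self.logp):
            raise ValueError(f"{self.ligand_id}: logp must be finite")


def _check_unique_ids(records: Iterable[LigandRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.ligand_id in seen:
            raise ValueError(f"duplicate ligand_id: {rec.ligand_id!r}")
        seen.add(rec.ligand_id)


def _read_sdf(path: Path) -> list[LigandRecord]:
    records: list[LigandRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: molecule %d failed sanitization; skipped", path, i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        ligand_id = name.strip() or f"mol_{i}"
        records.append(
            LigandRecord(
                ligand_id=ligand_id,
                mol=mol,
                smiles=Chem.MolToSmiles(mol),
            )
        )
    return records


def _read_smiles(path: Path) -> list[LigandRecord]:
    records: list[LigandRecord] = []
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            ligand_id = parts[1] if len(parts) > 1 else f"mol_{i}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning(
                    "%s line %d: unparsable SMILES %r; skipped", path, i + 1, smiles
                )
                continue
            records.append(
                LigandRecord(ligand_id=ligand_id, mol=mol, smiles=Chem.MolToSmiles(mol))
            )
    return records


def _sniff_delimiter(path: Path) -> str:
    with open(path) as handle:
        head = handle.readline()
    return "\t" if "\t" in head else ","


def read_score_table(path: Path | str) -> pd.DataFrame:
    """Read a delimited score table (tab or comma separated).

    Required column: ``ligand_id``.  Optional: ``logp``, ``hsa_percent``,
    and any number of per-structure per-site score columns named
    ``<pdbid>:<site>`` (kcal/mol, more negative = more favorable).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=_sniff_delimiter(path))
    for col in SCORE_TABLE_REQUIRED:
        if col not in table.columns:
            raise ValueError(f"score table missing required column {col!r}")
    if table["ligand_id"].duplicated().any():
        dupes = table.loc[table["ligand_id"].duplicated(), "ligand_id"].tolist()
        raise ValueError(f"duplicate ligand_id: {dupes}")
    return table


def score_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-(structure, site) score columns in a score table."""
    return [c for c in table.columns if ":" in c]


def _read_score_table_records(path: Path) -> list[LigandRecord]:
    table = read_score_table(path)
    records = []
    for _, row in table.iterrows():
        hsa_values = []
        if "hsa_percent" in table.columns and pd.notna(row["hsa_percent"]):
            hsa_values.append((float(row["hsa_percent"]), "score-table"))
        logp = None
        if "logp" in table.columns and pd.notna(row["logp"]):
            logp = float(row["logp"])
        smiles = None
        mol = None
        if "smiles" in table.columns and pd.notna(row["smiles"]):
            mol = Chem.MolFromSmiles(str(row["smiles"]))
            smiles = Chem.MolToSmiles(mol) if mol is not None else str(row["smiles"])
        records.append(
            LigandRecord(
                ligand_id=str(row["ligand_id"]),
                mol=mol,
                smiles=smiles,
                logp=logp,
                hsa_percent_values=hsa_values,
            )
        )
    return records


def read_ligands(path: Path | str, format: str) -> list[LigandRecord]:
    """Read ligands from ``path`` in the named format.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``sdf``, ``smiles``, ``score-table``.

    Molecules that fail sanitization are logged and skipped, never
    silently dropped.  Both members of an enantiomer pair survive as
    separate records when the input lists them separately (stereo
    information is preserved in the canonical SMILES).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On an unknown format, zero parsable records, or duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {
        "sdf": _read_sdf,
        "smiles": _read_smiles,
        "score-table": _read_score_table_records,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    records = readers[format](path)
    if not records:
        raise ValueError(f"{path}: zero parsable records")
    _check_unique_ids(records)
    return records


def map_selenium_to_sulfur(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy of ``mol`` with Se atoms replaced by S.

    Optional preprocessing for selenium-containing xenobiotics (e.g.
    ebselen) whose Se chemistry is poorly parameterized by
    atomic-contribution descriptor schemes.
    """
    out = Chem.RWMol(mol)
    changed = False
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 34:
            atom.SetAtomicNum(16)
            changed = True
    if changed:
        Chem.SanitizeMol(out)
    return out.GetMol()


def compute_logp(ligand: LigandRecord, *, se_to_s: bool = False) -> float:
    """Wildman–Crippen atomic-contribution octanol/water logP.

    Deterministic: identical molecular graphs give identical values.  If
    the record already carries a precomputed logP (score-table input),
    that value is returned untouched.  ``se_to_s`` maps selenium to
    sulfur before the calculation.
    """
    if ligand.logp is not None:
        return ligand.logp
    if ligand.mol is None or ligand.mol.GetNumAtoms() == 0:
        raise ValueError(f"{ligand.ligand_id}: no valid molecular graph")
    mol = map_selenium_to_sulfur(ligand.mol) if se_to_s else ligand.mol
    value = float(Crippen.MolLogP(mol))
    ligand.logp = value
    return value


def write_score_table(table: pd.DataFrame, path: Path | str, sep: str = "\t") -> None:
    """Write a score table in the package's delimited-text schema."""
    table.to_csv(path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)
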