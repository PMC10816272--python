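"""Library I/O: whitespace-separated SMILES files and V2000 SDF.

Malformed entries are skipped with a logged warning, never fatal; the
funnel's audit counts reconcile against the number of *parsed* records.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, List

from rdkit import Chem, RDLogger

from .records import MoleculeRecord, StateTag

log = logging.getLogger(__name__)

# RDKit's C++-side parse chatter is redundant with our own skip log.
RDLogger.DisableLog("rdApp.error")


def read_library(path, fmt: str = "smiles") -> List[MoleculeRecord]:
    """Read a ligand library, one record per well-formed entry.

    Parameters
    ----------
    path : path-like
        File to read.  SMILES files are UTF-8, one ``SMILES id`` pair
        (whitespace-separated) per line; an absent id defaults to the
        1-based line number.  SDF is V2000; the id is the molecule title
        falling back to the record index.
    fmt : {"smiles", "sdf"}

    Returns
    -------
    list of MoleculeRecord
        Input order preserved.  Malformed entries are logged and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"library file not found: {path}")
    if fmt == "smiles":
        records = list(_read_smiles(path))
    elif fmt == "sdf":
        records = list(_read_sdf(path))
    else:
        raise ValueError(f"unsupported library format: {fmt!r}")
    if not records:
        log.warning("no parseable records in %s", path)
    return records


def _read_smiles(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            rec_id = parts[1] if len(parts) > 1 else str(lineno)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                log.warning("skipping malformed SMILES at %s:%d: %s", path, lineno, smiles)
                continue
            yield MoleculeRecord(rec_id, mol)


def _read_sdf(path: Path):
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("skipping malformed SDF record %d in %s", i, path)
            continue
        rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else str(i)
        labels = {}
        if mol.HasProp("labels"):
            try:
                labels = json.loads(mol.GetProp("labels"))
            except json.JSONDecodeError:
                log.warning("unparseable labels field on SDF record %s", rec_id)
        yield MoleculeRecord(rec_id, mol, labels=labels)


def write_library(records: Iterable[MoleculeRecord], path, fmt: str = "smiles") -> None:
    """Write records as a SMILES file or V2000 SDF (conformers included)."""
    path = Path(path)
    records = list(records)
    if fmt == "smiles":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(f"{rec.smiles} {rec.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in records:
                mol = Chem.Mol(rec.mol)
                mol.SetProp("_Name", rec.id)
                if rec.labels:
                    mol.SetProp("labels", json.dumps(rec.labels))
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unsupported library format: {fmt!r}")
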