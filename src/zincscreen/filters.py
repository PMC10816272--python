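"""Library curation filters: substructure, protonation state, rule-of-five
and structural alerts.

All filters are order-preserving subsets of their input (no duplicates
introduced) and idempotent.  Removal logs carry ``(record id, reason)``
pairs so the funnel's audit trail can attribute every elimination.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Iterable, List, Sequence, Tuple

import yaml
from rdkit import Chem

from .properties import RO5_THRESHOLDS, compute_properties
from .records import AlertSet, MoleculeRecord, StateTag

#: Substructure defining the screened chemotype: hydroxamic acid directly on
#: a benzene ring.  Written in its Kekulé form, as commonly printed.
BENZOHYDROXAMATE_SMARTS = "C1=CC=C(C(=O)NO)C=C1"

#: Anionic (deprotonated) hydroxamate state pattern used to select the zinc-
#: chelating form from an ionization-state-enumerated library.
HYDROXAMATE_ANION_SMARTS = "[O-]N([H])C(=O)c1ccccc1"


def compile_substructure(pattern: str) -> Chem.Mol:
    """Compile a substructure pattern, tolerating Kekulé-form aromatic rings.

    Patterns are first tried as SMARTS; if the SMARTS parse fails, or the
    pattern is also valid SMILES describing an aromatic system (so that a
    strict SMARTS reading would wrongly demand aliphatic ring atoms), the
    sanitized SMILES-derived query is used instead.
    """
    as_smarts = Chem.MolFromSmarts(pattern)
    as_smiles = Chem.MolFromSmiles(pattern, sanitize=True)
    if as_smiles is not None and any(a.GetIsAromatic() for a in as_smiles.GetAtoms()):
        return as_smiles
    if as_smarts is not None:
        return Chem.MergeQueryHs(as_smarts)
    if as_smiles is not None:
        return as_smiles
    raise ValueError(f"unparseable substructure pattern: {pattern!r}")


def substructure_filter(
    records: Sequence[MoleculeRecord], pattern: str = BENZOHYDROXAMATE_SMARTS
) -> List[MoleculeRecord]:
    """Keep records containing at least one embedding of ``pattern``."""
    query = compile_substructure(pattern)
    return [rec for rec in records if rec.mol.HasSubstructMatch(query)]


@lru_cache(maxsize=8)
def _anion_query(pattern: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        raise ValueError(f"unparseable state pattern: {pattern!r}")
    return Chem.MergeQueryHs(patt)


def select_hydroxamate_state(
    records: Sequence[MoleculeRecord], pattern: str = HYDROXAMATE_ANION_SMARTS
) -> List[MoleculeRecord]:
    """Keep the deprotonated (anionic) hydroxamate states.

    Survivors are tagged ``state_tag=hydroxamate_anion``.  An empty result
    is legitimate (a library may contain no enumerated anion states).
    """
    query = _anion_query(pattern)
    out = []
    for rec in records:
        if rec.mol.HasSubstructMatch(query):
            rec.state_tag = StateTag.HYDROXAMATE_ANION
            out.append(rec)
    return out


def lipinski_filter(
    records: Sequence[MoleculeRecord],
    thresholds=RO5_THRESHOLDS,
    strict: bool = True,
) -> Tuple[List[MoleculeRecord], dict]:
    """Rule-of-five filter: survivors have zero violations.

    Returns ``(survivors, violations_by_id)``.
    """
    survivors, violations = [], {}
    for rec in records:
        profile = compute_properties(rec, thresholds=thresholds, strict=strict)
        violations[rec.id] = profile.violations
        if profile.violations == 0:
            survivors.append(rec)
    return survivors, violations


def default_alerts() -> AlertSet:
    """The shipped structural-alert set (``data/alerts.yaml``)."""
    text = resources.files("zincscreen.data").joinpath("alerts.yaml").read_text()
    cfg = yaml.safe_load(text)["alerts"]
    return AlertSet.from_pairs(cfg.items())


def load_alerts(path) -> AlertSet:
    """Load an alert set from a YAML file of ``alerts: {name: smarts}`` shape."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)["alerts"]
    return AlertSet.from_pairs(cfg.items())


def reos_filter(
    records: Sequence[MoleculeRecord], alerts: AlertSet | None = None
) -> Tuple[List[MoleculeRecord], List[Tuple[str, str]]]:
    """Rapid elimination of reactive/toxic/assay-interfering substructures.

    A record is removed iff any alert pattern matches; the removal log lists
    ``(record id, alert name)`` with the first triggering alert.
    """
    if alerts is None:
        alerts = default_alerts()
    compiled = list(alerts.compiled())
    survivors, removals = [], []
    for rec in records:
        hit = next((name for name, q in compiled if rec.mol.HasSubstructMatch(q)), None)
        if hit is None:
            survivors.append(rec)
        else:
            removals.append((rec.id, hit))
    return survivors, removals
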