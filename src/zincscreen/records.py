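"""Core ligand containers shared across the screening funnel.

A :class:`MoleculeRecord` is one library entry: an identifier, a SMILES
string (kept as parsed RDKit molecule), an optional protonation-state tag,
optional 3D conformers carried on the RDKit molecule, and -- for synthetic
libraries only -- a mapping of ground-truth labels used by tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from rdkit import Chem


class StateTag(str, enum.Enum):
    """Protonation-state tag of a library entry.

    State *enumeration* (pKa engines) is out of scope here; records arrive
    already enumerated and the funnel only selects among them.
    """

    NEUTRAL = "neutral"
    HYDROXAMATE_ANION = "hydroxamate_anion"
    OTHER = "other"


@dataclass
class MoleculeRecord:
    """One ligand of a screening library.

    Parameters
    ----------
    id : str
        Identifier, unique within a library.
    mol : rdkit.Chem.Mol
        Parsed molecule.  3D conformers, when present, live on this object.
    state_tag : StateTag
        Protonation-state tag; updated by the state-selection filter.
    labels : dict, optional
        Ground-truth flags attached by the synthetic-data generator.
    """

    id: str
    mol: Chem.Mol
    state_tag: StateTag = StateTag.NEUTRAL
    labels: dict = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        """Canonical SMILES of the record."""
        return Chem.MolToSmiles(self.mol)

    @classmethod
    def from_smiles(
        cls,
        rec_id: str,
        smiles: str,
        state_tag: StateTag = StateTag.NEUTRAL,
        labels: Optional[Mapping] = None,
    ) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for record {rec_id!r}: {smiles!r}")
        return cls(rec_id, mol, state_tag, dict(labels or {}))

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()


@dataclass(frozen=True)
class PropertyProfile:
    """Rule-of-five physicochemical profile of one ligand.

    ``mw`` uses average atomic weights (Da), ``logp`` a fragment-additive
    estimate (Wildman-Crippen), ``hbd``/``hba`` integer donor/acceptor counts
    from the perception SMARTS shipped in ``data/perception.yaml``, and
    ``violations`` the number of failed rule-of-five conditions.
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    violations: int

    def __post_init__(self):
        if min(self.hbd, self.hba, self.violations) < 0:
            raise ValueError("hbd, hba and violations must be non-negative")


@dataclass(frozen=True)
class AlertSet:
    """Named collection of structural-alert SMARTS (the 'swill' to eliminate)."""

    alerts: tuple  # of (name, smarts) pairs

    def __post_init__(self):
        names = [n for n, _ in self.alerts]
        if len(set(names)) != len(names):
            raise ValueError("alert names must be unique")
        for name, smarts in self.alerts:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"unparseable alert SMARTS {name!r}: {smarts!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable) -> "AlertSet":
        return cls(tuple((str(n), str(s)) for n, s in pairs))

    def __len__(self) -> int:
        return len(self.alerts)

    def compiled(self):
        """Yield ``(name, query_mol)`` pairs with merged explicit-H queries."""
        for name, smarts in self.alerts:
            patt = Chem.MolFromSmarts(smarts)
            yield name, Chem.MergeQueryHs(patt)
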