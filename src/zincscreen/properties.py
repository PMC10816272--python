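"""Physicochemical property profiles for rule-of-five screening.

Molecular weight uses average atomic weights; logP is the Wildman-Crippen
fragment-additive estimate; donor/acceptor counts follow the perception
SMARTS in ``data/perception.yaml`` (donors = N-H and O-H bonds, acceptors =
N and O atoms, the classical rule-of-five reading).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .records import MoleculeRecord, PropertyProfile

#: Rule-of-five thresholds: (mw, logp, hbd, hba).  Strict '<' comparisons by
#: default, matching the wording "molecular weight < 500 Da, logP < 5,
#: H-bond donors < 5 and H-bond acceptors < 10".
RO5_THRESHOLDS = (500.0, 5.0, 5, 10)

_SUPPORTED_ELEMENTS = frozenset(
    "H B C N O F Si P S Cl Se Br I Na K Ca Mg Zn Fe".split()
)


@dataclass(frozen=True)
class _PerceptionRules:
    donor: Chem.Mol
    acceptor: Chem.Mol


@lru_cache(maxsize=1)
def _ro5_rules() -> _PerceptionRules:
    text = resources.files("zincscreen.data").joinpath("perception.yaml").read_text()
    cfg = yaml.safe_load(text)["ro5"]
    return _PerceptionRules(
        donor=Chem.MolFromSmarts(cfg["donor_atoms"]),
        acceptor=Chem.MolFromSmarts(cfg["acceptor_atoms"]),
    )


def count_donors(mol: Chem.Mol) -> int:
    """Number of O-H and N-H donor hydrogens."""
    rules = _ro5_rules()
    return sum(
        mol.GetAtomWithIdx(idx).GetTotalNumHs(includeNeighbors=True)
        for (idx,) in mol.GetSubstructMatches(rules.donor)
    )


def count_acceptors(mol: Chem.Mol) -> int:
    """Number of N and O acceptor atoms."""
    return len(mol.GetSubstructMatches(_ro5_rules().acceptor))


def compute_properties(record: MoleculeRecord, thresholds=RO5_THRESHOLDS,
                       strict: bool = True) -> PropertyProfile:
    """Compute the rule-of-five profile of one record.

    Parameters
    ----------
    record : MoleculeRecord
    thresholds : tuple, optional
        ``(mw, logp, hbd, hba)`` condition thresholds.
    strict : bool, optional
        Strict ``<`` comparisons (default, following the protocol wording);
        ``False`` uses the classical ``<=`` reading.

    Returns
    -------
    PropertyProfile
        ``violations`` is the number of failed conditions.
    """
    mol = record.mol
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _SUPPORTED_ELEMENTS:
            raise ValueError(
                f"element {atom.GetSymbol()!r} in record {record.id!r} is outside "
                "the supported property table"
            )
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    hbd = count_donors(mol)
    hba = count_acceptors(mol)
    t_mw, t_logp, t_hbd, t_hba = thresholds
    if strict:
        ok = (mw < t_mw, logp < t_logp, hbd < t_hbd, hba < t_hba)
    else:
        ok = (mw <= t_mw, logp <= t_logp, hbd <= t_hbd, hba <= t_hba)
    return PropertyProfile(mw=mw, logp=logp, hbd=hbd, hba=hba,
                           violations=sum(1 for c in ok if not c))
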