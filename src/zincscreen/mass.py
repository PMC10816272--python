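"""Molecular-formula mass calculator for protonated ions.

Monoisotopic masses sum the most-abundant-isotope mass of every atom in the
protonated formula; the electron mass is deliberately ignored, matching the
convention of printed "calculated" HRMS [M+H]+ values.  Nominal masses sum
integer mass numbers.
"""

from __future__ import annotations

import re
from typing import Mapping, Union

from rdkit.Chem.rdchem import GetPeriodicTable

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

Formula = Union[str, Mapping[str, int]]


def parse_formula(formula: str) -> dict:
    """Parse a Hill-style molecular formula string into element counts."""
    counts: dict = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula: {formula!r}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula: {formula!r}")
    return counts


def _as_counts(formula: Formula) -> dict:
    return parse_formula(formula) if isinstance(formula, str) else dict(formula)


def formula_mass(formula: Formula, mode: str = "monoisotopic") -> float:
    """Mass of a neutral formula.

    Parameters
    ----------
    formula : str or mapping
        Molecular formula (``"C21H19N3O5"``) or element->count mapping.
    mode : {"monoisotopic", "nominal"}
        Most-abundant-isotope exact masses, or integer mass numbers.
    """
    pt = GetPeriodicTable()
    counts = _as_counts(formula)
    total = 0.0
    for element, n in counts.items():
        try:
            known = pt.GetAtomicNumber(element) > 0
        except RuntimeError:
            known = False
        if not known:
            raise ValueError(f"unknown element in formula: {element!r}")
        if mode == "monoisotopic":
            total += pt.GetMostCommonIsotopeMass(element) * n
        elif mode == "nominal":
            total += pt.GetMostCommonIsotope(element) * n
        else:
            raise ValueError(f"unknown mass mode: {mode!r}")
    return total


def protonated_mass(formula: Formula, mode: str = "monoisotopic") -> float:
    """m/z of the [M+H]+ ion of a neutral formula (electron mass ignored).

    ``protonated_mass("C21H19N3O5")`` reports 394.1403 at four decimals;
    ``protonated_mass("C9H11NO3", "nominal")`` reports 182.
    """
    counts = _as_counts(formula)
    counts["H"] = counts.get("H", 0) + 1
    mass = formula_mass(counts, mode)
    return round(mass, 4) if mode == "monoisotopic" else mass
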