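"""Receptor/pose structures and zinc-chelation geometry.

The pose filter of the funnel is purely geometric: the two hydroxamate
chelator oxygens are located by substructure matching, their Euclidean
distances to the catalytic zinc are measured, and the pose is classified
bidentate / monodentate / none against a contact cutoff (default 2.6 Å,
boundary inclusive -- only poses *beyond* the cutoff fail).

Docking engines attach through a minimal backend contract
(:class:`DockingBackend`); only a deterministic mock backend is shipped,
since the funnel's logic is engine-agnostic.
"""

from __future__ import annotations

import enum
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .filters import HYDROXAMATE_ANION_SMARTS, _anion_query
from .records import MoleculeRecord

#: Maximum chelator-oxygen -> zinc contact distance (Å).
DEFAULT_CHELATION_CUTOFF = 2.6


class ChelationClass(str, enum.Enum):
    BIDENTATE = "bidentate"
    MONODENTATE = "monodentate"
    NONE = "none"


@dataclass
class ReceptorContext:
    """A receptor structure with its designated catalytic zinc."""

    label: str
    atoms: "object"  # pandas DataFrame of atom records (PDB semantics)
    zinc: np.ndarray  # (3,) Å

    def protein_coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class DockedPose:
    """One ligand pose in the receptor frame (the backend's top-scored pose)."""

    ligand_id: str
    coords: np.ndarray             # (n_atoms, 3) Å, heavy atoms
    chelator_pair: Tuple[int, int]  # (carbonyl O index, hydroxylate O index)
    score: Optional[float] = None   # lower is better
    mol: Optional[Chem.Mol] = None

    def __post_init__(self):
        i, j = self.chelator_pair
        n = len(self.coords)
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError("chelator_pair indices must be valid and distinct")


@dataclass(frozen=True)
class ChelationAssessment:
    """Distances of the two chelator oxygens to the zinc, and the verdict."""

    d_carbonyl: float
    d_hydroxyl: float
    cls: ChelationClass


class DockingBackend(Protocol):
    """Contract for docking engines: one top-scored pose per ligand, or
    None when the ligand cannot be docked in that receptor."""

    def dock(self, record: MoleculeRecord, receptor: ReceptorContext,
             seed: int) -> Optional[DockedPose]: ...


def load_receptor(pdb_path, label: str = "receptor",
                  zinc_selector: Optional[dict] = None) -> ReceptorContext:
    """Load a receptor PDB and resolve its catalytic zinc.

    ``zinc_selector`` may narrow by ``chain`` and/or ``resnum``; the element
    is always ZN.  Zero or multiple matching zincs raise an error listing
    the candidates.  Coordinates are Å, residue numbering as in the file.
    """
    import pandas as pd
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(label, str(pdb_path))
    rows = []
    zincs = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = (atom.element or "").strip().upper()
                    rec = {
                        "serial": atom.serial_number,
                        "name": atom.get_name(),
                        "resname": residue.get_resname().strip(),
                        "chain": chain.id,
                        "resnum": residue.get_id()[1],
                        "element": element,
                        "x": atom.coord[0], "y": atom.coord[1], "z": atom.coord[2],
                    }
                    if element == "ZN":
                        zincs.append(rec)
                    else:
                        rows.append(rec)
        break  # first model only
    sel = zinc_selector or {}
    candidates = [
        z for z in zincs
        if ("chain" not in sel or z["chain"] == sel["chain"])
        and ("resnum" not in sel or z["resnum"] == sel["resnum"])
    ]
    if len(candidates) != 1:
        listing = [f"ZN chain={z['chain']} resnum={z['resnum']}" for z in candidates]
        raise ValueError(
            f"expected exactly one catalytic zinc in {pdb_path}, found "
            f"{len(candidates)}: {listing}"
        )
    zn = candidates[0]
    return ReceptorContext(
        label=label,
        atoms=pd.DataFrame(rows),
        zinc=np.array([zn["x"], zn["y"], zn["z"]], dtype=float),
    )


def identify_chelators(
    ligand: Chem.Mol,
    receptor: Optional[ReceptorContext] = None,
    conf_id: int = 0,
) -> Tuple[int, int]:
    """Locate the hydroxamate chelator oxygens: (carbonyl O, anionic O).

    With multiple hydroxamate embeddings and a receptor supplied, the
    embedding whose oxygen midpoint lies nearest the zinc wins; without a
    receptor the first embedding is used.
    """
    query = _anion_query(HYDROXAMATE_ANION_SMARTS)
    matches = ligand.GetSubstructMatches(query)
    if not matches:
        raise ValueError("ligand has no (anionic) hydroxamate moiety")
    # pattern atom order: [O-], N, C, =O, ring...
    pairs = [(m[3], m[0]) for m in matches]
    if len(pairs) > 1 and receptor is not None and ligand.GetNumConformers() > 0:
        pos = ligand.GetConformer(conf_id).GetPositions()
        def mid_dist(pair):
            return float(np.linalg.norm(pos[list(pair)].mean(axis=0) - receptor.zinc))
        pairs.sort(key=mid_dist)
    return pairs[0]


def classify(d1: float, d2: float,
             cutoff: float = DEFAULT_CHELATION_CUTOFF) -> ChelationClass:
    """Chelation class from the two chelator distances (boundary inclusive)."""
    within = (d1 <= cutoff) + (d2 <= cutoff)
    if within == 2:
        return ChelationClass.BIDENTATE
    if within == 1:
        return ChelationClass.MONODENTATE
    return ChelationClass.NONE


def assess_chelation(
    pose: DockedPose,
    receptor: ReceptorContext,
    cutoff: float = DEFAULT_CHELATION_CUTOFF,
) -> ChelationAssessment:
    """Measure the chelator-oxygen -> zinc distances and classify the pose."""
    i, j = pose.chelator_pair
    d1 = float(np.linalg.norm(pose.coords[i] - receptor.zinc))
    d2 = float(np.linalg.norm(pose.coords[j] - receptor.zinc))
    return ChelationAssessment(d1, d2, classify(d1, d2, cutoff))


# ---------------------------------------------------------------------------
# Mock docking backend
# ---------------------------------------------------------------------------

def _conformer_coords(record: MoleculeRecord, seed: int) -> Tuple[Chem.Mol, np.ndarray]:
    mol = Chem.Mol(record.mol)
    if mol.GetNumConformers() == 0:
        molh = Chem.AddHs(mol)
        if AllChem.EmbedMolecule(molh, randomSeed=int(seed) % (2**31 - 1)) != 0:
            raise ValueError(f"could not embed a conformer for {record.id!r}")
        mol = Chem.RemoveHs(molh)
    return mol, mol.GetConformer().GetPositions()


def _two_sphere_point(zn: np.ndarray, d1: float, d2: float, a: float,
                      e1: np.ndarray, e2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Positions for the two chelator oxygens: O1 at distance d1 from the
    zinc along e1, O2 at distance d2 from the zinc and a from O1, placed in
    the (e1, e2) plane."""
    p1 = zn + d1 * e1
    # law of cosines in the zn-p1-p2 triangle
    cos_t = (d1**2 + d2**2 - a**2) / (2 * d1 * d2)
    cos_t = float(np.clip(cos_t, -1.0, 1.0))
    sin_t = float(np.sqrt(1.0 - cos_t**2))
    p2 = zn + d2 * (cos_t * e1 + sin_t * e2)
    return p1, p2


def mock_dock(
    record: MoleculeRecord,
    receptor: ReceptorContext,
    mode: str = "chelating",
    seed: int = 0,
) -> DockedPose:
    """Deterministic geometric stand-in for a docking engine.

    ``chelating`` places both chelator oxygens 2.0-2.3 Å from the zinc,
    ``monodentate`` exactly one (the other beyond the cutoff), and
    ``nonbinding`` both beyond 4 Å.  The rest of the ligand is placed
    rigidly, rotated about the chelation axis to the least-clashing of a
    fixed set of orientations.  Identical seeds give identical coordinates.
    """
    if mode not in ("chelating", "monodentate", "nonbinding"):
        raise ValueError(f"unknown docking mode: {mode!r}")
    rec_hash = zlib.crc32(record.id.encode("utf-8"))  # stable across processes
    rng = np.random.default_rng([int(seed) % 2**31, rec_hash])
    mol, xyz = _conformer_coords(record, rng.integers(2**31))
    if mode in ("chelating", "monodentate"):
        i_carb, i_hydx = identify_chelators(mol)
    else:
        try:
            i_carb, i_hydx = identify_chelators(mol)
        except ValueError:
            i_carb, i_hydx = 0, 1  # any pair; distances are what matter
    zn = receptor.zinc
    prot = receptor.protein_coords()
    pocket_dir = zn - prot.mean(axis=0) if len(prot) else np.array([0.0, 0.0, 1.0])
    norm = np.linalg.norm(pocket_dir)
    e1 = pocket_dir / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    helper = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)

    a = float(np.linalg.norm(xyz[i_carb] - xyz[i_hydx]))
    if mode == "chelating":
        d1, d2 = rng.uniform(2.0, 2.3, size=2)
        d1, d2 = float(d1), float(d2)
        lo = abs(d1 - d2)
        if not (lo <= a <= d1 + d2):
            raise ValueError(
                f"chelating geometry infeasible for {record.id!r}: O-O distance {a:.2f} Å"
            )
    elif mode == "monodentate":
        d1 = float(rng.uniform(2.0, 2.3))
        d2 = float(np.clip(rng.uniform(3.0, 3.8), a - d1 + 0.05, a + d1 - 0.05))
        if d2 <= DEFAULT_CHELATION_CUTOFF:
            raise ValueError(f"monodentate geometry infeasible for {record.id!r}")
    else:  # nonbinding
        extent = float(np.linalg.norm(xyz - xyz.mean(axis=0), axis=1).max())
        shift = zn + (extent + 5.0 + rng.uniform(0, 2)) * e1 - xyz.mean(axis=0)
        coords = xyz + shift
        pose = DockedPose(record.id, coords, (i_carb, i_hydx), mol=mol)
        d_min = min(np.linalg.norm(coords[i_carb] - zn), np.linalg.norm(coords[i_hydx] - zn))
        if d_min <= 4.0:
            raise ValueError(f"nonbinding geometry infeasible for {record.id!r}")
        return pose

    p1, p2 = _two_sphere_point(zn, d1, d2, a, e1, e2)
    coords = _rigid_place(xyz, i_carb, i_hydx, p1, p2, prot, rng)
    return DockedPose(record.id, coords, (i_carb, i_hydx), mol=mol)


def _rigid_place(xyz, i1, i2, p1, p2, prot, rng, n_orientations: int = 12):
    """Rigidly place coordinates so atoms i1/i2 land on p1/p2 exactly, then
    pick the rotation about the p1-p2 axis with the fewest protein clashes."""
    from scipy.spatial.transform import Rotation

    v_src = xyz[i2] - xyz[i1]
    v_dst = p2 - p1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(v_dst[None, :], v_src[None, :])
    base = (xyz - xyz[i1]) @ rot.as_matrix().T + p1
    axis = v_dst / np.linalg.norm(v_dst)
    best_coords, best_pen = None, None
    for k in range(n_orientations):
        angle = 2 * np.pi * k / n_orientations
        spin = Rotation.from_rotvec(angle * axis)
        coords = (base - p1) @ spin.as_matrix().T + p1
        if len(prot):
            dmin = np.linalg.norm(coords[:, None, :] - prot[None, :, :], axis=2).min()
            pen = max(0.0, 1.5 - dmin)
        else:
            pen = 0.0
        if best_pen is None or pen < best_pen - 1e-12:
            best_coords, best_pen = coords, pen
        if pen == 0.0:
            break
    # re-pin the chelators exactly (spin preserves them, but guard numerics)
    return best_coords
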