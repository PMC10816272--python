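"""Trajectory analysis with the conventions of pose-stability studies:
backbone-fit superposition, RMSD/RMSF series, chelation-distance traces and
interaction-persistence fractions.

The portable trajectory format is multi-model PDB (read and written through
MDAnalysis); the analysis itself operates on plain arrays, so frames from
any reader can be supplied.  Protein RMSD is measured on backbone atoms,
ligand/zinc RMSD after fitting to the protein backbone, and flexible
termini can be excluded from the fit by residue range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import kabsch

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Default geometric criteria, following common simulation-suite conventions.
HBOND_MAX_HA = 2.5      # Å, hydrogen ... acceptor
HBOND_MIN_ANGLE = 120.0  # degrees, donor-H-acceptor
SALT_BRIDGE_MAX = 4.0    # Å, charged-group heavy atoms


@dataclass
class Trajectory:
    """Atom records plus a stack of coordinate frames (Å).

    ``atoms`` columns: name, resname, resid, element, role -- where role is
    one of protein/ligand/zinc/other; ``coords`` has shape
    ``(n_frames, n_atoms, 3)``; ``dt_ns`` is the frame spacing metadata.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    dt_ns: float = 0.1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("every frame must cover every atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    # -- I/O --------------------------------------------------------------
    def to_pdb(self, path) -> None:
        """Write as multi-model PDB."""
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        resids = self.atoms["resid"].to_numpy()
        # residue bookkeeping preserves file order (np.unique would sort)
        seen = {}
        atom_res = []
        for rid in resids:
            if rid not in seen:
                seen[rid] = len(seen)
            atom_res.append(seen[rid])
        n_res = len(seen)
        first_atom = {}
        for i, rid in enumerate(resids):
            first_atom.setdefault(rid, i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                self.n_atoms, n_residues=n_res, atom_resindex=np.array(atom_res),
                residue_segindex=np.zeros(n_res, dtype=int), trajectory=True,
            )
            u.add_TopologyAttr("names", self.atoms["name"].tolist())
            u.add_TopologyAttr(
                "resnames",
                [self.atoms["resname"].iloc[first_atom[r]] for r in seen],
            )
            u.add_TopologyAttr("resids", [int(r) for r in seen])
            u.add_TopologyAttr("elements", self.atoms["element"].tolist())
            u.load_new(self.coords.astype(np.float32), format=MemoryReader)
            with mda.Writer(str(path), self.n_atoms, multiframe=True) as writer:
                for _ in u.trajectory:
                    writer.write(u.atoms)

    @classmethod
    def from_pdb(cls, path, dt_ns: float = 0.1,
                 ligand_resnames: Sequence[str] = ("LIG", "UNL", "UNK")) -> "Trajectory":
        """Read a multi-model PDB (topology + frames)."""
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            atoms = pd.DataFrame(
                {
                    "name": u.atoms.names,
                    "resname": u.atoms.resnames,
                    "resid": u.atoms.resids,
                    "element": [e.capitalize() for e in u.atoms.elements],
                }
            )
            coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
        atoms["role"] = _assign_roles(atoms, ligand_resnames)
        return cls(atoms, coords, dt_ns)


def _assign_roles(atoms: pd.DataFrame, ligand_resnames=("LIG", "UNL", "UNK")) -> List[str]:
    roles = []
    for _, row in atoms.iterrows():
        if str(row["element"]).upper() == "ZN":
            roles.append("zinc")
        elif row["resname"] in ligand_resnames:
            roles.append("ligand")
        else:
            roles.append("protein")
    return roles


def make_trajectory(atoms: pd.DataFrame, coords: np.ndarray, dt_ns: float = 0.1,
                    ligand_resnames: Sequence[str] = ("LIG", "UNL", "UNK")) -> Trajectory:
    """Build a trajectory from raw atom records, assigning roles."""
    atoms = atoms.copy()
    if "role" not in atoms.columns:
        atoms["role"] = _assign_roles(atoms, ligand_resnames)
    return Trajectory(atoms, coords, dt_ns)


@dataclass(frozen=True)
class Selection:
    """Atom selection by role, with optional residue-range exclusion.

    ``role``: protein_backbone, protein, ligand, zinc, custom or all;
    ``exclude_resids``: inclusive ``(first, last)`` ranges dropped from the
    selection (used to exclude flexible termini from fits);
    ``indices``: explicit atom indices for ``role='custom'``.
    """

    role: str = "all"
    exclude_resids: Tuple[Tuple[int, int], ...] = ()
    indices: Tuple[int, ...] = ()

    def resolve(self, traj: Trajectory) -> np.ndarray:
        atoms = traj.atoms
        if self.role == "custom":
            idx = np.asarray(self.indices, dtype=int)
        elif self.role == "all":
            idx = np.arange(len(atoms))
        elif self.role == "protein_backbone":
            mask = (atoms["role"] == "protein") & atoms["name"].isin(BACKBONE_NAMES)
            idx = np.flatnonzero(mask.to_numpy())
        elif self.role in ("protein", "ligand", "zinc"):
            idx = np.flatnonzero((atoms["role"] == self.role).to_numpy())
        else:
            raise ValueError(f"unknown selection role: {self.role!r}")
        if self.exclude_resids:
            resids = atoms["resid"].to_numpy()[idx]
            keep = np.ones(len(idx), dtype=bool)
            for first, last in self.exclude_resids:
                keep &= ~((resids >= first) & (resids <= last))
            idx = idx[keep]
        if len(idx) == 0:
            raise ValueError(f"selection {self} resolves to zero atoms")
        return idx


def superpose(ref: np.ndarray, mob: np.ndarray):
    """Kabsch superposition of paired coordinates (proper rotation).

    Requires at least three non-collinear atoms; returns the rigid
    transform and the fit RMSD in Å.
    """
    return kabsch(ref, mob, require_noncollinear=True)


def rmsd_series(
    traj: Trajectory,
    fit_selection: Selection,
    measure_selection: Selection,
    reference: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after fitting each frame to
    the reference (default: frame 0) on ``fit_selection``."""
    fit_idx = fit_selection.resolve(traj)
    mea_idx = measure_selection.resolve(traj)
    ref = traj.coords[0] if reference is None else np.asarray(reference, float)
    ref_fit = ref[fit_idx]
    ref_mea = ref[mea_idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        transform, _ = superpose(ref_fit, traj.coords[f][fit_idx])
        moved = transform.apply(traj.coords[f][mea_idx])
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_mea) ** 2, axis=1)))
    return out


def rmsf(
    traj: Trajectory,
    selection: Selection,
    fit_selection: Optional[Selection] = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-average position,
    after per-frame fitting on ``fit_selection`` (no fitting when None)."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = selection.resolve(traj)
    if fit_selection is not None:
        fit_idx = fit_selection.resolve(traj)
        ref_fit = traj.coords[0][fit_idx]
        stack = np.empty((traj.n_frames, len(idx), 3))
        for f in range(traj.n_frames):
            transform, _ = superpose(ref_fit, traj.coords[f][fit_idx])
            stack[f] = transform.apply(traj.coords[f][idx])
    else:
        stack = traj.coords[:, idx, :]
    mean_pos = stack.mean(axis=0)
    return np.sqrt(np.mean(np.sum((stack - mean_pos) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# Interaction persistence
# ---------------------------------------------------------------------------

AtomSelector = Union[int, Tuple[int, str]]


@dataclass(frozen=True)
class InteractionSpec:
    """Geometric interaction criteria evaluated per frame.

    kinds: ``hbond`` (participants donor, hydrogen, acceptor; criteria
    ``max_distance`` H...acceptor and ``min_angle`` donor-H-acceptor),
    ``salt_bridge`` (participants a, b; ``max_distance``) and ``distance``
    (participants a, b; user ``max_distance`` -- chelation traces use the
    chelation cutoff).  Atom selectors are indices or ``(resid, name)``.
    """

    name: str
    kind: str
    participants: Tuple[Tuple[str, AtomSelector], ...]
    max_distance: Optional[float] = None
    min_angle: Optional[float] = None

    def _participant(self, role: str) -> AtomSelector:
        for key, sel in self.participants:
            if key == role:
                return sel
        raise ValueError(f"interaction {self.name!r} lacks participant {role!r}")


def _resolve_atom(traj: Trajectory, sel: AtomSelector) -> int:
    if isinstance(sel, (int, np.integer)):
        if not 0 <= sel < traj.n_atoms:
            raise ValueError(f"atom index {sel} out of range")
        return int(sel)
    resid, name = sel
    mask = (traj.atoms["resid"] == resid) & (traj.atoms["name"] == name)
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) != 1:
        raise ValueError(
            f"selector (resid={resid}, name={name!r}) resolves to {len(idx)} atoms"
        )
    return int(idx[0])


def interaction_mask(traj: Trajectory, spec: InteractionSpec) -> np.ndarray:
    """Boolean per-frame mask of the interaction's geometric criteria."""
    if spec.kind == "hbond":
        d = _resolve_atom(traj, spec._participant("donor"))
        h = _resolve_atom(traj, spec._participant("hydrogen"))
        a = _resolve_atom(traj, spec._participant("acceptor"))
        max_d = spec.max_distance if spec.max_distance is not None else HBOND_MAX_HA
        min_a = spec.min_angle if spec.min_angle is not None else HBOND_MIN_ANGLE
        ha = np.linalg.norm(traj.coords[:, a] - traj.coords[:, h], axis=1)
        v1 = traj.coords[:, d] - traj.coords[:, h]
        v2 = traj.coords[:, a] - traj.coords[:, h]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return (ha <= max_d) & (angles >= min_a)
    if spec.kind in ("salt_bridge", "distance"):
        a = _resolve_atom(traj, spec._participant("a"))
        b = _resolve_atom(traj, spec._participant("b"))
        if spec.kind == "salt_bridge":
            max_d = spec.max_distance if spec.max_distance is not None else SALT_BRIDGE_MAX
        else:
            if spec.max_distance is None:
                raise ValueError(f"distance interaction {spec.name!r} needs max_distance")
            max_d = spec.max_distance
        dist = np.linalg.norm(traj.coords[:, a] - traj.coords[:, b], axis=1)
        return dist <= max_d
    raise ValueError(f"unknown interaction kind: {spec.kind!r}")


def persistence(traj: Trajectory, spec: InteractionSpec) -> float:
    """Fraction of frames in which the interaction's criteria all hold."""
    mask = interaction_mask(traj, spec)
    return float(mask.sum()) / traj.n_frames


def distance_series(traj: Trajectory, a: AtomSelector, b: AtomSelector) -> np.ndarray:
    """Per-frame distance between two atoms (e.g. chelator oxygen to zinc)."""
    ia, ib = _resolve_atom(traj, a), _resolve_atom(traj, b)
    return np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)


@dataclass
class TrajectorySummary:
    """Bundle of analysis products: RMSD/distance series (per name), RMSF
    per atom, and interaction persistences as fractions in [0, 1]."""

    rmsd: Dict[str, np.ndarray] = field(default_factory=dict)
    rmsf: Dict[str, np.ndarray] = field(default_factory=dict)
    distances: Dict[str, np.ndarray] = field(default_factory=dict)
    persistence: Dict[str, float] = field(default_factory=dict)

    def save_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for group in ("rmsd", "distances"):
            for name, series in getattr(self, group).items():
                pd.DataFrame({"frame": np.arange(len(series)), "value": series}).to_csv(
                    out / f"{group}_{name}.csv", index=False
                )
        if self.persistence:
            rows = [
                {"interaction": k, "fraction": v, "percent": 100.0 * v}
                for k, v in self.persistence.items()
            ]
            pd.DataFrame(rows).to_csv(out / "persistence.csv", index=False)


def load_interaction_specs(path) -> List[InteractionSpec]:
    """Read interaction specs from YAML: a list of mappings with keys
    name, kind, participants ({role: index | [resid, name]}), and optional
    max_distance / min_angle."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for item in raw:
        participants = tuple(
            (role, tuple(sel) if isinstance(sel, (list, tuple)) else int(sel))
            for role, sel in item["participants"].items()
        )
        specs.append(
            InteractionSpec(
                name=item["name"],
                kind=item["kind"],
                participants=participants,
                max_distance=item.get("max_distance"),
                min_angle=item.get("min_angle"),
            )
        )
    return specs


def summarize(
    traj: Trajectory,
    specs: Sequence[InteractionSpec] = (),
    exclude_termini: Tuple[Tuple[int, int], ...] = (),
) -> TrajectorySummary:
    """Standard pose-stability summary: backbone-fit protein RMSD (termini
    excluded from the fit when requested), ligand and zinc RMSD fit to the
    backbone, ligand-heavy-atom RMSF, and interaction persistences."""
    backbone = Selection("protein_backbone", exclude_resids=tuple(exclude_termini))
    summary = TrajectorySummary()
    summary.rmsd["protein_backbone"] = rmsd_series(traj, backbone, backbone)
    for role in ("ligand", "zinc"):
        try:
            sel = Selection(role)
            sel.resolve(traj)
        except ValueError:
            continue
        summary.rmsd[role] = rmsd_series(traj, backbone, sel)
    try:
        lig = Selection("ligand")
        if traj.n_frames >= 2:
            summary.rmsf["ligand"] = rmsf(traj, lig, backbone)
    except ValueError:
        pass
    for spec in specs:
        summary.persistence[spec.name] = persistence(traj, spec)
    return summary
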