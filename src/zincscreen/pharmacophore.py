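"""Structure-based pharmacophore hypotheses and multi-conformer screening.

A hypothesis is a set of typed feature points (acceptor, donor, negative,
positive, aromatic, hydrophobic) with spherical tolerances, plus excluded
volumes marking protein-occupied space.  A ligand conformer matches when a
kind-compatible assignment of its perceived features to the hypothesis
features exists whose rigid-body least-squares alignment puts every anchor
within its feature's tolerance while no ligand heavy atom enters an
excluded volume.  At most one result -- the lowest-fit conformer and
assignment -- is reported per ligand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from rdkit import Chem

from .geometry import kabsch
from .records import MoleculeRecord

FEATURE_KINDS = ("acceptor", "donor", "negative", "positive", "aromatic", "hydrophobic")

#: Defaults for hypothesis construction; all three are config keys.
DEFAULT_TOLERANCE = 1.5      # Å, feature sphere radius
DEFAULT_VOLUME_RADIUS = 1.2  # Å, excluded-volume sphere radius
DEFAULT_SHELL_DISTANCE = 5.0  # Å, receptor shell captured as excluded volumes


@dataclass(frozen=True)
class Feature:
    kind: str
    center: tuple  # (x, y, z) Å
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))


@dataclass(frozen=True)
class ExcludedVolume:
    center: tuple
    radius: float = DEFAULT_VOLUME_RADIUS

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("excluded-volume radius must be positive")
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))


@dataclass
class PharmacophoreHypothesis:
    """The screening query: features + excluded volumes.

    ``required_count`` defaults to all features (full-match screening).
    """

    features: List[Feature]
    volumes: List[ExcludedVolume] = field(default_factory=list)
    required_count: Optional[int] = None

    def __post_init__(self):
        if self.required_count is None:
            self.required_count = len(self.features)
        if self.required_count > len(self.features):
            raise ValueError("required_count exceeds the number of features")

    # -- serialization (YAML; JSON-compatible structure) ------------------
    def to_dict(self) -> dict:
        return {
            "features": [
                {"kind": f.kind, "center": list(f.center), "tolerance": f.tolerance}
                for f in self.features
            ],
            "volumes": [
                {"center": list(v.center), "radius": v.radius} for v in self.volumes
            ],
            "required_count": self.required_count,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PharmacophoreHypothesis":
        return cls(
            features=[
                Feature(d["kind"], tuple(d["center"]), float(d["tolerance"]))
                for d in data["features"]
            ],
            volumes=[
                ExcludedVolume(tuple(d["center"]), float(d["radius"]))
                for d in data.get("volumes", [])
            ],
            required_count=data.get("required_count"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, default_flow_style=None)

    @classmethod
    def load(cls, path) -> "PharmacophoreHypothesis":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PerceivedFeature:
    """A feature site found on a ligand conformer: kind + anchor point."""

    kind: str
    anchor: tuple
    atoms: tuple  # contributing atom indices (ring atoms for aromatic)


@dataclass(frozen=True)
class MatchResult:
    ligand_id: str
    conformer: int
    assignment: tuple  # per hypothesis feature: the PerceivedFeature assigned
    fit_rmsd: float


@lru_cache(maxsize=1)
def _feature_queries() -> Dict[str, tuple]:
    text = resources.files("zincscreen.data").joinpath("perception.yaml").read_text()
    cfg = yaml.safe_load(text)["features"]
    return {
        kind: tuple(Chem.MergeQueryHs(Chem.MolFromSmarts(s)) for s in patterns)
        for kind, patterns in cfg.items()
    }


def perceive_features(mol: Chem.Mol, conf_id: int = 0) -> List[PerceivedFeature]:
    """Locate pharmacophore feature sites on one conformer.

    Point features sit on the first matched heavy atom of the perception
    SMARTS; aromatic features sit on ring centroids.  Deterministic: sites
    follow RDKit match order, deduplicated per (kind, anchor atom).
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("feature perception requires 3D coordinates")
    pos = mol.GetConformer(conf_id).GetPositions()
    found: List[PerceivedFeature] = []
    seen = set()
    for kind, queries in _feature_queries().items():
        for query in queries:
            for match in mol.GetSubstructMatches(query):
                anchor_idx = match[0]
                key = (kind, anchor_idx)
                if key in seen:
                    continue
                seen.add(key)
                found.append(
                    PerceivedFeature(kind, tuple(pos[anchor_idx]), (anchor_idx,))
                )
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid = pos[list(ring)].mean(axis=0)
            found.append(PerceivedFeature("aromatic", tuple(centroid), tuple(ring)))
    return found


def build_hypothesis(
    ligand: Chem.Mol,
    protein_coords: np.ndarray,
    feature_picks: Sequence[str],
    shell_distance: float = DEFAULT_SHELL_DISTANCE,
    tolerance: float = DEFAULT_TOLERANCE,
    volume_radius: float = DEFAULT_VOLUME_RADIUS,
    conf_id: int = 0,
) -> PharmacophoreHypothesis:
    """Derive a hypothesis from a bound ligand pose and its receptor.

    Features are placed at the picked perceived anchors of the ligand pose;
    one excluded volume is placed on every protein heavy atom within
    ``shell_distance`` of any ligand heavy atom, except volumes that would
    engulf a feature center.  Ligand pose and protein must share one
    coordinate frame.
    """
    perceived = perceive_features(ligand, conf_id)
    pool: Dict[str, list] = {}
    for pf in perceived:
        pool.setdefault(pf.kind, []).append(pf)
    features = []
    for kind in feature_picks:
        if not pool.get(kind):
            raise ValueError(f"picked feature {kind!r} is absent from the ligand pose")
        pf = pool[kind].pop(0)
        features.append(Feature(kind, pf.anchor, tolerance))

    lig_xyz = ligand.GetConformer(conf_id).GetPositions()
    volumes = []
    protein_coords = np.asarray(protein_coords, float).reshape(-1, 3)
    if protein_coords.size:
        dists = np.linalg.norm(
            protein_coords[:, None, :] - lig_xyz[None, :, :], axis=2
        ).min(axis=1)
        centers = np.array([f.center for f in features])
        for coord, d in zip(protein_coords, dists):
            if d > shell_distance:
                continue
            if np.linalg.norm(centers - coord, axis=1).min() <= volume_radius:
                continue
            volumes.append(ExcludedVolume(tuple(coord), volume_radius))
    return PharmacophoreHypothesis(features, volumes)


def _clashes(coords: np.ndarray, volumes: Sequence[ExcludedVolume]) -> bool:
    for vol in volumes:
        if np.linalg.norm(coords - np.asarray(vol.center), axis=1).min() < vol.radius:
            return True
    return False


def _evaluate_assignment(
    hypothesis: PharmacophoreHypothesis,
    assignment: Sequence[PerceivedFeature],
    heavy_xyz: np.ndarray,
) -> Optional[float]:
    """Rigid-align assigned anchors onto feature centers; return fit RMSD or
    None when a tolerance or excluded-volume constraint fails."""
    centers = np.array([f.center for f in hypothesis.features])
    anchors = np.array([pf.anchor for pf in assignment])
    transform, fit = kabsch(centers, anchors)
    aligned_anchors = transform.apply(anchors)
    devs = np.linalg.norm(aligned_anchors - centers, axis=1)
    for dev, feat in zip(devs, hypothesis.features):
        if dev > feat.tolerance:
            return None
    if hypothesis.volumes and _clashes(transform.apply(heavy_xyz), hypothesis.volumes):
        return None
    return fit


def _search_assignments(hypothesis, perceived, heavy_xyz):
    """Backtracking search over kind-compatible injective assignments with a
    pairwise-distance prune (rigid alignment preserves distances, so
    |d_lig - d_hyp| > tol_i + tol_j rules a pair out)."""
    feats = hypothesis.features
    centers = [np.asarray(f.center) for f in feats]
    by_kind: Dict[str, list] = {}
    for pf in perceived:
        by_kind.setdefault(pf.kind, []).append(pf)
    best: List[Optional[float]] = [None]
    best_assign: List[Optional[tuple]] = [None]

    order = sorted(range(len(feats)), key=lambda i: len(by_kind.get(feats[i].kind, [])))
    assign: List[Optional[PerceivedFeature]] = [None] * len(feats)
    used = set()

    def backtrack(depth: int):
        if depth == len(order):
            fit = _evaluate_assignment(hypothesis, assign, heavy_xyz)
            if fit is not None and (best[0] is None or fit < best[0]):
                best[0] = fit
                best_assign[0] = tuple(assign)
            return
        i = order[depth]
        for pf in by_kind.get(feats[i].kind, []):
            if id(pf) in used:
                continue
            ok = True
            for j in order[:depth]:
                d_hyp = np.linalg.norm(centers[i] - centers[j])
                d_lig = np.linalg.norm(
                    np.asarray(pf.anchor) - np.asarray(assign[j].anchor)
                )
                if abs(d_lig - d_hyp) > feats[i].tolerance + feats[j].tolerance:
                    ok = False
                    break
            if not ok:
                continue
            assign[i] = pf
            used.add(id(pf))
            backtrack(depth + 1)
            used.discard(id(pf))
            assign[i] = None

    backtrack(0)
    return best[0], best_assign[0]


def _generate_conformers(record: MoleculeRecord, n: int, seed: int) -> Chem.Mol:
    """Deterministic ETKDG conformer ensemble for records supplied without
    3D coordinates; the seed derives from the record id so library order
    cannot change any ligand's conformers."""
    import zlib

    from rdkit.Chem import AllChem

    molh = Chem.AddHs(Chem.Mol(record.mol))
    conf_seed = (seed + zlib.crc32(record.id.encode("utf-8"))) % (2**31 - 1)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(conf_seed)
    AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    return Chem.RemoveHs(molh)


def match(
    record: MoleculeRecord,
    hypothesis: PharmacophoreHypothesis,
    max_conformers: int = 50,
    conformer_seed: int = 0,
) -> Optional[MatchResult]:
    """Screen one multi-conformer ligand against a hypothesis.

    Up to ``max_conformers`` conformers are considered; the accepted
    assignment with the lowest fit RMSD across conformers wins, ties going
    to the lowest conformer index.  Records without conformers get a
    seeded ETKDG ensemble.  Returns None when no conformer matches.
    """
    if not hypothesis.features:
        raise ValueError("hypothesis has zero features")
    mol = record.mol
    if mol.GetNumConformers() == 0:
        mol = _generate_conformers(record, max_conformers, conformer_seed)
    n_conf = min(mol.GetNumConformers(), max_conformers)
    if n_conf == 0:
        raise ValueError(f"record {record.id!r} has no conformers to match")
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    best: Optional[MatchResult] = None
    for ci in range(n_conf):
        perceived = perceive_features(mol, ci)
        heavy_xyz = mol.GetConformer(ci).GetPositions()[heavy]
        fit, assign = _search_assignments(hypothesis, perceived, heavy_xyz)
        if fit is None:
            continue
        if best is None or fit < best.fit_rmsd - 1e-12:
            best = MatchResult(record.id, ci, assign, fit)
    return best


def screen(
    records: Sequence[MoleculeRecord],
    hypothesis: PharmacophoreHypothesis,
    max_conformers: int = 50,
    conformer_seed: int = 0,
) -> Tuple[List[MoleculeRecord], Dict[str, MatchResult]]:
    """Screen a library; survivors are exactly the records with a match."""
    survivors, results = [], {}
    for rec in records:
        res = match(rec, hypothesis, max_conformers, conformer_seed)
        if res is not None:
            survivors.append(rec)
            results[rec.id] = res
    return survivors, results
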