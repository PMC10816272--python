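"""Labelled synthetic inputs for every funnel stage.

The generators emulate the statistical structure the screening pipeline
assumes -- a ligand library with planted fractions of benzohydroxamates,
anionic states, rule-of-five violators, pharmacophore matchers and
alert-bearing compounds; a pocket defined by a zinc position, pharmacophore
anchors and excluded volumes; docked poses with controllable chelator-zinc
distances; and trajectories with exactly realized interaction persistences.
Everything is deterministic under a fixed seed and ships machine-readable
ground truth, and every planted positive/negative is verified by the
corresponding filter at generation time.

Planted subset sizes use round-half-up of ``n * fraction`` so tests can
assert exact counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from . import filters
from .funnel import (
    RULE_BIDENTATE,
    RULE_BIDENTATE_OR_MONO,
    FunnelConfig,
)
from .md import InteractionSpec, Trajectory, interaction_mask, make_trajectory
from .pharmacophore import (
    DEFAULT_TOLERANCE,
    DEFAULT_VOLUME_RADIUS,
    ExcludedVolume,
    Feature,
    PharmacophoreHypothesis,
    match,
)
from .poses import (
    ChelationClass,
    DockedPose,
    ReceptorContext,
    assess_chelation,
    identify_chelators,
    mock_dock,
)
from .records import MoleculeRecord, StateTag


def round_half_up(x: float) -> int:
    """Planted-count rounding rule."""
    return int(math.floor(x + 0.5))


@lru_cache(maxsize=1)
def scaffold_pools() -> dict:
    text = resources.files("zincscreen.data").joinpath("scaffolds.yaml").read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Pocket generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPocket:
    """A generated binding pocket: receptor context, screening hypothesis,
    the planted template ligand pose, and recorded ground truth."""

    receptor: ReceptorContext
    hypothesis: PharmacophoreHypothesis
    template: MoleculeRecord           # conformer in the pocket frame
    chelator_pair: Tuple[int, int]
    ground_truth: dict

    def template_pose(self) -> DockedPose:
        coords = self.template.mol.GetConformer().GetPositions()
        return DockedPose(self.template.id, coords, self.chelator_pair)


def _embed(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=seed % (2**31 - 1)) != 0:
        raise RuntimeError(f"conformer embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(molh)
    return Chem.RemoveHs(molh)


def _cap_ring_centroid(mol: Chem.Mol, anion_idx: int) -> np.ndarray:
    """Centroid of the aromatic ring farthest from the anionic oxygen (the
    capping ring, as opposed to the hydroxamate's own benzo ring)."""
    pos = mol.GetConformer().GetPositions()
    best, best_d = None, -1.0
    for ring in mol.GetRingInfo().AtomRings():
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        centroid = pos[list(ring)].mean(axis=0)
        d = float(np.linalg.norm(centroid - pos[anion_idx]))
        if d > best_d:
            best, best_d = centroid, d
    if best is None:
        raise RuntimeError("template has no aromatic ring")
    return best


def gen_pocket(
    seed: int = 0,
    label: str = "HDAC11",
    n_shell_atoms: int = 12,
    shell_radius: float = 4.0,
    zinc_distance: float = 2.2,
    tolerance: float = DEFAULT_TOLERANCE,
    volume_radius: float = DEFAULT_VOLUME_RADIUS,
) -> SyntheticPocket:
    """Generate a synthetic zinc pocket with a planted chelating pose.

    The template (an ortho-methoxy benzohydroxamate anion with a
    benzyloxy-phenyl cap) is embedded, the zinc is placed equidistant
    (``zinc_distance``) from both chelator oxygens, and ``n_shell_atoms``
    pseudo protein atoms are scattered on a hemisphere behind the zinc.
    The hypothesis carries the four anchor features (acceptor at the
    carbonyl O, donor at the N-H, negative at the anionic O, aromatic at
    the cap-ring centroid) plus one excluded volume per shell atom.
    """
    rng = np.random.default_rng([seed % 2**31, 0xB10C])
    pools = scaffold_pools()
    template_smiles = pools["matchers"][0]
    mol = _embed(template_smiles, int(rng.integers(1, 2**31 - 1)))
    i_carb, i_anion = identify_chelators(mol)
    pos = mol.GetConformer().GetPositions()
    o1, o2 = pos[i_carb], pos[i_anion]
    mid = (o1 + o2) / 2.0
    a_half = np.linalg.norm(o2 - o1) / 2.0
    if zinc_distance <= a_half:
        raise ValueError("zinc_distance shorter than half the O-O separation")
    height = float(np.sqrt(zinc_distance**2 - a_half**2))
    away = mid - pos.mean(axis=0)
    axis = o2 - o1
    axis /= np.linalg.norm(axis)
    perp = away - np.dot(away, axis) * axis
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    zinc = mid + height * perp

    # pseudo protein shell: hemisphere behind the zinc
    e1 = zinc - pos.mean(axis=0)
    e1 /= np.linalg.norm(e1)
    shell = []
    while len(shell) < n_shell_atoms:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if np.dot(v, e1) >= 0.5:
            shell.append(zinc + shell_radius * v)
    shell = np.asarray(shell)

    names = ["N", "CA", "C", "O"]
    rows = []
    for i, coord in enumerate(shell):
        rows.append(
            {
                "serial": i + 1,
                "name": names[i % 4],
                "resname": "GLY",
                "chain": "A",
                "resnum": i // 4 + 1,
                "element": names[i % 4][0],
                "x": coord[0], "y": coord[1], "z": coord[2],
            }
        )
    receptor = ReceptorContext(label=label, atoms=pd.DataFrame(rows), zinc=zinc)

    # hypothesis anchors from the template pose
    query = filters._anion_query(filters.HYDROXAMATE_ANION_SMARTS)
    m = mol.GetSubstructMatch(query)
    anchor_anion, anchor_n, anchor_carb = pos[m[0]], pos[m[1]], pos[m[3]]
    cap = _cap_ring_centroid(mol, m[0])
    features = [
        Feature("acceptor", tuple(anchor_carb), tolerance),
        Feature("donor", tuple(anchor_n), tolerance),
        Feature("negative", tuple(anchor_anion), tolerance),
        Feature("aromatic", tuple(cap), tolerance),
    ]
    centers = np.array([f.center for f in features])
    volumes = [
        ExcludedVolume(tuple(c), volume_radius)
        for c in shell
        if np.linalg.norm(centers - c, axis=1).min() > volume_radius
    ]
    hypothesis = PharmacophoreHypothesis(features, volumes)

    record = MoleculeRecord(f"{label}-template", mol, StateTag.HYDROXAMATE_ANION)
    pocket = SyntheticPocket(
        receptor=receptor,
        hypothesis=hypothesis,
        template=record,
        chelator_pair=(i_carb, i_anion),
        ground_truth={
            "zinc": zinc.tolist(),
            "shell": shell.tolist(),
            "template_smiles": template_smiles,
        },
    )
    # self-checks: the planted pose chelates bidentately and matches the query
    assessment = assess_chelation(pocket.template_pose(), receptor)
    if assessment.cls != ChelationClass.BIDENTATE:
        raise RuntimeError("generated pocket failed its bidentate self-check")
    if match(record, hypothesis) is None:
        raise RuntimeError("generated pocket template fails its own hypothesis")
    return pocket


def write_pocket_pdb(pocket: SyntheticPocket, path) -> None:
    """Write the pocket (pseudo protein + zinc) as a single-model PDB."""
    atoms = pocket.receptor.atoms
    rows = pd.DataFrame(
        {
            "name": list(atoms["name"]) + ["ZN"],
            "resname": list(atoms["resname"]) + ["ZN"],
            "resid": list(atoms["resnum"]) + [int(atoms["resnum"].max()) + 1],
            "element": list(atoms["element"]) + ["Zn"],
        }
    )
    coords = np.vstack([atoms[["x", "y", "z"]].to_numpy(), pocket.receptor.zinc])
    make_trajectory(rows, coords[None, :, :]).to_pdb(path)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

DEFAULT_CHELATION = {
    "HDAC11": {"bidentate": 0.7, "monodentate": 0.2},
    "HDAC1": {"undocked": 0.5, "bidentate": 0.1},
    "HDAC6": {"bidentate": 0.06, "monodentate": 0.1},
    "HDAC8": {"bidentate": 0.1},
}

DEFAULT_RULES = {
    "HDAC1": RULE_BIDENTATE,
    "HDAC6": RULE_BIDENTATE_OR_MONO,
    "HDAC8": RULE_BIDENTATE,
}


@dataclass
class LibrarySpec:
    """Composition of a synthetic screening library.

    All fractions are of ``n`` (round-half-up counts) and nest:
    anionic ⊆ benzohydroxamate, violators ⊆ anionic, matchers ⊆ anionic
    minus violators, alert bearers ⊆ comparative-elimination survivors.
    ``chelation`` maps receptor -> class fractions over the matcher set;
    the key ``undocked`` marks ligands that fail to dock in that receptor
    (and therefore cannot trigger its elimination rule).
    """

    n: int = 200
    f_benzohydroxamate: float = 0.5
    f_anionic: float = 0.35
    f_ro5_violator: float = 0.05
    f_matcher: float = 0.25
    f_alert: float = 0.02
    chelation: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHELATION.items()}
    )
    target: str = "HDAC11"
    rules: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_RULES))
    top_k: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("f_benzohydroxamate", "f_anionic", "f_ro5_violator",
                     "f_matcher", "f_alert"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        for receptor, dist in self.chelation.items():
            total = sum(dist.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"chelation fractions for {receptor!r} exceed 1")
        if self.target not in self.chelation:
            raise ValueError("chelation table lacks the target receptor")

    @property
    def counts(self) -> dict:
        n_b = round_half_up(self.n * self.f_benzohydroxamate)
        n_a = round_half_up(self.n * self.f_anionic)
        n_v = round_half_up(self.n * self.f_ro5_violator)
        n_m = round_half_up(self.n * self.f_matcher)
        n_alert = round_half_up(self.n * self.f_alert)
        if n_b > self.n or n_a > n_b or n_v > n_a or n_m > n_a - n_v:
            raise ValueError(
                f"infeasible nested fractions: n={self.n}, benzo={n_b}, "
                f"anionic={n_a}, violators={n_v}, matchers={n_m}"
            )
        return {"benzo": n_b, "anionic": n_a, "violator": n_v,
                "matcher": n_m, "alert": n_alert}


@dataclass
class GroundTruth:
    """Machine-readable planted truth: the per-stage expected survivor id
    sets, the per-ligand label table, and the expected final ranking."""

    expected_survivors: Dict[str, frozenset]
    labels: pd.DataFrame
    expected_ranking: List[Tuple[str, float]]

    def expected_counts(self) -> Dict[str, int]:
        return {k: len(v) for k, v in self.expected_survivors.items()}

    def save(self, path) -> None:
        payload = {
            "expected_survivors": {k: sorted(v) for k, v in self.expected_survivors.items()},
            "expected_ranking": [{"id": i, "score": s} for i, s in self.expected_ranking],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _core_conformer(pocket: SyntheticPocket) -> Chem.Mol:
    """The shared matcher core with the template's pocket-frame geometry."""
    core = Chem.MolFromSmiles(scaffold_pools()["matcher_core"])
    tmpl = pocket.template.mol
    mcs_match = tmpl.GetSubstructMatch(core)
    if not mcs_match:
        raise RuntimeError("template does not contain the matcher core")
    conf = Chem.Conformer(core.GetNumAtoms())
    tpos = tmpl.GetConformer().GetPositions()
    for core_idx, tmpl_idx in enumerate(mcs_match):
        conf.SetAtomPosition(core_idx, tpos[tmpl_idx].tolist())
    core.AddConformer(conf, assignId=True)
    return core


def _constrained_embed(smiles: str, core: Chem.Mol, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    last = None
    for attempt in range(5):
        try:
            AllChem.ConstrainedEmbed(mol, core, randomseed=(seed + attempt) % (2**31 - 1))
            return Chem.RemoveHs(mol)
        except ValueError as exc:  # embedding failure
            last = exc
    raise RuntimeError(f"constrained embedding failed for {smiles!r}: {last}")


def _assign_classes(rng, n_m: int, dist: Mapping[str, float]):
    """Planted chelation classes for one receptor over the matcher set."""
    order = rng.permutation(n_m)
    classes = np.array(["none"] * n_m, dtype=object)
    pos = 0
    for cls, frac in dist.items():
        k = round_half_up(n_m * frac)
        classes[order[pos:pos + k]] = cls
        pos += k
    return classes


def gen_library(
    spec: LibrarySpec,
    pocket: Optional[SyntheticPocket] = None,
    self_check: bool = True,
) -> Tuple[List[MoleculeRecord], GroundTruth]:
    """Generate a labelled library realizing the spec's planted fractions.

    With a pocket supplied, matcher records receive a conformer whose core
    matches the pocket template geometry (so the pharmacophore stage
    recovers exactly the planted matcher set) and non-matching anions
    receive an unconstrained conformer.  Self-checks verify every planted
    label against the corresponding filter and raise on any mismatch.
    """
    counts = spec.counts
    rng = np.random.default_rng([spec.seed % 2**31, 0x5EED])
    pools = scaffold_pools()
    n = spec.n
    n_b, n_a, n_v, n_m = counts["benzo"], counts["anionic"], counts["violator"], counts["matcher"]
    n_alert = counts["alert"]

    # per-category scaffold assignments (cycled through the pools)
    def take(pool_name: str, k: int) -> List[str]:
        pool = pools[pool_name]
        return [pool[i % len(pool)] for i in range(k)]

    categories: List[Tuple[str, str]] = []  # (category, smiles)
    categories += [("decoy", s) for s in take("decoys", n - n_b)]
    categories += [("neutral", s) for s in take("neutral_benzohydroxamates", n_b - n_a)]
    categories += [("plain_anion", s) for s in take("anionic_plain", n_a - n_v - n_m)]
    categories += [("violator", s) for s in take("ro5_violators", n_v)]
    categories += [("matcher", s) for s in take("matchers", n_m)]

    order = rng.permutation(len(categories))
    categories = [categories[i] for i in order]
    ids = [f"mol-{i:04d}" for i in range(1, n + 1)]

    # planted chelation classes over the matcher set; reshuffle (bounded)
    # until enough comparative survivors exist to host the alert bearers
    matcher_slots = [i for i, (cat, _) in enumerate(categories) if cat == "matcher"]
    for attempt in range(32):
        sub = np.random.default_rng([spec.seed % 2**31, 0xC1A55, attempt])
        classes = {
            receptor: _assign_classes(sub, n_m, dist)
            for receptor, dist in spec.chelation.items()
        }
        target_bid = [
            j for j in range(n_m)
            if classes[spec.target][j] == ChelationClass.BIDENTATE.value
        ]
        survivors = []
        for j in target_bid:
            removed = False
            for receptor, rule in spec.rules.items():
                cls = classes.get(receptor, np.array(["none"] * n_m))[j]
                if cls == "undocked":
                    continue
                if cls == "bidentate" or (
                    rule == RULE_BIDENTATE_OR_MONO and cls == "monodentate"
                ):
                    removed = True
                    break
            if not removed:
                survivors.append(j)
        if len(survivors) >= n_alert:
            break
    else:
        raise ValueError(
            f"cannot plant {n_alert} alert bearers among "
            f"{len(survivors)} comparative survivors; adjust the spec"
        )

    alert_matcher_js = set(
        int(j) for j in np.asarray(survivors)[
            np.random.default_rng([spec.seed % 2**31, 0xA1E7]).permutation(len(survivors))[:n_alert]
        ]
    )
    alert_pool = pools["alert_matchers"]
    for k, j in enumerate(sorted(alert_matcher_js)):
        categories[matcher_slots[j]] = ("matcher", alert_pool[k % len(alert_pool)])

    core = _core_conformer(pocket) if pocket is not None else None
    embed_seed = int(rng.integers(1, 2**31 - 1))

    records: List[MoleculeRecord] = []
    label_rows = []
    matcher_counter = 0
    for idx, (rec_id, (cat, smiles)) in enumerate(zip(ids, categories)):
        labels: dict = {
            "benzohydroxamate": cat in ("neutral", "plain_anion", "violator", "matcher"),
            "anionic": cat in ("plain_anion", "violator", "matcher"),
            "ro5_violator": cat == "violator",
            "matcher": cat == "matcher",
            "alert": False,
            "chelation": {},
            "score": float(np.round(rng.uniform(-65.0, -35.0), 3)),
        }
        if cat == "matcher":
            j = matcher_counter
            matcher_counter += 1
            labels["alert"] = j in alert_matcher_js
            labels["chelation"] = {
                receptor: classes[receptor][j] for receptor in classes
            }
        rec = MoleculeRecord.from_smiles(rec_id, smiles, labels=labels)
        if cat == "matcher" and core is not None:
            rec.mol = _constrained_embed(smiles, core, embed_seed + idx)
        elif cat == "plain_anion" and pocket is not None:
            rec.mol = _embed(smiles, embed_seed + idx)
        records.append(rec)
        label_rows.append({"id": rec_id, "category": cat, "smiles": smiles, **{
            k: v for k, v in labels.items() if k not in ("chelation",)
        }})

    truth = _ground_truth(spec, records)
    if self_check:
        _self_check(spec, records, pocket)
    return records, truth


def _ground_truth(spec: LibrarySpec, records: Sequence[MoleculeRecord]) -> GroundTruth:
    by = lambda key: frozenset(r.id for r in records if r.labels.get(key))
    benzo, anion = by("benzohydroxamate"), by("anionic")
    ro5_pass = frozenset(
        r.id for r in records if r.labels.get("anionic") and not r.labels.get("ro5_violator")
    )
    matchers = by("matcher")
    docked = frozenset(
        r.id for r in records
        if r.labels.get("matcher")
        and r.labels["chelation"].get(spec.target, "undocked") != "undocked"
    )
    target_bid = frozenset(
        r.id for r in records
        if r.id in docked and r.labels["chelation"][spec.target] == "bidentate"
    )
    comparative = []
    for r in records:
        if r.id not in target_bid:
            continue
        removed = False
        for receptor, rule in spec.rules.items():
            cls = r.labels["chelation"].get(receptor, "none")
            if cls == "undocked":
                continue
            if cls == "bidentate" or (
                rule == RULE_BIDENTATE_OR_MONO and cls == "monodentate"
            ):
                removed = True
                break
        if not removed:
            comparative.append(r.id)
    comparative = frozenset(comparative)
    alert_pass = frozenset(
        r.id for r in records if r.id in comparative and not r.labels.get("alert")
    )
    scores = {r.id: r.labels["score"] for r in records}
    ranking = sorted(((i, scores[i]) for i in alert_pass), key=lambda t: (t[1], t[0]))
    ranking = ranking[: spec.top_k]
    expected = {
        "substructure": benzo,
        "state_selection": anion,
        "rule_of_five": ro5_pass,
        "pharmacophore": matchers,
        "docking_target": docked,
        "pose_filter": target_bid,
        "comparative_elimination": comparative,
        "alerts": alert_pass,
        "ranking": frozenset(i for i, _ in ranking),
    }
    labels_df = pd.DataFrame(
        [
            {"id": r.id, **{k: v for k, v in r.labels.items() if k != "chelation"},
             **{f"chelation_{rec}": cls for rec, cls in r.labels.get("chelation", {}).items()}}
            for r in records
        ]
    )
    return GroundTruth(expected, labels_df, ranking)


def _self_check(spec, records, pocket) -> None:
    """Verify every planted label with the corresponding filter."""
    benzo = {r.id for r in filters.substructure_filter(records)}
    if benzo != {r.id for r in records if r.labels["benzohydroxamate"]}:
        raise RuntimeError("benzohydroxamate labels disagree with the filter")
    anions = {r.id for r in filters.select_hydroxamate_state(list(records))}
    if anions != {r.id for r in records if r.labels["anionic"]}:
        raise RuntimeError("anionic-state labels disagree with the filter")
    anion_recs = [r for r in records if r.labels["anionic"]]
    ro5_pass, _ = filters.lipinski_filter(anion_recs)
    expected = {r.id for r in anion_recs if not r.labels["ro5_violator"]}
    if {r.id for r in ro5_pass} != expected:
        raise RuntimeError("rule-of-five labels disagree with the filter")
    if pocket is not None:
        for r in records:
            if not r.labels["anionic"] or r.labels["ro5_violator"]:
                continue
            got = match(r, pocket.hypothesis) is not None
            if got != bool(r.labels["matcher"]):
                raise RuntimeError(
                    f"pharmacophore label disagrees with the matcher for {r.id}"
                )
    alert_ids = {r.id for r in records if r.labels["alert"]}
    _, removals = filters.reos_filter(list(records))
    removed_ids = {i for i, _ in removals}
    if not alert_ids <= removed_ids:
        raise RuntimeError("alert labels disagree with the alert filter")
    if any(r.labels["matcher"] and not r.labels["alert"] and r.id in removed_ids
           for r in records):
        raise RuntimeError("a non-alert matcher trips the alert filter")


# ---------------------------------------------------------------------------
# Planted docking backend + campaign bundle
# ---------------------------------------------------------------------------

_MODE_BY_CLASS = {
    "bidentate": "chelating",
    "monodentate": "monodentate",
    "none": "nonbinding",
}


class PlantedBackend:
    """Docking backend for synthetic libraries: realizes each record's
    planted per-receptor chelation class geometrically via the mock docker
    (one top-scored pose per ligand; ``undocked`` ligands return None)."""

    def dock(self, record: MoleculeRecord, receptor: ReceptorContext, seed: int):
        cls = record.labels.get("chelation", {}).get(receptor.label)
        if cls is None or cls == "undocked":
            return None
        return mock_dock(record, receptor, _MODE_BY_CLASS[cls], seed)


@dataclass
class Campaign:
    """Everything needed for an end-to-end synthetic funnel run."""

    records: List[MoleculeRecord]
    truth: GroundTruth
    receptors: Dict[str, ReceptorContext]
    backend: PlantedBackend
    config: FunnelConfig
    pocket: SyntheticPocket


def gen_campaign(spec: Optional[LibrarySpec] = None, seed: Optional[int] = None) -> Campaign:
    """Generate a complete synthetic screening campaign: pocket + receptors,
    labelled library, planted backend and a matching funnel configuration."""
    spec = spec or LibrarySpec()
    if seed is not None:
        spec.seed = seed
    pocket = gen_pocket(spec.seed, label=spec.target)
    receptors = {spec.target: pocket.receptor}
    for k, label in enumerate(sorted(spec.rules)):
        anti = gen_pocket(spec.seed + k + 1, label=label)
        receptors[label] = anti.receptor
    records, truth = gen_library(spec, pocket)
    config = FunnelConfig(
        target=spec.target,
        anti_targets=dict(spec.rules),
        hypothesis=pocket.hypothesis,
        top_k=spec.top_k,
        seed=spec.seed,
    )
    return Campaign(records, truth, receptors, PlantedBackend(), config, pocket)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction with an exactly realized persistence fraction.

    ``kind`` and criteria mirror :class:`zincscreen.md.InteractionSpec`;
    the *movable* participant (hydrogen for hbond, ``b`` for salt_bridge,
    ``a`` for distance) is repositioned frame by frame so the criteria
    hold in exactly the masked frames.
    """

    name: str
    kind: str
    fraction: float
    max_distance: Optional[float] = None
    min_angle: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("persistence fraction must lie in [0, 1]")


@dataclass
class TrajectorySpec:
    """Synthetic trajectory parameters: frame count, per-axis jitter (Å),
    planted interactions, an optional total ligand drift (Å, linear
    schedule), and the seed."""

    n_frames: int = 1000
    jitter_ligand: float = 0.0
    jitter_protein: float = 0.0
    interactions: Tuple[PlantedInteraction, ...] = ()
    ligand_drift: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    dt_ns: float = 0.1
    seed: int = 0


def gen_trajectory(
    pocket: SyntheticPocket,
    spec: TrajectorySpec,
) -> Tuple[Trajectory, List[InteractionSpec], dict]:
    """Generate a pocket trajectory with exactly planted persistences.

    Returns ``(trajectory, interaction specs, ground truth)`` where the
    ground truth carries each interaction's frame mask and fraction.
    Contradictory plants (two interactions moving one atom) are an error.
    """
    rng = np.random.default_rng([spec.seed % 2**31, 0x7124])
    receptor = pocket.receptor
    prot = receptor.atoms
    lig_mol = pocket.template.mol
    lig_xyz = lig_mol.GetConformer().GetPositions()
    n_prot, n_lig = len(prot), len(lig_xyz)

    # ligand hydrogen on the hydroxamate nitrogen hosts planted h-bonds
    query = filters._anion_query(filters.HYDROXAMATE_ANION_SMARTS)
    m = lig_mol.GetSubstructMatch(query)
    i_anion, i_n, i_carb = m[0], m[1], m[3]
    n_dir = lig_xyz[i_n] - (lig_xyz[i_anion] + lig_xyz[i_carb]) / 2
    n_dir /= np.linalg.norm(n_dir)
    h_pos = lig_xyz[i_n] + 1.0 * n_dir

    rows = []
    for _, r in prot.iterrows():
        rows.append({"name": r["name"], "resname": r["resname"],
                     "resid": int(r["resnum"]), "element": r["element"]})
    base_resid = int(prot["resnum"].max()) + 1 if n_prot else 1
    for i, atom in enumerate(lig_mol.GetAtoms()):
        rows.append({"name": f"{atom.GetSymbol()}{i+1}", "resname": "LIG",
                     "resid": base_resid, "element": atom.GetSymbol()})
    rows.append({"name": "HN1", "resname": "LIG", "resid": base_resid, "element": "H"})
    rows.append({"name": "ZN", "resname": "ZN", "resid": base_resid + 1, "element": "Zn"})
    atoms = pd.DataFrame(rows)

    base = np.vstack([
        prot[["x", "y", "z"]].to_numpy() if n_prot else np.zeros((0, 3)),
        lig_xyz, h_pos[None, :], receptor.zinc[None, :],
    ])
    F = spec.n_frames
    coords = np.tile(base, (F, 1, 1))

    lig_slice = slice(n_prot, n_prot + n_lig + 1)  # heavy atoms + HN1
    i_h = n_prot + n_lig
    i_zn = n_prot + n_lig + 1
    if spec.jitter_protein > 0 and n_prot:
        coords[:, :n_prot] += rng.normal(0, spec.jitter_protein, (F, n_prot, 3))
    if spec.jitter_ligand > 0:
        coords[:, lig_slice] += rng.normal(0, spec.jitter_ligand, (F, n_lig + 1, 3))
    drift = np.asarray(spec.ligand_drift, float)
    if np.any(drift):
        sched = np.linspace(0.0, 1.0, F)[:, None] * drift[None, :]
        coords[:, lig_slice] += sched[:, None, :]

    # realize planted interactions
    specs: List[InteractionSpec] = []
    truth: dict = {"masks": {}, "fractions": {}}
    movable_used: dict = {}
    anchor_used: dict = {}
    salt_partner = 0 if n_prot else None  # first pseudo protein atom
    hb_acceptor = 1 if n_prot > 1 else None
    n_distance_plants = 0

    for k, plant in enumerate(spec.interactions):
        n_on = round_half_up(F * plant.fraction)
        mask = np.zeros(F, dtype=bool)
        mask[rng.permutation(F)[:n_on]] = True
        if plant.kind == "hbond":
            if hb_acceptor is None:
                raise ValueError("hbond plant needs at least two protein atoms")
            movable = i_h
            anchors = (i_n + n_prot, hb_acceptor)
            max_d = plant.max_distance if plant.max_distance is not None else 2.5
            spec_obj = InteractionSpec(
                plant.name, "hbond",
                (("donor", i_n + n_prot), ("hydrogen", i_h), ("acceptor", hb_acceptor)),
                max_distance=plant.max_distance, min_angle=plant.min_angle,
            )
            for f in range(F):
                d_pos = coords[f, i_n + n_prot]
                a_pos = coords[f, hb_acceptor]
                u = a_pos - d_pos
                dist_da = np.linalg.norm(u)
                u /= dist_da
                if mask[f]:
                    # colinear D-H...A at a compliant H...A distance
                    coords[f, i_h] = a_pos - min(max_d - 0.4, dist_da - 1.0) * u
                else:
                    coords[f, i_h] = d_pos - 1.0 * u  # points away: angle 0
        elif plant.kind in ("salt_bridge", "distance"):
            if plant.kind == "salt_bridge":
                if salt_partner is None:
                    raise ValueError("salt_bridge plant needs a protein atom")
                movable = salt_partner
                anchor = i_anion + n_prot
                max_d = plant.max_distance if plant.max_distance is not None else 4.0
                participants = (("a", anchor), ("b", movable))
            else:
                # first distance plant moves the carbonyl O, the second the
                # anionic O (which anchors the salt bridge and must not move
                # when one is planted alongside)
                movable = i_carb + n_prot if n_distance_plants == 0 else i_anion + n_prot
                n_distance_plants += 1
                anchor = i_zn
                if plant.max_distance is None:
                    raise ValueError("distance plant needs max_distance")
                max_d = plant.max_distance
                participants = (("a", movable), ("b", anchor))
            spec_obj = InteractionSpec(
                plant.name, plant.kind, participants,
                max_distance=plant.max_distance, min_angle=plant.min_angle,
            )
            for f in range(F):
                a_pos = coords[f, anchor]
                u = coords[f, movable] - a_pos
                norm = np.linalg.norm(u)
                u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
                target_d = max_d - 0.5 if mask[f] else max_d + 1.0
                coords[f, movable] = a_pos + target_d * u
            anchors = (anchor,)
        else:
            raise ValueError(f"unknown planted interaction kind: {plant.kind!r}")
        clash = movable_used.get(movable) or anchor_used.get(movable)
        if clash or any(a in movable_used for a in anchors):
            other = clash or movable_used[next(a for a in anchors if a in movable_used)]
            raise ValueError(
                f"contradictory plants: interactions {other!r} and "
                f"{plant.name!r} constrain a shared atom"
            )
        movable_used[movable] = plant.name
        for a in anchors:
            anchor_used.setdefault(a, plant.name)
        specs.append(spec_obj)
        truth["masks"][plant.name] = mask
        truth["fractions"][plant.name] = n_on / F

    traj = make_trajectory(atoms, coords, spec.dt_ns)
    # self-check: masks are realized exactly
    for spec_obj, plant in zip(specs, spec.interactions):
        got = interaction_mask(traj, spec_obj)
        if not np.array_equal(got, truth["masks"][plant.name]):
            raise RuntimeError(
                f"planted interaction {plant.name!r} not exactly realized"
            )
    return traj, specs, truth
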