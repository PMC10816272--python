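"""The comparative screening funnel: orchestration, anti-target
elimination, ranking and the audit report.

Stage order is fixed: substructure curation, protonation-state selection,
rule-of-five, pharmacophore prefilter, docking into the target, chelation
pose filter, comparative docking into the anti-targets with per-receptor
elimination rules, structural-alert removal, and score-based ranking.
Counts telescope stage to stage and every removal is attributed to exactly
one stage and reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from . import filters
from .pharmacophore import PharmacophoreHypothesis, screen
from .poses import (
    DEFAULT_CHELATION_CUTOFF,
    ChelationAssessment,
    ChelationClass,
    DockingBackend,
    ReceptorContext,
    assess_chelation,
)
from .records import AlertSet, MoleculeRecord

#: Anti-target elimination rules.  The stricter rule additionally removes
#: monodentate chelators (used for receptors where even a single-oxygen
#: contact marks a non-selective ligand).
RULE_BIDENTATE = "remove_if_bidentate"
RULE_BIDENTATE_OR_MONO = "remove_if_bidentate_or_monodentate"
ELIMINATION_RULES = (RULE_BIDENTATE, RULE_BIDENTATE_OR_MONO)

STAGE_ORDER = (
    "substructure",
    "state_selection",
    "rule_of_five",
    "pharmacophore",
    "docking_target",
    "pose_filter",
    "comparative_elimination",
    "alerts",
    "ranking",
)


@dataclass
class FunnelConfig:
    """Parameters of one funnel run.  Exactly one target receptor; each
    anti-target carries its elimination rule."""

    target: str
    anti_targets: Dict[str, str] = field(default_factory=dict)
    hypothesis: Optional[PharmacophoreHypothesis] = None
    substructure: str = filters.BENZOHYDROXAMATE_SMARTS
    state_pattern: str = filters.HYDROXAMATE_ANION_SMARTS
    ro5_strict: bool = True
    chelation_cutoff: float = DEFAULT_CHELATION_CUTOFF
    max_conformers: int = 50
    top_k: int = 5
    seed: int = 0
    alerts: Optional[AlertSet] = None

    def __post_init__(self):
        for label, rule in self.anti_targets.items():
            if rule not in ELIMINATION_RULES:
                raise ValueError(
                    f"unknown elimination rule {rule!r} for anti-target {label!r}"
                )

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        hyp = cfg.get("hypothesis")
        if isinstance(hyp, str):
            hyp = PharmacophoreHypothesis.load(Path(path).parent / hyp)
        elif isinstance(hyp, dict):
            hyp = PharmacophoreHypothesis.from_dict(hyp)
        alerts = cfg.get("alerts")
        if isinstance(alerts, str):
            alerts = filters.load_alerts(Path(path).parent / alerts)
        return cls(
            target=cfg["target"],
            anti_targets=dict(cfg.get("anti_targets", {})),
            hypothesis=hyp,
            substructure=cfg.get("substructure", filters.BENZOHYDROXAMATE_SMARTS),
            state_pattern=cfg.get("state_pattern", filters.HYDROXAMATE_ANION_SMARTS),
            ro5_strict=bool(cfg.get("ro5_strict", True)),
            chelation_cutoff=float(cfg.get("chelation_cutoff", DEFAULT_CHELATION_CUTOFF)),
            max_conformers=int(cfg.get("max_conformers", 50)),
            top_k=int(cfg.get("top_k", 5)),
            seed=int(cfg.get("seed", 0)),
            alerts=alerts,
        )


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    survivors: Tuple[str, ...]
    removals: List[Tuple[str, str]] = field(default_factory=list)  # (id, reason)


@dataclass
class FunnelReport:
    """Audit trail of a funnel run: per-stage counts, survivor id sets,
    removal attributions, and the final ranking table."""

    stages: List[StageResult] = field(default_factory=list)
    ranking: List[Tuple[str, float]] = field(default_factory=list)

    def add(self, stage: StageResult) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {stage.name!r} input count {stage.n_in} does not telescope "
                f"from previous output {self.stages[-1].n_out}"
            )
        if stage.n_in != stage.n_out + len(stage.removals):
            raise ValueError(f"stage {stage.name!r} audit counts do not reconcile")
        self.stages.append(stage)

    def counts(self) -> Dict[str, Tuple[int, int]]:
        return {s.name: (s.n_in, s.n_out) for s in self.stages}

    def survivors(self, stage: Optional[str] = None) -> Tuple[str, ...]:
        if stage is None:
            return self.stages[-1].survivors if self.stages else ()
        for s in self.stages:
            if s.name == stage:
                return s.survivors
        raise KeyError(stage)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "survivors": list(s.survivors),
                    "removals": [{"id": i, "reason": r} for i, r in s.removals],
                }
                for s in self.stages
            ],
            "ranking": [{"id": i, "score": sc} for i, sc in self.ranking],
        }

    def save(self, out_dir) -> None:
        """Write the machine-readable JSON plus per-stage CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        with open(out / "removals.csv", "w", encoding="utf-8") as fh:
            fh.write("id,stage,reason\n")
            for s in self.stages:
                for rec_id, reason in s.removals:
                    fh.write(f"{rec_id},{s.name},{reason}\n")
        with open(out / "ranking.csv", "w", encoding="utf-8") as fh:
            fh.write("id,score\n")
            for rec_id, score in self.ranking:
                fh.write(f"{rec_id},{score}\n")


def comparative_eliminate(
    target_pass: Sequence[str],
    antitarget_assessments: Mapping[str, Mapping[str, ChelationAssessment]],
    rules: Mapping[str, str],
) -> Tuple[List[str], List[Tuple[str, str]]]:
    """Remove ligands that chelate in any anti-target per its rule.

    A ligand absent from an anti-target's assessments (it failed to dock
    there) is *not* removed by that receptor.  Returns the surviving ids in
    input order plus the removal log ``(id, "receptor:class")``.
    """
    for label in rules:
        if label not in antitarget_assessments:
            raise ValueError(f"elimination rule references unknown receptor {label!r}")
    survivors, removals = [], []
    for rec_id in target_pass:
        trigger = None
        for label, rule in rules.items():
            assessment = antitarget_assessments[label].get(rec_id)
            if assessment is None:
                continue
            cls = assessment.cls
            if cls == ChelationClass.BIDENTATE or (
                rule == RULE_BIDENTATE_OR_MONO and cls == ChelationClass.MONODENTATE
            ):
                trigger = f"{label}:{cls.value}"
                break
        if trigger is None:
            survivors.append(rec_id)
        else:
            removals.append((rec_id, trigger))
    return survivors, removals


def rank(
    survivors: Sequence[str],
    scores: Mapping[str, float],
    top_k: Optional[int] = None,
) -> List[Tuple[str, float]]:
    """Order survivors ascending by binding score (most negative first);
    ties break lexicographically by id.  Missing scores are an error."""
    missing = [s for s in survivors if s not in scores]
    if missing:
        raise ValueError(f"missing binding scores for: {sorted(missing)}")
    table = sorted(((s, float(scores[s])) for s in survivors), key=lambda t: (t[1], t[0]))
    return table[:top_k] if top_k is not None else table


def run_funnel(
    config: FunnelConfig,
    records: Sequence[MoleculeRecord],
    receptors: Mapping[str, ReceptorContext],
    backend: DockingBackend,
    scores: Optional[Mapping[str, float]] = None,
) -> FunnelReport:
    """Execute the full funnel and return its audit report.

    ``receptors`` must contain the target and every anti-target.  ``scores``
    is the external binding-score table (lower = better); when omitted, the
    per-record label ``score`` is used (synthetic libraries plant one).
    Deterministic given ``config.seed`` and the backend.
    """
    if config.target not in receptors:
        raise ValueError(f"target receptor {config.target!r} not supplied")
    for label in config.anti_targets:
        if label not in receptors:
            raise ValueError(f"anti-target receptor {label!r} not supplied")

    report = FunnelReport()
    current: List[MoleculeRecord] = list(records)

    def close_stage(name, survivors, removed):
        report.add(
            StageResult(
                name=name,
                n_in=len(current),
                n_out=len(survivors),
                survivors=tuple(r.id for r in survivors),
                removals=removed,
            )
        )

    # 1. substructure curation
    kept = filters.substructure_filter(current, config.substructure)
    kept_ids = {r.id for r in kept}
    close_stage("substructure",
                kept, [(r.id, "no_substructure_match") for r in current if r.id not in kept_ids])
    current = kept

    # 2. protonation-state selection
    kept = filters.select_hydroxamate_state(current, config.state_pattern)
    kept_ids = {r.id for r in kept}
    close_stage("state_selection",
                kept, [(r.id, "not_hydroxamate_anion") for r in current if r.id not in kept_ids])
    current = kept

    # 3. rule of five
    kept, violations = filters.lipinski_filter(current, strict=config.ro5_strict)
    kept_ids = {r.id for r in kept}
    close_stage("rule_of_five",
                kept,
                [(r.id, f"ro5_violations={violations[r.id]}")
                 for r in current if r.id not in kept_ids])
    current = kept

    # 4. pharmacophore prefilter
    if config.hypothesis is None:
        raise ValueError("funnel configuration lacks a pharmacophore hypothesis")
    kept, _matches = screen(current, config.hypothesis, config.max_conformers,
                            conformer_seed=config.seed)
    kept_ids = {r.id for r in kept}
    close_stage("pharmacophore",
                kept, [(r.id, "no_pharmacophore_match") for r in current if r.id not in kept_ids])
    current = kept

    # 5. docking into the target
    target = receptors[config.target]
    poses = {}
    kept = []
    removed = []
    for rec in current:
        pose = backend.dock(rec, target, config.seed)
        if pose is None:
            removed.append((rec.id, f"undocked_in_{config.target}"))
        else:
            poses[rec.id] = pose
            kept.append(rec)
    close_stage("docking_target", kept, removed)
    current = kept

    # 6. chelation pose filter in the target
    kept, removed = [], []
    for rec in current:
        assessment = assess_chelation(poses[rec.id], target, config.chelation_cutoff)
        if assessment.cls == ChelationClass.BIDENTATE:
            kept.append(rec)
        else:
            removed.append((rec.id, f"chelation_{assessment.cls.value}"))
    close_stage("pose_filter", kept, removed)
    current = kept

    # 7. comparative docking + elimination in the anti-targets
    anti_assessments: Dict[str, Dict[str, ChelationAssessment]] = {}
    for label in config.anti_targets:
        receptor = receptors[label]
        table = {}
        for rec in current:
            pose = backend.dock(rec, receptor, config.seed)
            if pose is not None:
                table[rec.id] = assess_chelation(pose, receptor, config.chelation_cutoff)
        anti_assessments[label] = table
    surviving_ids, removals = comparative_eliminate(
        [r.id for r in current], anti_assessments, config.anti_targets
    )
    keep_set = set(surviving_ids)
    kept = [r for r in current if r.id in keep_set]
    close_stage("comparative_elimination", kept, removals)
    current = kept

    # 8. structural alerts
    kept, removals = filters.reos_filter(current, config.alerts)
    close_stage("alerts", kept, [(i, f"alert_{name}") for i, name in removals])
    current = kept

    # 9. ranking
    if scores is None:
        scores = {r.id: r.labels["score"] for r in current if "score" in r.labels}
    report.ranking = rank([r.id for r in current], scores, config.top_k)
    ranked_ids = {i for i, _ in report.ranking}
    close_stage("ranking",
                [r for r in current if r.id in ranked_ids],
                [(r.id, "below_top_k") for r in current if r.id not in ranked_ids])
    return report
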