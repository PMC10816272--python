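"""Binding-pose-metadynamics style pose-stability scoring.

A pose is probed by repeated short biased simulations ("trials") that use
the ligand RMSD from its starting pose as the collective variable.  Each
trial contributes its time-averaged ligand RMSD and its per-interaction
persistence fractions; the aggregate scores are

* ``PoseScore`` -- mean over trials of the trial-averaged ligand RMSD (Å);
  poses at or below 2 Å are conventionally called stable;
* ``PersScore`` -- mean over trials of the mean per-interaction
  persistence; at or above 0.6 the contact network is considered
  maintained;
* ``CompScore`` -- PoseScore − 5 × PersScore, increasingly negative for
  more stable poses.

The metadynamics sampling itself is out of scope; trials come from
trajectory analysis of supplied or synthetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .md import InteractionSpec, Selection, Trajectory, persistence, rmsd_series

POSE_STABLE_MAX = 2.0      # Å
PERS_MAINTAINED_MIN = 0.6  # fraction
DEFAULT_COMP_WEIGHT = 5.0  # CompScore = pose - weight * pers


@dataclass(frozen=True)
class TrialResult:
    """One metadynamics trial: the ligand-RMSD series relative to the
    starting pose and the per-interaction persistence fractions."""

    trial: int
    ligand_rmsd: tuple  # Å, per analysis window
    persistences: tuple  # of (interaction name, fraction) pairs

    def __post_init__(self):
        if any(r < 0 for r in self.ligand_rmsd):
            raise ValueError("RMSD values must be non-negative")
        if any(not (0.0 <= p <= 1.0) for _, p in self.persistences):
            raise ValueError("persistence fractions must lie in [0, 1]")

    @property
    def mean_rmsd(self) -> float:
        if not self.ligand_rmsd:
            raise ValueError("trial has an empty RMSD series")
        return float(np.mean(self.ligand_rmsd))

    @property
    def mean_persistence(self) -> float:
        if not self.persistences:
            raise ValueError("trial has no interactions")
        return float(np.mean([p for _, p in self.persistences]))


@dataclass(frozen=True)
class BPMDResult:
    pose_score: float
    pers_score: float
    comp_score: float
    pose_stable: bool
    contacts_maintained: bool

    def summary_line(self) -> str:
        return (
            f"{self.pose_score},{self.pers_score},{self.comp_score},"
            f"{self.pose_stable},{self.contacts_maintained}"
        )


def pose_score(trials: Sequence[TrialResult]) -> float:
    """Mean over trials of each trial's time-averaged ligand RMSD (Å)."""
    if not trials:
        raise ValueError("pose_score needs at least one trial")
    return float(np.mean([t.mean_rmsd for t in trials]))


def pers_score(trials: Sequence[TrialResult]) -> float:
    """Mean over trials of the mean per-interaction persistence."""
    if not trials:
        raise ValueError("pers_score needs at least one trial")
    return float(np.mean([t.mean_persistence for t in trials]))


def comp_score(pose: float, pers: float, weight: float = DEFAULT_COMP_WEIGHT) -> float:
    """Composite stability score: ``pose - weight * pers``.

    Strictly increasing in the pose score and strictly decreasing in the
    persistence score, so more negative means more stable.
    """
    if not (np.isfinite(pose) and np.isfinite(pers)):
        raise ValueError("comp_score inputs must be finite")
    return float(pose) - float(weight) * float(pers)


def score_trials(trials: Sequence[TrialResult],
                 weight: float = DEFAULT_COMP_WEIGHT) -> BPMDResult:
    """Aggregate trials into the full score triple plus stability flags."""
    ps = pose_score(trials)
    rs = pers_score(trials)
    return BPMDResult(
        pose_score=ps,
        pers_score=rs,
        comp_score=comp_score(ps, rs, weight),
        pose_stable=ps <= POSE_STABLE_MAX,
        contacts_maintained=rs >= PERS_MAINTAINED_MIN,
    )


def trial_from_trajectory(
    trial: int,
    traj: Trajectory,
    specs: Sequence[InteractionSpec],
    fit_selection: Selection | None = None,
) -> TrialResult:
    """Reduce one trial trajectory to a TrialResult.

    The ligand RMSD is measured relative to the starting pose (frame 0)
    after fitting on ``fit_selection`` (default: protein backbone);
    persistences are measured for the interactions defined at frame 0.
    """
    fit = fit_selection or Selection("protein_backbone")
    series = rmsd_series(traj, fit, Selection("ligand"))
    pers = tuple((s.name, persistence(traj, s)) for s in specs)
    return TrialResult(trial, tuple(series), pers)
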