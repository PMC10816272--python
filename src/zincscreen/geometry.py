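"""Rigid-body superposition helpers (Kabsch) shared by the pharmacophore
matcher and the trajectory analysis."""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation


class RigidTransform(NamedTuple):
    """Proper rigid transform ``x -> R @ (x - mob_centroid) + ref_centroid``."""

    rotation: np.ndarray      # (3, 3), det +1
    mob_centroid: np.ndarray  # (3,)
    ref_centroid: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mob_centroid) @ self.rotation.T + self.ref_centroid


def kabsch(ref: np.ndarray, mob: np.ndarray, *, require_noncollinear: bool = False):
    """Least-squares optimal proper rotation + translation of ``mob`` onto ``ref``.

    Parameters
    ----------
    ref, mob : (n, 3) arrays
        Paired coordinates in Å.
    require_noncollinear : bool
        When True, demand at least three non-collinear points (the fit is
        otherwise rotationally ambiguous about the common axis).

    Returns
    -------
    (RigidTransform, float)
        The transform and the fit RMSD in Å.
    """
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mob must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n == 0:
        raise ValueError("cannot superpose empty selections")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    ref0 = ref - ref_c
    mob0 = mob - mob_c
    if require_noncollinear:
        if n < 3 or np.linalg.matrix_rank(ref0, tol=1e-8) < 2:
            raise ValueError("superposition needs at least 3 non-collinear atoms")
    with warnings.catch_warnings():
        # rank-deficient point sets trigger an 'optimal rotation is not
        # unique' warning; any optimum is acceptable downstream
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(ref0, mob0)
    rmsd = float(rssd) / np.sqrt(n)
    return RigidTransform(rot.as_matrix(), mob_c, ref_c), rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between paired coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_rigid_transform(rng: np.random.Generator) -> RigidTransform:
    """A uniformly random proper rotation plus a random translation."""
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.uniform(-20.0, 20.0, size=3)
    return RigidTransform(rot.as_matrix(), np.zeros(3), shift)
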