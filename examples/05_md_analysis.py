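"""Analyze a pose-stability trajectory.

Generates a synthetic pocket trajectory with planted interaction
persistences (a salt bridge at 98%, an H-bond at 68%, a chelation-distance
trace at 100%), then measures backbone-fit RMSD series, ligand RMSF and
per-interaction persistence fractions.
"""

import numpy as np

from zincscreen import persistence, rmsd_series, rmsf
from zincscreen.md import Selection, summarize
from zincscreen.synthetic import (
    PlantedInteraction,
    TrajectorySpec,
    gen_pocket,
    gen_trajectory,
)

pocket = gen_pocket(seed=5)
spec = TrajectorySpec(
    n_frames=1000,
    jitter_ligand=0.25,
    jitter_protein=0.10,
    interactions=(
        PlantedInteraction("salt_bridge_his", "salt_bridge", 0.98),
        PlantedInteraction("hbond_his", "hbond", 0.68),
        PlantedInteraction("chelation_carbonyl", "distance", 1.00,
                           max_distance=2.6),
    ),
    seed=5,
)
traj, specs, truth = gen_trajectory(pocket, spec)
print(f"trajectory: {traj.n_frames} frames x {traj.n_atoms} atoms")

backbone = Selection("protein_backbone")
lig_rmsd = rmsd_series(traj, backbone, Selection("ligand"))
print(f"ligand RMSD (backbone fit): mean {lig_rmsd.mean():.2f} Å, "
      f"max {lig_rmsd.max():.2f} Å")

vals = rmsf(traj, Selection("ligand"), backbone)
print(f"ligand RMSF: mean {vals.mean():.2f} Å "
      f"(pure-jitter reference sqrt(3)*sigma = "
      f"{np.sqrt(3) * spec.jitter_ligand:.2f} Å; planted-interaction atoms "
      f"fluctuate more)")

for s in specs:
    frac = persistence(traj, s)
    print(f"persistence {s.name:20s} {100 * frac:5.1f}%  "
          f"(planted {100 * truth['fractions'][s.name]:5.1f}%)")
# Persistence fractions are recovered exactly because the generator
# realizes each interaction's criteria in exactly the masked frames.
summary = summarize(traj, specs)
print("summary series:", sorted(summary.rmsd))
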