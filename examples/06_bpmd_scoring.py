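"""Binding-pose-metadynamics scoring of a pose.

Reduces ten short planted trials to PoseScore (mean ligand RMSD), PersScore
(mean interaction persistence) and CompScore = PoseScore - 5 x PersScore,
then evaluates the composite rule on the printed per-pose statistics of a
validated hit's two poses.
"""

from zincscreen import comp_score, score_trials, trial_from_trajectory
from zincscreen.synthetic import (
    PlantedInteraction,
    TrajectorySpec,
    gen_pocket,
    gen_trajectory,
)

pocket = gen_pocket(seed=9)
trials = []
for i in range(10):
    traj, specs, _ = gen_trajectory(
        pocket,
        TrajectorySpec(
            n_frames=100, jitter_ligand=0.3, seed=900 + i,
            interactions=(
                PlantedInteraction("salt_bridge", "salt_bridge", 0.95),
                PlantedInteraction("hbond", "hbond", 0.60),
            ),
        ),
    )
    trials.append(trial_from_trajectory(i, traj, specs))

result = score_trials(trials)
print(f"PoseScore {result.pose_score:.3f} Å  (stable <= 2 Å: {result.pose_stable})")
print(f"PersScore {result.pers_score:.3f}    (maintained >= 0.6: "
      f"{result.contacts_maintained})")
print(f"CompScore {result.comp_score:.3f}    (more negative = more stable)")

# composite rule applied to the validated hit's printed per-pose statistics
print("original docked pose:  ", round(comp_score(3.226, 0.712), 3))
print("500 ns final-frame pose:", round(comp_score(1.747, 0.679), 3))
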