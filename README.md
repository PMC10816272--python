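# zincscreen

A comparative structure-based virtual-screening funnel for zinc-dependent
deacylase targets, built around hydroxamate chemistry.

Selective inhibition within the zinc-dependent histone deacylase (HDAC)
family is hard: the catalytic pockets are similar and the common
zinc-binding group — the deprotonated hydroxamate, `C(=O)N(H)O⁻` — chelates
the catalytic Zn²⁺ in every isoform. A practical route to selectivity is
*comparative* screening: dock the curated candidates into the target **and**
into anti-target isoforms, keep only ligands whose pose chelates the zinc
correctly in the target while failing to do so in every anti-target, then
validate the surviving hits by molecular-dynamics pose-stability analysis.
`zincscreen` implements that entire desk-side pipeline as an open, testable
library for computational chemists.

## What it does

The funnel runs nine fixed stages, each an order-preserving filter with a
full audit trail:

1. **Substructure curation** — keep the screened chemotype
   (benzohydroxamates, SMARTS `C1=CC=C(C(=O)NO)C=C1`).
2. **State selection** — keep the zinc-binding anionic hydroxamate state
   (`[O-]N([H])C(=O)c1ccccc1`).
3. **Rule of five** — strict drug-likeness: MW < 500 Da, logP < 5,
   H-bond donors < 5, H-bond acceptors < 10 (zero violations survive).
4. **Pharmacophore prefilter** — match up to 50 conformers per ligand
   against a four-feature hypothesis (carbonyl-O acceptor, N–H donor,
   anionic-O negative, capping-ring aromatic) with excluded volumes;
   at most one hit per ligand.
5. **Docking (target)** — one top-scored pose per ligand through a
   pluggable backend contract (a deterministic mock backend ships).
6. **Chelation pose filter** — measure both chelator-oxygen→Zn distances;
   keep bidentate poses (both ≤ 2.6 Å; the boundary passes).
7. **Comparative elimination** — dock survivors into each anti-target and
   remove any ligand that chelates there (bidentate anywhere; for
   anti-targets carrying the stricter rule, monodentate too). Ligands
   that fail to dock in an anti-target are *not* removed by it.
8. **Structural alerts** — rapid elimination of reactive/toxic/assay-
   interfering substructures (nitro groups and friends).
9. **Ranking** — ascending by externally supplied binding scores
   (MM-GBSA-like; lower = better), lexicographic tie-break, top-k.

Around the funnel:

- **MD analysis** (`zincscreen.md`): Kabsch superposition, backbone-fit
  RMSD series (flexible termini excludable by residue range), per-atom
  RMSF, chelation-distance traces, and interaction-persistence fractions
  (H-bond: H···acceptor ≤ 2.5 Å and donor angle ≥ 120°; salt bridge:
  ≤ 4.0 Å; distance traces at the chelation cutoff).
- **Pose-metadynamics scoring** (`zincscreen.bpmd`): per-trial ligand-RMSD
  and persistence reductions aggregated into
  `PoseScore` (mean ligand RMSD, stable ≤ 2 Å),
  `PersScore` (mean interaction persistence, maintained ≥ 0.6) and
  `CompScore = PoseScore − 5·PersScore` (more negative = more stable).
- **Synthetic data** (`zincscreen.synthetic`): seeded generators for
  labelled libraries, zinc pockets with pharmacophore hypotheses and
  excluded volumes, docked poses with controllable chelator–Zn distances,
  and trajectories whose interaction persistences are realized *exactly*
  as planted frame masks — so the whole pipeline is testable offline,
  with ground truth next to every artifact.

## Worked example

`examples/04_run_funnel.py` generates a 200-ligand synthetic campaign and
runs the full funnel:

```
stage                        in  out  planted
substructure                200  100      100
state_selection             100   70       70
rule_of_five                 70   60       60
pharmacophore                60   50       50
docking_target               50   50       50
pose_filter                  50   35       35
comparative_elimination      35   23       23
alerts                       23   19       19
ranking                      19    5        5

final ranking (binding score, lower = better):
  mol-0044   -64.23
  mol-0168   -62.79
  mol-0110   -56.45
  mol-0062   -56.27
  mol-0173   -55.92
```

Every stage's output count equals the generator's planted composition:
100 benzohydroxamates, 70 anionic states, 10 rule-of-five violators, 50
pharmacophore matchers, 35 target-bidentate poses, 12 ligands eliminated
by anti-target chelation, 4 alert bearers, and the 5 best-scoring
survivors. The other examples (`examples/01`–`06`) walk through each
capability on its own: curation, pharmacophore screening, chelation
classification, MD analysis and pose-metadynamics scoring.

A thin CLI wraps the same calls:

```bash
zincscreen simulate library --seed 4 --n 60 --out lib/
zincscreen simulate pocket  --seed 4 --out pocket/
zincscreen run --config cfg.yaml --library lib/library.sdf --format sdf --out report/
```

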