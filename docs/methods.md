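# Methods

This note documents the models, conventions and defaults behind
`zincscreen`, the design choices made where the design was genuinely open,
and what the synthetic-data generators do and do not emulate.

## Curation chemistry

**Substructure filter.** The screened chemotype is the benzohydroxamate,
written in its commonly printed Kekulé form `C1=CC=C(C(=O)NO)C=C1`.
Patterns whose strict SMARTS reading would demand aliphatic ring atoms for
an aromatic system are compiled from their sanitized SMILES interpretation
instead (`filters.compile_substructure`), so aromatic benzohydroxamic
acids match as chemically intended.

**State selection.** Protonation-state *enumeration* is out of scope —
libraries are expected to arrive with states already enumerated (as
ionization-state engines produce them). The filter only selects the
zinc-binding deprotonated form via `[O-]N([H])C(=O)c1ccccc1`, with the
explicit-H query merged onto the nitrogen's hydrogen count.

**Rule of five.** All four inequalities are strict (`<`), following the
protocol wording this pipeline reproduces; the classical `≤` reading is
available via `strict=False`. Molecular weight uses average atomic
weights. logP is the Wildman–Crippen fragment-additive estimate (RDKit's
`Crippen.MolLogP`, 1999 parameterization) — a published, reproducible
scheme chosen because proprietary descriptor packages are neither
available nor reimplementable. Donor/acceptor perception is shipped as
SMARTS data (`data/perception.yaml`), not code constants: donors are N–H
and O–H hydrogens (counted per hydrogen), acceptors are N and O atoms —
the classical rule-of-five counts. Integer counts are used throughout;
fractional donor/acceptor conventions of proprietary tools are not
reproduced, so survivor counts of historical runs using such tools are
not a comparison surface.

**Alerts.** The default alert set (`data/alerts.yaml`) covers nitro
groups, aldehydes, acyl and activated alkyl halides, Michael acceptors,
epoxides/aziridines, isocyanates, thiols, azo/diazonium species and
peroxides. It is a deliberately small, auditable YAML file; projects
should extend it rather than treat it as exhaustive.

**Masses.** `protonated_mass` adds one hydrogen to the neutral formula
and sums most-abundant-isotope masses, ignoring the electron mass — the
convention of printed "calculated" HRMS [M+H]⁺ values (394.1403 for
C21H19N3O5 + H; subtracting the electron mass would print 394.1397).
Nominal masses sum integer mass numbers.

## Pharmacophore model

A hypothesis is a list of typed features (acceptor, donor, negative,
positive, aromatic, hydrophobic) with spherical tolerances plus excluded
volumes. Defaults: tolerance **1.5 Å**, excluded-volume radius **1.2 Å**,
receptor shell distance **5.0 Å** — all three config keys; the upstream
screening software's internal values are unpublished, so these are this
package's own documented choices.

Feature perception is SMARTS-driven (`data/perception.yaml`) with anchors
on heavy atoms; aromatic features anchor on ring centroids. Direction
vectors (e.g. for aromatic ring normals or acceptor lone pairs) are *not*
modelled; matching is purely positional. Hydrophobic perception requires
an sp³ carbon with two carbon neighbours and no heteroatom neighbour, so
methane and ethane carry no features.

**Matching.** For each conformer (up to 50 by default, mirroring common
screening practice; records without 3D coordinates get a seeded ETKDG
ensemble), the matcher searches injective, kind-compatible assignments of
hypothesis features to perceived ligand features. The search is a
backtracking enumeration pruned by the pairwise-distance necessary
condition |d_ligand − d_hypothesis| ≤ tol_i + tol_j (rigid alignment
preserves distances, so the prune is lossless — asserted against an
exhaustive oracle in tests). Each complete assignment is evaluated by
rigid-body least-squares (Kabsch) alignment of the anchors onto the
feature centers; the assignment is accepted iff every aligned anchor lies
within its feature's tolerance and no ligand heavy-atom center lies
inside any excluded volume. The clash test uses atom centers against the
sphere with no van-der-Waals inflation: simple, deterministic and
documented. The lowest-fit-RMSD accepted assignment wins; across
conformers ties go to the lowest conformer index. At most one result per
ligand is reported.

## Chelation geometry

The pose filter measures Euclidean distances from the hydroxamate's
carbonyl and hydroxylate oxygens to the designated catalytic zinc.
Classification under the cutoff (default **2.6 Å**): bidentate iff both
distances ≤ cutoff, monodentate iff exactly one, none otherwise. The
boundary is inclusive — only poses *beyond* the cutoff fail — following
the removal wording of the protocol reproduced here. With several
hydroxamate embeddings, the pair whose midpoint lies nearest the zinc is
used when a receptor is supplied, else the first embedding.

Docking engines attach through a one-method backend contract (`dock ->
top pose or None`); "top-scored pose per ligand" is the backend's
responsibility. Only a deterministic geometric mock ships: it places the
chelator oxygens at prescribed distances (chelating 2.0–2.3 Å,
monodentate one in-band and one beyond the cutoff, nonbinding all beyond
4 Å) and rotates the remaining atoms about the chelation axis to the
least-clashing of twelve orientations. It makes no energetic claim — it
exists so the funnel's *logic* is testable without a commercial engine.

## Funnel semantics

Stage order is fixed (curation → pharmacophore → target docking → pose
filter → comparative elimination → alerts → ranking). Counts telescope;
every removal carries exactly one stage and reason; survivor sets are
permutation-invariant under library reordering (per-ligand seeds derive
from record ids, not positions). "Correct pose" in an anti-target is
operationalized purely as the chelation class — flipped or
pocket-unreachable poses fail the distance rule; no manual inspection
criteria are modelled. A ligand absent from an anti-target's assessments
(it failed to dock there) is treated as safe with respect to that
receptor: absence is not evidence of off-target chelation. Binding
scores are consumed, never computed — force-field rescoring belongs to
external tools; the ranking is ascending with lexicographic tie-breaks
for reproducibility.

## Trajectory analysis

The reference structure is frame 0 (configurable to an external pose).
RMSD series fit each frame to the reference on the fit selection
(protein backbone by default: N/CA/C/O of protein residues), then measure
over the measurement selection — so ligand and zinc RMSD are reported
"fit to backbone". Flexible termini can be excluded from selections by
inclusive residue ranges. Superposition is the Kabsch optimum via
`scipy`'s `Rotation.align_vectors`, restricted to proper rotations, and
requires three non-collinear atoms. RMSF is the per-atom RMS deviation
from the time-average position after per-frame fitting; for isotropic
per-axis jitter σ it converges to √3·σ (used as a closed-form test).

Interaction persistence is the fraction of frames satisfying all
geometric criteria of a spec. Defaults follow common simulation-suite
conventions, since no single standard exists: H-bond H···acceptor
≤ 2.5 Å with donor–H–acceptor angle ≥ 120°; salt-bridge heavy-atom
distance ≤ 4.0 Å; plain distance traces take a user cutoff (chelation
traces use the 2.6 Å chelation cutoff). All criteria live in config so
reported persistences are reproducible. Fractions are stored in [0, 1]
and formatted as percent in reports. Multi-model PDB is the portable
trajectory format (read/written via MDAnalysis, ~10⁻³ Å coordinate
precision); other formats can be loaded through any reader that yields
coordinate arrays.

## Pose-metadynamics scoring

Each trial contributes its time-averaged ligand RMSD (the collective
variable of the underlying biased-sampling method) and its
per-interaction persistences, measured for interactions defined at the
starting pose. `PoseScore` is the mean over trials of the trial averages
(averaging window: the full series; configurable). `PersScore` is the
mean over trials of the mean per-interaction persistence. `CompScore =
PoseScore − weight·PersScore` with weight 5 (config constant), verified
against both printed score triples of the validated hit
((3.226, 0.712) → −0.334 vs printed −0.335; (1.747, 0.679) → −1.648 vs
printed −1.647; both within rounding of three-decimal inputs). Stability
flags: pose stable at PoseScore ≤ 2 Å, contacts maintained at
PersScore ≥ 0.6. The metadynamics sampling itself (bias construction,
free-energy surfaces) is not implemented; trials come from trajectory
analysis of supplied or synthetic runs.

## Synthetic data: what it emulates, and what it does not

`gen_library` plants nested subsets with round-half-up counts:
benzohydroxamates ⊇ anionic states ⊇ {rule-of-five violators,
pharmacophore matchers}; alert bearers are planted among
comparative-elimination survivors so every stage's effect is observable.
Matcher conformers are constrained-embedded onto a shared
benzyloxy-phenyl-capped benzohydroxamate core in the pocket frame, which
makes pharmacophore recovery exact by construction; non-matching anions
are capless scaffolds whose single aromatic ring cannot reach the distal
aromatic feature. Per-receptor chelation classes (including an
`undocked` mass) are planted over the matcher set and realized
geometrically by the mock backend. Class assignments are reshuffled
(seeded, bounded) until enough comparative survivors exist to host the
planted alert bearers; an infeasible spec raises. Every generator is
deterministic under its seed, emits ground truth, and self-verifies each
planted label against the corresponding filter at generation time.

Default library composition (fractions of n): benzohydroxamates 0.50,
anionic states 0.35, rule-of-five violators 0.05, pharmacophore matchers
0.25, alert bearers 0.02; target chelation 70% bidentate / 20%
monodentate; anti-targets with 6–10% bidentate triggers, one carrying
the stricter monodentate rule, and a 50% undocked mass on one
anti-target to exercise the absence-is-not-removal rule. These defaults
give a 200-ligand campaign whose count structure (broad entry, sharp
comparative attrition, a handful of ranked hits) mirrors a real
funnel at desk scale; absolute database-scale counts are expressly not a
target, since they depend on external databases and commercial software.

`gen_trajectory` realizes interactions by geometric construction, not
sampling: after jitter and drift are applied, each interaction's movable
atom (the H for H-bonds, the protein partner for salt bridges, a
chelator oxygen for distance traces) is repositioned frame by frame to
satisfy or violate the criteria exactly per the planted mask, with
0.4–0.5 Å margins so other atoms' jitter cannot flip a frame. This makes
persistence recovery exact — and means the trajectories are *not*
physically realistic ensembles: no force field, no water, no correlated
motions, occasionally unphysical bond lengths on moved atoms. Passing
tests therefore demonstrate estimator correctness, not the behaviour of
real MD data.

Problem sizes used in the shipped tests and examples — 200-ligand
libraries, 1,000–2,000-frame trajectories, 10 trials × 50–100 frames for
scoring — were chosen as the smallest sizes at which every planted
effect is exactly observable (fraction granularity, RMSF convergence
within 5%).

## Known limitations

- No docking energetics: the mock backend is geometric; real engines
  must be attached via the backend contract.
- No state enumeration, tautomers or 3D energy minimization beyond the
  embedding force field.
- Pharmacophore matching is rigid per conformer (no on-the-fly
  minimization) and positional (no feature direction vectors); partial
  matches are not scored.
- Persistence criteria are single-geometry: water-mediated contacts and
  π–π stacking are not detected.
- The chelation filter assumes the single supplied pose per ligand per
  receptor is the representative one.
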