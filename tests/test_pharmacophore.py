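"""Pharmacophore perception, hypothesis construction and matching.

The matcher is checked against a brute-force oracle that enumerates every
kind-compatible injective assignment and evaluates each with an independent
Kabsch fit.
"""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from zincscreen import (
    ExcludedVolume,
    Feature,
    PharmacophoreHypothesis,
    build_hypothesis,
    match,
    perceive_features,
    screen,
)
from zincscreen.pharmacophore import MatchResult, PerceivedFeature
from zincscreen.records import MoleculeRecord


def embed(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    return Chem.RemoveHs(mol)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive assignment enumeration + plain Kabsch
# ---------------------------------------------------------------------------

def oracle_best_fit(hypothesis, perceived, heavy_xyz):
    """Enumerate all injective kind-compatible assignments; return the best
    accepted fit RMSD (or None).  Uses its own Kabsch via numpy SVD."""

    def kabsch_rmsd(ref, mob):
        ref = np.asarray(ref, float)
        mob = np.asarray(mob, float)
        rc, mc = ref.mean(0), mob.mean(0)
        h = (mob - mc).T @ (ref - rc)
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        moved = (mob - mc) @ rot.T + rc
        return rot, mc, rc, np.sqrt(np.mean(np.sum((moved - ref) ** 2, 1)))

    feats = hypothesis.features
    centers = np.array([f.center for f in feats])
    candidates = [[p for p in perceived if p.kind == f.kind] for f in feats]
    best = None
    for combo in itertools.product(*candidates):
        if len({id(p) for p in combo}) != len(combo):
            continue
        anchors = np.array([p.anchor for p in combo])
        rot, mc, rc, fit = kabsch_rmsd(centers, anchors)
        moved = (anchors - mc) @ rot.T + rc
        if any(
            np.linalg.norm(m - c) > f.tolerance
            for m, c, f in zip(moved, centers, feats)
        ):
            continue
        lig_moved = (heavy_xyz - mc) @ rot.T + rc
        clash = any(
            np.linalg.norm(lig_moved - np.asarray(v.center), axis=1).min() < v.radius
            for v in hypothesis.volumes
        )
        if clash:
            continue
        if best is None or fit < best:
            best = fit
    return best


def random_instance(rng, n_features, n_ligand_features):
    kinds = ["acceptor", "donor", "negative", "aromatic", "hydrophobic", "positive"]
    feat_kinds = [kinds[rng.integers(0, len(kinds))] for _ in range(n_features)]
    centers = rng.uniform(-5, 5, (n_features, 3))
    features = [
        Feature(k, tuple(c), tolerance=float(rng.uniform(0.8, 2.0)))
        for k, c in zip(feat_kinds, centers)
    ]
    hyp = PharmacophoreHypothesis(features)
    perceived = []
    for i in range(n_ligand_features):
        if i < n_features and rng.random() < 0.7:
            kind = feat_kinds[i]
            anchor = centers[i] + rng.normal(0, 0.6, 3)
        else:
            kind = kinds[rng.integers(0, len(kinds))]
            anchor = rng.uniform(-6, 6, 3)
        perceived.append(PerceivedFeature(kind, tuple(anchor), (i,)))
    heavy = rng.uniform(-6, 6, (max(n_ligand_features, 4), 3))
    return hyp, perceived, heavy


class TestPerception:
    def test_hydroxamate_anion_has_all_four_feature_kinds(self):
        mol = embed("[O-]NC(=O)c1ccccc1")
        kinds = {f.kind for f in perceive_features(mol)}
        assert {"acceptor", "donor", "negative", "aromatic"} <= kinds

    def test_methane_has_no_features(self):
        mol = embed("C")
        assert perceive_features(mol) == []

    def test_counts_match_hand_enumeration(self):
        # (smiles, expected counts per kind)
        cases = [
            ("c1ccccc1", {"aromatic": 1}),
            ("c1ccncc1", {"aromatic": 1, "acceptor": 1}),
            ("CC(=O)N", {"acceptor": 1, "donor": 1}),
            ("CC(C)C", {"hydrophobic": 1}),
            ("[O-]C(=O)c1ccccc1", {"negative": 1, "acceptor": 1, "aromatic": 1}),
            ("OCC", {"donor": 1}),
            ("C[N+](C)(C)C", {"positive": 1, "hydrophobic": 0}),
            ("COC", {"acceptor": 1}),
            ("CCCC", {"hydrophobic": 2}),
            ("[O-]NC(=O)c1ccccc1", {"negative": 1, "donor": 1, "acceptor": 1,
                                    "aromatic": 1}),
        ]
        for smiles, expected in cases:
            mol = embed(smiles)
            found = perceive_features(mol)
            for kind, n in expected.items():
                got = sum(1 for f in found if f.kind == kind)
                assert got == n, f"{smiles}: {kind} expected {n}, got {got}"

    def test_requires_conformer(self):
        with pytest.raises(ValueError, match="3D"):
            perceive_features(Chem.MolFromSmiles("CCO"))


class TestBuildHypothesis:
    def test_no_shell_atoms_gives_no_volumes(self):
        mol = embed("[O-]NC(=O)c1ccccc1")
        hyp = build_hypothesis(mol, np.zeros((0, 3)),
                               ["acceptor", "donor", "negative", "aromatic"])
        assert len(hyp.features) == 4 and hyp.volumes == []

    def test_shell_atoms_become_volumes(self, rng):
        mol = embed("[O-]NC(=O)c1ccccc1")
        lig = mol.GetConformer().GetPositions()
        # 12 protein atoms placed 3.5-4.5 Å from ligand atoms
        shell = []
        while len(shell) < 12:
            base = lig[rng.integers(0, len(lig))]
            probe = base + rng.normal(0, 1, 3) * 0 + rng.uniform(3.5, 4.5) * _unit(rng)
            if np.linalg.norm(probe - lig, axis=1).min() > 2.0:
                shell.append(probe)
        hyp = build_hypothesis(mol, np.array(shell),
                               ["acceptor", "donor", "negative", "aromatic"])
        assert len(hyp.volumes) == 12
        assert {tuple(np.round(v.center, 6)) for v in hyp.volumes} == {
            tuple(np.round(s, 6)) for s in shell
        }

    def test_missing_pick_is_named(self):
        mol = embed("c1ccccc1")
        with pytest.raises(ValueError, match="negative"):
            build_hypothesis(mol, np.zeros((0, 3)), ["negative"])

    def test_template_pose_yields_four_feature_hypothesis(self, pocket):
        assert len(pocket.hypothesis.features) == 4
        assert [f.kind for f in pocket.hypothesis.features] == [
            "acceptor", "donor", "negative", "aromatic",
        ]


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestMatching:
    def test_identity_geometry_matches_with_zero_rmsd(self, pocket):
        result = match(pocket.template, pocket.hypothesis)
        assert result is not None
        assert result.fit_rmsd < 0.3  # template built the hypothesis anchors

    def test_rigid_transform_invariance(self, pocket, rng):
        mol = Chem.Mol(pocket.template.mol)
        conf = mol.GetConformer()
        rot = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        shift = np.array([10.0, -3.0, 7.0])
        pos = conf.GetPositions() @ rot.T + shift
        for i, p in enumerate(pos):
            conf.SetAtomPosition(i, p.tolist())
        moved = MoleculeRecord("moved", mol)
        base = match(pocket.template, pocket.hypothesis)
        res = match(moved, pocket.hypothesis)
        assert res is not None
        assert res.fit_rmsd == pytest.approx(base.fit_rmsd, abs=1e-6)

    def test_pure_translation_gives_same_fit(self, pocket):
        mol = Chem.Mol(pocket.template.mol)
        conf = mol.GetConformer()
        pos = conf.GetPositions() + np.array([10.0, 0.0, 0.0])
        for i, p in enumerate(pos):
            conf.SetAtomPosition(i, p.tolist())
        res = match(MoleculeRecord("shifted", mol), pocket.hypothesis)
        base = match(pocket.template, pocket.hypothesis)
        assert res.fit_rmsd == pytest.approx(base.fit_rmsd, abs=1e-9)

    def test_zero_feature_hypothesis_is_configuration_error(self, pocket):
        with pytest.raises(ValueError):
            match(pocket.template, PharmacophoreHypothesis([]))

    def test_atom_inside_excluded_volume_removes_match(self, pocket):
        hyp = pocket.hypothesis
        lig = pocket.template.mol.GetConformer().GetPositions()
        clashing = PharmacophoreHypothesis(
            hyp.features, [ExcludedVolume(tuple(lig[5]), 1.2)]
        )
        assert match(pocket.template, clashing) is None

    def test_pruned_search_equals_exhaustive_oracle(self, rng):
        from zincscreen.pharmacophore import _search_assignments

        checked_matches = 0
        for trial in range(40):
            n_f = int(rng.integers(2, 7))
            n_l = int(rng.integers(n_f, 9))
            hyp, perceived, heavy = random_instance(rng, n_f, n_l)
            fit, _ = _search_assignments(hyp, perceived, heavy)
            oracle = oracle_best_fit(hyp, perceived, heavy)
            if oracle is None:
                assert fit is None
            else:
                assert fit == pytest.approx(oracle, abs=1e-9)
                checked_matches += 1
        assert checked_matches >= 5  # instances actually exercised matches

    def test_fit_rmsd_loose_bound(self, campaign):
        hyp = campaign.config.hypothesis
        max_tol = max(f.tolerance for f in hyp.features)
        bound = max_tol * np.sqrt(len(hyp.features))
        _, results = screen(
            [r for r in campaign.records if r.labels["matcher"]], hyp
        )
        assert results
        assert all(res.fit_rmsd <= bound for res in results.values())


class TestScreen:
    def test_empty_library(self, pocket):
        survivors, results = screen([], pocket.hypothesis)
        assert survivors == [] and results == {}

    def test_planted_matchers_recovered_exactly(self, campaign):
        anions = [
            r for r in campaign.records
            if r.labels["anionic"] and not r.labels["ro5_violator"]
        ]
        survivors, results = screen(anions, campaign.config.hypothesis)
        expected = {r.id for r in anions if r.labels["matcher"]}
        assert {r.id for r in survivors} == expected
        assert set(results) == expected


class TestSerialization:
    def test_round_trip_lossless(self, pocket, tmp_path):
        path = tmp_path / "hyp.yaml"
        pocket.hypothesis.save(path)
        back = PharmacophoreHypothesis.load(path)
        assert back.required_count == pocket.hypothesis.required_count
        for a, b in zip(back.features, pocket.hypothesis.features):
            assert a.kind == b.kind
            assert np.allclose(a.center, b.center, atol=1e-6)
            assert a.tolerance == pytest.approx(b.tolerance, abs=1e-6)
        for a, b in zip(back.volumes, pocket.hypothesis.volumes):
            assert np.allclose(a.center, b.center, atol=1e-6)
            assert a.radius == pytest.approx(b.radius, abs=1e-6)

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            Feature("acceptor", (0, 0, 0), tolerance=0.0)
        with pytest.raises(ValueError):
            ExcludedVolume((0, 0, 0), radius=-1.0)
        with pytest.raises(ValueError):
            PharmacophoreHypothesis(
                [Feature("acceptor", (0, 0, 0))], required_count=2
            )
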