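"""Sequence alignment, Kabsch fitting, refinement and local superposition."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import consite as cs
from consite.superposition import rmsd_between

from _oracles import brute_align_score
from conftest import random_rigid_transform


BLOSUM_DIAG = {"H": 8, "E": 5, "A": 4, "G": 6, "W": 11}


class TestAlignSequences:
    def test_identity_alignment(self):
        seq = "HEAGAWGHEE"
        pairs = cs.align_sequences(seq, seq)
        assert pairs == [(i, i) for i in range(len(seq))]
        expected = sum(BLOSUM_DIAG[c] for c in seq)
        assert cs.superposition.alignment_score(seq, seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cs.align_sequences("AAAA", "")

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seq_a = "".join(rng.choice(alphabet, size=7))
        seq_b = "".join(rng.choice(alphabet, size=6))
        got = cs.superposition.alignment_score(seq_a, seq_b)
        assert got == pytest.approx(brute_align_score(seq_a, seq_b))
        pairs = cs.align_sequences(seq_a, seq_b)
        # pairs must be a strictly increasing valid correspondence
        assert all(a2 > a1 and b2 > b1 for (a1, b1), (a2, b2)
                   in zip(pairs, pairs[1:]))
        assert all(0 <= a < 7 and 0 <= b < 6 for a, b in pairs)


class TestKabschFit:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        t, rmsd = cs.kabsch_fit(pts, pts)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        t, rmsd = cs.kabsch_fit(pts, pts + np.array([1.0, 2.0, 3.0]))
        assert rmsd <= 1e-9
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(t.translation, [1, 2, 3], atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_constructed_transform(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=5.0, size=(10, 3))
        true = random_rigid_transform(rng)
        t, rmsd = cs.kabsch_fit(pts, true.apply(pts))
        assert rmsd <= 1e-9
        comp = t.compose(true.inverse())
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(comp.translation, 0.0, atol=1e-6)

    def test_too_few_points(self):
        pts = np.eye(3)[:2]
        with pytest.raises(cs.SuperpositionError):
            cs.kabsch_fit(pts, pts)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(cs.SuperpositionError, match="collinear"):
            cs.kabsch_fit(pts, pts)

    def test_montecarlo_minimality(self):
        rng = np.random.default_rng(42)
        moving = rng.normal(scale=4.0, size=(10, 3))
        fixed = rng.normal(scale=4.0, size=(10, 3))
        t, rmsd = cs.kabsch_fit(moving, fixed)
        assert rmsd <= rmsd_between(moving, fixed)
        for _ in range(200):
            cand = random_rigid_transform(rng)
            # give each candidate rotation its optimal translation
            moved = cand.apply(moving)
            moved += fixed.mean(axis=0) - moved.mean(axis=0)
            assert rmsd_between(moved, fixed) >= rmsd - 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    def test_transform_validity_property(self, seed):
        rng = np.random.default_rng(seed)
        moving = rng.normal(scale=3.0, size=(5, 3))
        fixed = rng.normal(scale=3.0, size=(5, 3))
        t, _ = cs.kabsch_fit(moving, fixed)
        R = t.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-8)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-8)


class TestRefineFit:
    def test_perfect_pairs_one_cycle(self):
        pts = np.random.default_rng(2).normal(size=(10, 3))
        res = cs.refine_fit(pts, pts, [(i, i) for i in range(10)])
        assert res.cycles_run == 1
        assert res.n_pairs_final == 10
        assert res.rmsd <= 1e-9

    def test_single_outlier_rejected(self):
        rng = np.random.default_rng(3)
        fixed = rng.normal(scale=5.0, size=(11, 3))
        moving = fixed.copy()
        moving[5] += np.array([10.0, 0.0, 0.0])
        res = cs.refine_fit(fixed, moving, [(i, i) for i in range(11)])
        assert res.n_pairs_final == 10
        assert (5, 5) not in res.pairs
        assert res.rmsd <= 1e-6
        assert res.cycles_run == 2

    def test_all_displaced_keeps_initial_fit(self):
        rng = np.random.default_rng(4)
        fixed = rng.normal(scale=5.0, size=(6, 3))
        moving = fixed + rng.normal(scale=6.0, size=(6, 3))
        params = cs.SuperpositionParams(reject_cutoff=0.01)
        res = cs.refine_fit(fixed, moving, [(i, i) for i in range(6)],
                            params)
        assert res.n_pairs_final == res.n_pairs_initial == 6
        assert res.cycles_run == 1

    def test_too_few_pairs(self):
        pts = np.eye(3)
        with pytest.raises(cs.SuperpositionError):
            cs.refine_fit(pts, pts, [(0, 0), (1, 1)])

    def test_rmsd_never_increases_across_cycles(self):
        rng = np.random.default_rng(5)
        fixed = rng.normal(scale=6.0, size=(30, 3))
        moving = fixed + rng.normal(scale=0.8, size=(30, 3))
        params = cs.SuperpositionParams(reject_cutoff=1.0)
        baseline_rmsd = cs.kabsch_fit(moving, fixed)[1]
        res = cs.refine_fit(fixed, moving, [(i, i) for i in range(30)],
                            params)
        assert res.rmsd <= baseline_rmsd + 1e-12


class TestSuperposeWhole:
    def test_exact_copy_gives_identity(self, small_family):
        q = small_family.query
        res = cs.superpose_whole(q, "A", q, "A")
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.transform.rotation, np.eye(3),
                                   atol=1e-6)
        np.testing.assert_allclose(res.transform.translation, 0.0,
                                   atol=1e-6)

    def test_rigidly_moved_copy_inverted(self, small_family):
        rng = np.random.default_rng(6)
        q = small_family.query
        moved_t = random_rigid_transform(rng)
        moved = cs.StructureModel(
            "MOV", {"A": cs.apply_transform(moved_t, q.chains["A"])})
        res = cs.superpose_whole(q, "A", moved, "A")
        assert res.rmsd <= 1e-6
        comp = res.transform.compose(moved_t)
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(comp.translation, 0.0, atol=1e-5)

    def test_noise_model_rmsd_band(self):
        # per-coordinate sigma -> pair rmsd concentrates near sigma*sqrt(3)
        sigma = 0.3
        hits = 0
        for seed in range(20):
            fam = cs.make_family(cs.FamilySpec(
                n_members=2, base_length=60, ca_noise=sigma,
                mutation_rate=0.1, planted_sites=(), decoys_per_member=0,
                seed=600 + seed))
            res = cs.superpose_whole(fam.query, "A", fam.homologs[0], "A")
            band = sigma * np.sqrt(3.0)
            hits += (0.7 * band <= res.rmsd <= 1.3 * band
                     and res.n_pairs_final >= 0.9 * res.n_pairs_initial)
        assert hits >= 18

    def test_equivariance_under_query_motion(self, small_family):
        rng = np.random.default_rng(7)
        q = small_family.query
        h = small_family.homologs[0]
        base = cs.superpose_whole(q, "A", h, "A")
        motion = random_rigid_transform(rng)
        moved_q = cs.StructureModel(
            "QM", {"A": cs.apply_transform(motion, q.chains["A"])})
        res = cs.superpose_whole(moved_q, "A", h, "A")
        expected = motion.compose(base.transform)
        np.testing.assert_allclose(res.transform.rotation,
                                   expected.rotation, atol=1e-5)
        np.testing.assert_allclose(res.transform.translation,
                                   expected.translation, atol=1e-4)

    def test_insufficient_correspondence(self):
        def chain(n, offset=0.0):
            return [cs.AtomRecord(i + 1, "CA", "", "ALA", "A", i + 1, "",
                                  np.array([3.8 * i, offset, 0.1 * i ** 2]),
                                  1.0, "C", False) for i in range(n)]
        tiny = cs.StructureModel("T", {"A": chain(2)})
        other = cs.StructureModel("U", {"A": chain(2, offset=1.0)})
        with pytest.raises(cs.SuperpositionError):
            cs.superpose_whole(tiny, "A", other, "A")


class TestSiteFragment:
    def _query_with_site(self, family):
        return family.query

    def test_fragment_matches_bruteforce(self, small_family):
        q = small_family.query
        site = cs.SiteSpec("ZN", "A", 1001)
        radius = 12.0
        frag = cs.select_site_fragment(q, site, radius)
        site_xyz = np.array([a.coord for a in q.chains["A"]
                             if a.is_het and a.res_name == "ZN"])
        expected = set()
        for atom in q.chains["A"]:
            if atom.is_het:
                continue
            d = np.linalg.norm(site_xyz - atom.coord, axis=1).min()
            if d <= radius:
                expected.add(atom.residue_key)
        got = {a.residue_key for a in frag.atoms()}
        assert got == expected
        assert all(not a.is_het for a in frag.atoms())

    def test_inclusive_radius_boundary(self):
        atoms = [
            cs.AtomRecord(1, "CA", "", "ALA", "A", 1, "",
                          np.array([5.0, 0, 0]), 1.0, "C", False),
            cs.AtomRecord(2, "CA", "", "GLY", "A", 2, "",
                          np.array([12.5, 0, 0]), 1.0, "C", False),
            cs.AtomRecord(3, "ZN", "", "ZN", "A", 101, "",
                          np.zeros(3), 1.0, "ZN", True),
        ]
        model = cs.StructureModel("B", {"A": atoms})
        frag = cs.select_site_fragment(model, cs.SiteSpec("ZN", "A", 101),
                                       12.0)
        kept = {a.res_seq for a in frag.atoms()}
        assert kept == {1}

    def test_missing_site_named_in_error(self, small_family):
        with pytest.raises(cs.SiteNotFoundError, match="MG A 999"):
            cs.select_site_fragment(small_family.query,
                                    cs.SiteSpec("MG", "A", 999), 12.0)


class TestSuperposeLocal:
    def test_exact_copy_identity(self, small_family):
        q = small_family.query
        res = cs.superpose_local(q, "A", cs.SiteSpec("ZN", "A", 1001),
                                 q, "A")
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.transform.rotation, np.eye(3),
                                   atol=1e-6)

    def test_distal_distortion_ignored_locally(self, small_family):
        q = small_family.query
        site = cs.SiteSpec("ZN", "A", 1001)
        site_pos = np.array([0.0, 0.0, 12.0])
        distorted_atoms = []
        for atom in q.chains["A"]:
            coord = atom.coord.copy()
            if not atom.is_het and \
                    np.linalg.norm(coord - site_pos) > 13.0:
                coord = coord + np.array([5.0, 0.0, 0.0])
            distorted_atoms.append(
                cs.AtomRecord(atom.serial, atom.atom_name, atom.alt_loc,
                              atom.res_name, atom.chain_id, atom.res_seq,
                              atom.insertion_code, coord, atom.occupancy,
                              atom.element, atom.is_het))
        distorted = cs.StructureModel("D", {"A": distorted_atoms})
        # single un-refined fit isolates the raw compromise the whole-chain
        # correspondence is forced into
        params = cs.SuperpositionParams(refine_cycles=0)
        local = cs.superpose_local(q, "A", site, distorted, "A", params)
        whole = cs.superpose_whole(q, "A", distorted, "A", params)
        assert local.rmsd <= 1e-6
        assert whole.rmsd > 1.0

    def test_fragment_too_small_suggests_radius(self, small_family):
        params = cs.SuperpositionParams(local_radius=0.5)
        with pytest.raises(cs.SuperpositionError, match="radius"):
            cs.superpose_local(small_family.query, "A",
                               cs.SiteSpec("ZN", "A", 1001),
                               small_family.homologs[0], "A", params)


class TestApplyTransform:
    def test_identity_leaves_coordinates(self, tiny_model):
        atoms = list(tiny_model.atoms())
        out = cs.apply_transform(cs.RigidTransform.identity(), atoms)
        for a, b in zip(atoms, out):
            np.testing.assert_allclose(a.coord, b.coord)
            assert a.res_name == b.res_name

    def test_translation(self):
        t = cs.RigidTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(t.apply(np.zeros(3)), [1.0, 0.0, 0.0])

    def test_quarter_turn_about_z(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = cs.RigidTransform(R, np.zeros(3))
        np.testing.assert_allclose(t.apply(np.array([1.0, 0.0, 0.0])),
                                   [0.0, 1.0, 0.0], atol=1e-9)

    def test_improper_rotation_rejected(self):
        M = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            cs.RigidTransform(M, np.zeros(3))
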