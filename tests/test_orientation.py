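"""Orientation RMSD, clustering, coresets, consensus, frames and the six measures."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from fvorient.geometry import RigidTransform, superpose
from fvorient.orientation import (
    ConsensusDomain,
    build_consensus,
    build_consensus_and_frames,
    build_frame_system,
    compute_measures,
    derive_coresets,
    fit_frame,
    linkage_to_newick,
    orientation_rmsd,
    pairwise_matrix_and_cluster,
)
from fvorient.structures import DomainStructure, FvStructure, Residue, StructureError
from fvorient.synthetic import PoseSpec, make_fv, make_pose_family, scaffold_domain

from .conftest import rigid_motion


def _rotate_domain(domain, axis, angle_deg, pivot):
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis)).as_matrix()
    t = RigidTransform(R, pivot - R @ pivot)
    return domain.transformed(t)


def _with_h_domain(fv, new_h):
    return FvStructure(
        first=new_h, second=fv.second, receptor_class=fv.receptor_class, pdb_id=fv.pdb_id
    )


class TestOrientationRmsd:
    def test_identical_structures_give_zero(self, default_fv):
        fv, _ = default_fv
        assert orientation_rmsd(fv, fv) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_translation_of_one_domain_gives_its_magnitude(self, default_fv):
        fv, _ = default_fv
        shift = RigidTransform(np.eye(3), np.array([1.0, 2.0, 2.0]) * (2.0 / 3.0))  # |v| = 2 A
        y = _with_h_domain(fv, fv.first.transformed(shift))
        assert orientation_rmsd(fv, y) == pytest.approx(2.0, abs=1e-6)

    def test_rotation_case_matches_literal_recipe_oracle(self, default_fv):
        """Ten-degree domain rotation: value equals a step-by-step recomputation
        of the bidirectional recipe built on Biopython's SVD superimposer."""
        from Bio.SVDSuperimposer import SVDSuperimposer

        fv, _ = default_fv
        h_ca = np.array([r.ca for r in fv.first.residues])
        y = _with_h_domain(
            fv, _rotate_domain(fv.first, [0.0, 0.0, 1.0], 10.0, h_ca.mean(axis=0))
        )

        shared_h = sorted(fv.first.present_framework() & y.first.present_framework())
        shared_l = sorted(fv.second.present_framework() & y.second.present_framework())

        def direction(a, b, anchor_pos, other_pos, anchor, other):
            sup = SVDSuperimposer()
            sup.set(
                a.domain(anchor).ca_array(anchor_pos),
                b.domain(anchor).ca_array(anchor_pos),
            )
            sup.run()
            rot, tran = sup.get_rotran()
            moved = b.domain(other).ca_array(other_pos) @ rot + tran
            sup2 = SVDSuperimposer()
            sup2.set(a.domain(other).ca_array(other_pos), moved)
            sup2.run()
            rot2, tran2 = sup2.get_rotran()
            fitted = moved @ rot2 + tran2
            return np.sqrt(((moved - fitted) ** 2).sum() / len(moved))

        expected = 0.5 * (
            direction(fv, y, shared_l, shared_h, "L", "H")
            + direction(fv, y, shared_h, shared_l, "H", "L")
        )
        assert orientation_rmsd(fv, y) == pytest.approx(expected, abs=1e-6)

    def test_symmetric_in_arguments(self, pose_families):
        fam_a, fam_b = pose_families
        x, y = fam_a[0], fam_b[0]
        assert orientation_rmsd(x, y) == pytest.approx(orientation_rmsd(y, x), abs=1e-9)

    def test_invariant_under_whole_structure_rigid_motion(self, pose_families):
        fam_a, fam_b = pose_families
        x, y = fam_a[0], fam_b[1]
        d0 = orientation_rmsd(x, y)
        d1 = orientation_rmsd(x.transformed(rigid_motion(9)), y.transformed(rigid_motion(10)))
        assert d0 == pytest.approx(d1, abs=1e-9)

    def test_insufficient_shared_positions_named_in_error(self, default_fv):
        fv, _ = default_fv
        small = DomainStructure(residues=fv.first.residues[:10], domain_type="VB")
        y = _with_h_domain(fv, small)
        with pytest.raises(StructureError, match="shared"):
            orientation_rmsd(fv, y)


class TestClustering:
    def test_two_pose_families_perfectly_recovered(self, pose_families):
        fam_a, fam_b = pose_families
        res = pairwise_matrix_and_cluster(fam_a + fam_b, k=2)
        a_labels = set(res.cluster_labels[: len(fam_a)])
        b_labels = set(res.cluster_labels[len(fam_a) :])
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_single_structure_degenerates_gracefully(self, default_fv):
        fv, _ = default_fv
        res = pairwise_matrix_and_cluster([fv])
        assert list(res.cluster_labels) == [1]
        assert res.linkage_matrix is None
        assert res.newick().endswith(";")

    def test_merge_heights_match_brute_force_complete_linkage(self):
        rng = np.random.default_rng(17)
        d = rng.uniform(1.0, 10.0, size=(6, 6))
        D = np.triu(d, 1) + np.triu(d, 1).T

        # O(n^3) agglomeration oracle
        clusters = [frozenset([i]) for i in range(6)]
        heights = []
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    h = max(D[a, b] for a in clusters[i] for b in clusters[j])
                    if best is None or h < best[0]:
                        best = (h, i, j)
            h, i, j = best
            heights.append(h)
            merged = clusters[i] | clusters[j]
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]

        Z = linkage(squareform(D, checks=False), method="complete")
        assert np.allclose(sorted(Z[:, 2]), sorted(heights))

    def test_newick_contains_all_labels(self, pose_families):
        fam_a, _ = pose_families
        res = pairwise_matrix_and_cluster(fam_a[:5], k=2)
        nwk = res.newick()
        for label in res.labels:
            assert label in nwk


def _jittered_scaffold(dtype, chain, seed, sd=0.0, jitter_position=None, jitter_sd=5.0,
                       drop=()):
    base = scaffold_domain(dtype, chain)
    rng = np.random.default_rng(seed)
    residues = []
    for r in base.residues:
        if r.imgt_position in drop:
            continue
        ca = r.ca + (rng.normal(0, sd, 3) if sd else 0.0)
        if jitter_position is not None and r.imgt_position == jitter_position:
            ca = ca + rng.normal(0, jitter_sd, 3)
        residues.append(
            Residue(chain, r.author_number, r.amino_acid, ca, ca, imgt_position=r.imgt_position)
        )
    return DomainStructure(residues=tuple(residues), domain_type=dtype)


class TestCoresets:
    def test_identical_ensemble_retains_all_qualifying_positions(self):
        ens = [_jittered_scaffold("VA", "A", i) for i in range(5)]
        core = derive_coresets(ens)
        assert core.positions == ens[0].present_framework()

    def test_high_spread_position_excluded(self):
        ens = [
            _jittered_scaffold("VA", "A", i, sd=0.05, jitter_position=20) for i in range(8)
        ]
        core = derive_coresets(ens)
        assert 20 not in core.positions
        assert max(core.spreads.values()) <= 1.0

    def test_low_presence_position_excluded_before_iteration(self):
        ens = [_jittered_scaffold("VA", "A", i) for i in range(9)]
        ens.append(_jittered_scaffold("VA", "A", 9, drop=(45,)))  # present in 90% only
        core = derive_coresets(ens)
        assert 45 not in core.positions

    def test_small_ensemble_rejected(self):
        ens = [_jittered_scaffold("VA", "A", i) for i in range(3)]
        with pytest.raises(StructureError, match=">= 5"):
            derive_coresets(ens)


class TestConsensusAndFrames:
    def test_identical_ensemble_consensus_equals_member(self):
        ens = [_jittered_scaffold("VA", "A", i) for i in range(5)]
        core = derive_coresets(ens)
        cons = build_consensus(ens, core)
        member = ens[0]
        for p in cons.positions:
            assert np.abs(cons.coord(p) - member.get(p).ca).max() < 1e-6

    def test_two_member_consensus_is_aligned_midpoint(self):
        m1 = _jittered_scaffold("VA", "A", 1)
        m2 = _jittered_scaffold("VA", "A", 2, sd=0.1)
        core = derive_coresets([m1, m2, m1, m2, m1])
        cons = build_consensus([m1, m2], core)
        positions = sorted(core.positions)
        T, _ = superpose(m2.ca_array(positions), m1.ca_array(positions))
        midpoint = 0.5 * (m1.ca_array(positions) + T.apply(m2.ca_array(positions)))
        _, rmsd = superpose(cons.ca_array(positions), midpoint)
        assert rmsd < 1e-6

    def test_frame_vectors_orthonormal(self):
        ens = {
            "H": [_jittered_scaffold("VB", "B", i) for i in range(5)],
            "L": [_jittered_scaffold("VA", "A", i) for i in range(5)],
        }
        fs = build_consensus_and_frames(ens)
        for side in ("H", "L"):
            f = fs.frames[side]
            assert abs(np.linalg.norm(f.e1) - 1) < 1e-9
            assert abs(np.linalg.norm(f.e2) - 1) < 1e-9
            assert abs(f.e1 @ f.e2) < 1e-9

    def test_missing_sign_anchor_is_error(self):
        dom = _jittered_scaffold("VA", "A", 0, drop=(104,))
        cons = ConsensusDomain(
            "VA",
            tuple(sorted(dom.positions())),
            np.array([dom.get(p).ca for p in sorted(dom.positions())]),
        )
        with pytest.raises(StructureError, match="anchor"):
            fit_frame(cons, frozenset(range(38, 51)) | frozenset(range(87, 105)))


class TestComputeMeasures:
    def test_reference_pose_reproduces_stored_reference_values(self, pose_families):
        fam_a, _ = pose_families
        fs = build_frame_system(fam_a[:6])
        ref = fs.consensus_fv(fam_a[0])
        m = compute_measures(ref, fs)
        assert np.allclose(m.as_array(), fs.reference_measures.as_array(), atol=1e-9)

    def test_rotation_about_pivot_shifts_only_the_torsion(self, default_fv, frame_system):
        fv, truth = default_fv
        frame_h, _ = frame_system.register("H", fv.first)
        frame_l, _ = frame_system.register("L", fv.second)
        c_axis = frame_h.origin - frame_l.origin
        c_axis = c_axis / np.linalg.norm(c_axis)
        rotated = _rotate_domain(fv.first, c_axis, 10.0, frame_l.origin)
        m = compute_measures(_with_h_domain(fv, rotated), frame_system)
        assert m.HL == pytest.approx(truth["HL"] + 10.0, abs=1e-6)
        assert m.dc == pytest.approx(truth["dc"], abs=1e-6)
        assert m.HC1 == pytest.approx(truth["HC1"], abs=1e-6)
        assert m.HC2 == pytest.approx(truth["HC2"], abs=1e-6)

    def test_translation_along_pivot_changes_only_dc(self, default_fv, frame_system):
        fv, truth = default_fv
        frame_h, _ = frame_system.register("H", fv.first)
        frame_l, _ = frame_system.register("L", fv.second)
        c_axis = frame_h.origin - frame_l.origin
        c_axis = c_axis / np.linalg.norm(c_axis)
        shifted = fv.first.transformed(RigidTransform(np.eye(3), c_axis))
        m = compute_measures(_with_h_domain(fv, shifted), frame_system)
        assert m.dc == pytest.approx(truth["dc"] + 1.0, abs=1e-6)
        for name in ("HL", "HC1", "HC2", "LC1", "LC2"):
            assert getattr(m, name) == pytest.approx(truth[name], abs=1e-6)

    def test_invariant_under_whole_query_rigid_motion(self, default_fv, frame_system):
        fv, _ = default_fv
        m0 = compute_measures(fv, frame_system)
        m1 = compute_measures(fv.transformed(rigid_motion(77)), frame_system)
        assert np.abs(m0.as_array() - m1.as_array()).max() < 1e-6

    @pytest.mark.parametrize("varied", ["HC2", "HL"])
    def test_rmsd_correlates_with_measure_space_distance(self, frame_system, varied):
        """Orientation RMSD rank-agrees with measure-space distance for small
        perturbations of one measure.  (Each measure displaces atoms with a
        different leverage, so an equal-weight Euclidean norm over jointly
        perturbed measures is not expected to rank-match the RMSD.)"""
        rng = np.random.default_rng(5)
        fam = []
        for i in range(12):
            kw = {varied: getattr(PoseSpec(), varied) + rng.normal(0.0, 2.0)}
            fv, _ = make_fv(PoseSpec(**kw), pdb_id=f"p{i}")
            fam.append(fv)
        measures = np.array([compute_measures(fv, frame_system).as_array() for fv in fam])
        rmsds, euclid = [], []
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                rmsds.append(orientation_rmsd(fam[i], fam[j]))
                euclid.append(np.linalg.norm(measures[i] - measures[j]))
        rho = spearmanr(rmsds, euclid).statistic
        assert rho >= 0.9
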