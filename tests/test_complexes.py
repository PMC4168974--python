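"""Docking angle, orientation grafting and steric clash/contact counting."""

import numpy as np
import pytest

from fvorient.complexes import (
    CB_CLASH_CUTOFF,
    CONTACT_CUTOFF,
    MissingAnchorError,
    contact_pairs,
    count_clashes,
    docking_angle,
    graft_orientation,
)
from fvorient.geometry import RigidTransform
from fvorient.structures import (
    DomainStructure,
    FvStructure,
    PMHCComplex,
    Residue,
    StructureError,
)
from fvorient.synthetic import PoseSpec, make_fv, make_pmhc, make_twist_decoys

from .conftest import rigid_motion


def _res(chain, num, aa, ca, cb=None, atoms=None, imgt=None):
    ca = np.asarray(ca, dtype=float)
    cb = ca if cb is None else np.asarray(cb, dtype=float)
    return Residue(chain, num, aa, ca, cb, imgt_position=imgt, atoms=atoms)


class TestDockingAngle:
    @pytest.mark.parametrize("angle", [0.0, 51.4, 90.0, 125.0])
    def test_requested_angle_recovered(self, angle):
        complex_, _ = make_pmhc(angle, seed=3)
        geom = docking_angle(complex_)
        assert geom.angle == pytest.approx(angle, abs=1e-6)
        assert geom.canonical == (40.0 <= angle <= 85.0)

    def test_invariant_under_whole_complex_rigid_motion(self, pmhc_complex):
        complex_, _ = pmhc_complex
        t = rigid_motion(13)
        moved = PMHCComplex(
            receptor=complex_.receptor.transformed(t),
            mhc_chains=tuple(
                tuple(r.transformed(t) for r in chain) for chain in complex_.mhc_chains
            ),
            peptide=tuple(r.transformed(t) for r in complex_.peptide),
            mhc_class=complex_.mhc_class,
        )
        a0 = docking_angle(complex_).angle
        a1 = docking_angle(moved).angle
        assert a0 == pytest.approx(a1, abs=1e-6)

    def test_short_peptide_rejected(self, pmhc_complex):
        complex_, _ = pmhc_complex
        short = PMHCComplex(
            receptor=complex_.receptor,
            mhc_chains=complex_.mhc_chains,
            peptide=complex_.peptide[:2],
            mhc_class="I",
        )
        with pytest.raises(StructureError, match="peptide"):
            docking_angle(short)

    def test_missing_cysteine_anchor_raises_named_error(self, pmhc_complex):
        complex_, _ = pmhc_complex
        second = complex_.receptor.second
        pruned = DomainStructure(
            residues=tuple(r for r in second.residues if r.imgt_position != 104),
            domain_type=second.domain_type,
        )
        broken = PMHCComplex(
            receptor=FvStructure(
                first=complex_.receptor.first,
                second=pruned,
                receptor_class="tcr",
            ),
            mhc_chains=complex_.mhc_chains,
            peptide=complex_.peptide,
            mhc_class="I",
        )
        with pytest.raises(MissingAnchorError, match="104"):
            docking_angle(broken)


class TestGraft:
    def test_identity_graft_reproduces_native(self, pmhc_complex):
        complex_, _ = pmhc_complex
        result = graft_orientation(complex_, complex_.receptor, anchored="L")
        native_h = np.array([r.ca for r in complex_.receptor.first.residues])
        grafted_h = np.array(
            [r.ca for r in result.grafted_complex.receptor.first.residues]
        )
        assert np.abs(native_h - grafted_h).max() < 1e-6
        assert count_clashes(result.grafted_complex) == count_clashes(complex_)

    def test_anchored_domain_never_moves(self, pmhc_complex):
        complex_, _ = pmhc_complex
        decoy, _ = make_fv(PoseSpec(HC2=100.0, seed=4))
        result = graft_orientation(complex_, decoy, anchored="L")
        nat = np.array([r.ca for r in complex_.receptor.second.residues])
        kept = np.array([r.ca for r in result.grafted_complex.receptor.second.residues])
        assert np.abs(nat - kept).max() < 1e-9

    def test_translated_decoy_displaces_partner_and_adds_clashes(self, pmhc_complex):
        complex_, _ = pmhc_complex
        native = complex_.receptor
        down = RigidTransform(np.eye(3), np.array([0.0, 0.0, -3.0]))
        decoy = FvStructure(
            first=native.first.transformed(down),
            second=native.second,
            receptor_class="tcr",
            pdb_id="pushed",
        )
        result = graft_orientation(complex_, decoy, anchored="L")
        nat_h = np.array([r.ca for r in native.first.residues])
        new_h = np.array([r.ca for r in result.grafted_complex.receptor.first.residues])
        assert np.allclose(new_h - nat_h, [0.0, 0.0, -3.0], atol=1e-6)
        native_counts = count_clashes(complex_)
        assert result.clashes_moved_domain > native_counts["H"]

    def test_role_symmetry_when_anchoring_h_side(self, pmhc_complex):
        complex_, _ = pmhc_complex
        decoy, _ = make_fv(PoseSpec(HC2=100.0, seed=4))
        result = graft_orientation(complex_, decoy, anchored="H")
        assert result.moved_domain == "VA"
        assert result.anchored_domain == "VB"
        nat = np.array([r.ca for r in complex_.receptor.first.residues])
        kept = np.array([r.ca for r in result.grafted_complex.receptor.first.residues])
        assert np.abs(nat - kept).max() < 1e-9

    def test_graft_preserves_internal_chain_geometry(self, pmhc_complex):
        complex_, _ = pmhc_complex
        decoy, _ = make_fv(PoseSpec(HL=-80.0, HC2=105.0, seed=6))
        result = graft_orientation(complex_, decoy, anchored="L")
        for dom_native, dom_grafted in zip(
            complex_.receptor.domains, result.grafted_complex.receptor.domains
        ):
            a = np.array([r.ca for r in dom_native.residues])
            b = np.array([r.ca for r in dom_grafted.residues])
            da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            assert np.abs(da - db).max() < 1e-6

    def test_twist_decoys_monotonically_increase_clashes(self, pmhc_complex):
        complex_, _ = pmhc_complex
        counts = []
        for twist, decoy in make_twist_decoys(complex_, [0.0, 10.0, 20.0, 30.0]):
            result = graft_orientation(complex_, decoy, anchored="L")
            counts.append(result.clashes_moved_domain)
        assert counts[0] == 0
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] > 0


class TestClashCounting:
    def _pmhc_from_residues(self, receptor_h, env):
        """Minimal complex: H-side domain with the given residues, trivial L."""
        l_res = tuple(
            _res("A", i + 1, "A", [50.0 + 4 * i, 50.0, 50.0], imgt=i + 1) for i in range(3)
        )
        h_dom = DomainStructure(residues=tuple(receptor_h), domain_type="VB")
        l_dom = DomainStructure(residues=l_res, domain_type="VA")
        fv = FvStructure(first=h_dom, second=l_dom, receptor_class="tcr")
        pep = tuple(env) or (_res("P", 1, "A", [0, 0, 0]),)
        return PMHCComplex(receptor=fv, mhc_chains=(), peptide=pep, mhc_class="I")

    def test_distant_residues_do_not_clash(self):
        c = self._pmhc_from_residues(
            [_res("B", 1, "A", [0, 0, 10.0], imgt=1)], [_res("P", 1, "A", [0, 0, 0])]
        )
        assert count_clashes(c) == {"H": 0, "L": 0}

    def test_multiple_overlapping_atom_pairs_count_once(self):
        atoms_a = tuple(("C" + s, "C", np.array([0.0, 0.0, float(i)])) for i, s in enumerate("ABG"))
        atoms_b = tuple(("C" + s, "C", np.array([0.5, 0.0, float(i)])) for i, s in enumerate("ABG"))
        r1 = _res("B", 1, "A", [0, 0, 0], atoms=atoms_a, imgt=1)
        r2 = _res("P", 1, "A", [0.5, 0, 0], atoms=atoms_b)
        c = self._pmhc_from_residues([r1], [r2])
        assert count_clashes(c)["H"] == 1

    @pytest.mark.parametrize(
        "separation,expected",
        [(2 * 1.70 - 0.5, 1), (2 * 1.70 - 0.3, 0)],
        ids=["overlap-0.5A", "overlap-0.3A"],
    )
    def test_vdw_overlap_threshold(self, separation, expected):
        """Carbon-carbon pairs clash at >= 0.4 A overlap of summed radii."""
        atoms_a = (("CG1", "C", np.array([0.0, 0.0, 0.0])), ("CG2", "C", np.array([0.0, 3.0, 0.0])))
        atoms_b = (("CG1", "C", np.array([separation, 0.0, 0.0])), ("CG2", "C", np.array([separation, 3.0, 0.0])))
        r1 = _res("B", 1, "V", [0, 0, 0], atoms=atoms_a, imgt=1)
        r2 = _res("P", 1, "V", [separation, 0, 0], atoms=atoms_b)
        c = self._pmhc_from_residues([r1], [r2])
        assert count_clashes(c)["H"] == expected

    def test_reduced_residues_use_cb_fallback(self):
        r1 = _res("B", 1, "A", [0, 0, 0], cb=[0, 0, 0], imgt=1)
        near = _res("P", 1, "A", [CB_CLASH_CUTOFF - 0.1, 0, 0])
        far = _res("P", 2, "A", [CB_CLASH_CUTOFF + 0.1, 0, 0])
        assert count_clashes(self._pmhc_from_residues([r1], [near]))["H"] == 1
        assert count_clashes(self._pmhc_from_residues([r1], [far]))["H"] == 0


class TestContacts:
    def test_cutoff_is_strict_less_than_seven(self):
        r1 = _res("B", 1, "A", [0, 0, 0], cb=[0, 0, 0], imgt=1)
        included = _res("P", 1, "A", [6.9, 0, 0])
        excluded = _res("P", 2, "A", [7.1, 0, 0])
        dom = DomainStructure(residues=(r1,), domain_type="VB")
        l_dom = DomainStructure(
            residues=(_res("A", 1, "A", [50, 50, 50], imgt=1),), domain_type="VA"
        )
        fv = FvStructure(first=dom, second=l_dom, receptor_class="tcr")
        c = PMHCComplex(
            receptor=fv, mhc_chains=(), peptide=(included, excluded), mhc_class="I"
        )
        pairs = contact_pairs(c)
        partners = {p[1].author_number for p in pairs if p[0].chain_id == "B"}
        assert partners == {1}

    def test_glycine_uses_ca_as_cb(self):
        gly = _res("B", 1, "G", [0, 0, 0], cb=[0, 0, 0], imgt=1)
        assert np.allclose(gly.cb, gly.ca)
        partner = _res("P", 1, "A", [6.5, 0, 0])
        dom = DomainStructure(residues=(gly,), domain_type="VB")
        l_dom = DomainStructure(
            residues=(_res("A", 1, "A", [50, 50, 50], imgt=1),), domain_type="VA"
        )
        fv = FvStructure(first=dom, second=l_dom, receptor_class="tcr")
        c = PMHCComplex(receptor=fv, mhc_chains=(), peptide=(partner,), mhc_class="I")
        assert any(p[0].chain_id == "B" for p in contact_pairs(c))

    def test_counts_match_all_pairs_brute_force(self, pmhc_complex):
        complex_, _ = pmhc_complex
        pairs = contact_pairs(complex_)
        env = complex_.environment_residues()
        brute = 0
        for dom in complex_.receptor.domains:
            for r in dom.residues:
                for e in env:
                    if np.linalg.norm(r.cb - e.cb) < CONTACT_CUTOFF:
                        brute += 1
        assert len(pairs) == brute
        dists = [p[2] for p in pairs]
        assert dists == sorted(dists)
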