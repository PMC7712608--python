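"""Backbone builder, torsion extraction and superposition RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rdcfold.constants import BOND_ANGLES, BOND_LENGTHS
from rdcfold.errors import DataError, FormatError, ValidationError
from rdcfold.geometry import (ATOM_INDEX, Structure, bb_rmsd, build_chain,
                              extend_fragment, extract_torsions,
                              internuclear_vector, read_pdb, write_pdb)

from conftest import random_rotation


# ---------------------------------------------------------------------------
# independent chain-builder oracle: sequential rotation-matrix frames,
# a different construction from the NeRF used by the implementation.

def oracle_backbone(n_res, phi, psi):
    """N/CA/C'/O coordinates from explicit frame rotations."""
    names = []
    bonds = []
    angles = []  # angle at previous atom (deg)
    torsions = []
    for i in range(n_res):
        if i == 0:
            names += ["N", "CA", "C"]
        else:
            names += ["N", "CA", "C"]
            bonds += [BOND_LENGTHS[("C", "N")], BOND_LENGTHS[("N", "CA")],
                      BOND_LENGTHS[("CA", "C")]]
            angles += [BOND_ANGLES[("CA", "C", "N")],
                       BOND_ANGLES[("C", "N", "CA")],
                       BOND_ANGLES[("N", "CA", "C")]]
            torsions += [psi, 180.0, phi]
    # seed triad
    pts = [np.zeros(3), np.array([BOND_LENGTHS[("N", "CA")], 0, 0])]
    th = math.radians(BOND_ANGLES[("N", "CA", "C")])
    pts.append(pts[1] + BOND_LENGTHS[("CA", "C")]
               * np.array([-math.cos(th), math.sin(th), 0]))
    for bond, ang, tor in zip(bonds, angles, torsions):
        a, b, c = pts[-3], pts[-2], pts[-1]
        u = (c - b) / np.linalg.norm(c - b)
        n = np.cross(b - a, u)
        n /= np.linalg.norm(n)
        # start along the extension of b->c, bend by (180 - ang) about the
        # plane normal, then twist by the torsion about the bond axis
        d = Rotation.from_rotvec(np.radians(tor) * u).apply(
            Rotation.from_rotvec(np.radians(180.0 - ang) * n).apply(u))
        pts.append(c + bond * d)
    coords = np.array(pts).reshape(n_res, 3, 3)
    # carbonyl O in the peptide plane, anti to the next N
    o = []
    th_o = BOND_ANGLES[("CA", "C", "O")]
    for i in range(n_res - 1):
        ca, cp, nn = coords[i, 1], coords[i, 2], coords[i + 1, 0]
        u1 = (ca - cp) / np.linalg.norm(ca - cp)
        u2 = (nn - cp) / np.linalg.norm(nn - cp)
        # in-plane direction at the O angle from CA, away from N
        nrm = np.cross(u1, u2)
        nrm /= np.linalg.norm(nrm)
        d = Rotation.from_rotvec(-np.radians(th_o) * nrm).apply(u1)
        o.append(cp + BOND_LENGTHS[("C", "O")] * d)
    return coords, np.array(o)


class TestBuildChain:
    @pytest.mark.parametrize("torsions", [
        [(-60.0, -45.0)] * 8,
        [(-120.0, 120.0)] * 8,
        [(-60.0, -45.0), (-75.0, -15.0), (55.0, 40.0), (-120.0, 120.0),
         (-90.0, 0.0), (-65.0, -40.0), (180.0, 180.0), (-60.0, -45.0)],
    ])
    def test_torsion_round_trip(self, torsions):
        full = [(None, None)] + torsions + [(None, None)]
        s = build_chain("ADEGKLVSQR", full)
        got = extract_torsions(s)
        for want, have in zip(torsions, got[1:-1]):
            assert have.phi == pytest.approx(want[0], abs=1e-9)
            assert have.psi == pytest.approx(want[1], abs=1e-9)

    def test_bonded_geometry_and_no_drift(self):
        s = build_chain("A" * 100,
                        [(None, None)] + [(-60.0, -45.0)] * 98
                        + [(None, None)])
        c = s.coords
        for (a_res, a_at), (b_res, b_at), ref in [
                ((0, "N"), (0, "CA"), BOND_LENGTHS[("N", "CA")]),
                ((0, "CA"), (0, "C"), BOND_LENGTHS[("CA", "C")]),
                ((0, "C"), (0, "O"), BOND_LENGTHS[("C", "O")]),
                ((0, "N"), (0, "H"), BOND_LENGTHS[("N", "H")]),
                ((0, "CA"), (0, "HA"), BOND_LENGTHS[("CA", "HA")])]:
            d = np.linalg.norm(
                c[a_res:, ATOM_INDEX[a_at]] - c[b_res:, ATOM_INDEX[b_at]],
                axis=1)
            assert np.all(np.abs(d - ref) < 1e-6)
        peptide = np.linalg.norm(c[1:, ATOM_INDEX["N"]]
                                 - c[:-1, ATOM_INDEX["C"]], axis=1)
        assert np.all(np.abs(peptide - BOND_LENGTHS[("C", "N")]) < 1e-6)

    def test_helix_h_bond_geometry_matches_oracle(self):
        """12-residue poly-Ala helix: O(i)..N(i+4) in the H-bond range,
        and every backbone atom agrees with the independent
        rotation-matrix builder."""
        s = build_chain("A" * 12, [(None, -45.0)] + [(-60.0, -45.0)] * 10
                        + [(-60.0, None)])
        ref, ref_o = oracle_backbone(12, -60.0, -45.0)
        got = s.coords[:, [ATOM_INDEX["N"], ATOM_INDEX["CA"],
                           ATOM_INDEX["C"]], :]
        assert np.allclose(got, ref, atol=1e-8)
        assert np.allclose(s.coords[:-1, ATOM_INDEX["O"]], ref_o, atol=1e-8)
        for i in range(8):
            d = np.linalg.norm(s.coords[i, ATOM_INDEX["O"]]
                               - s.coords[i + 4, ATOM_INDEX["N"]])
            assert 2.7 <= d <= 3.3

    def test_strand_ca_ca_matches_oracle(self):
        s = build_chain("A" * 6, [(None, 120.0)] + [(-120.0, 120.0)] * 4
                        + [(-120.0, None)])
        ref, _ = oracle_backbone(6, -120.0, 120.0)
        assert np.allclose(
            s.coords[:, [ATOM_INDEX["N"], ATOM_INDEX["CA"],
                         ATOM_INDEX["C"]], :], ref, atol=1e-8)
        ca = s.coords[:, ATOM_INDEX["CA"]]
        dist = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(dist - 3.8) < 0.1)

    def test_errors(self):
        with pytest.raises(FormatError):
            build_chain("AXA", [(None, None)] * 3)
        with pytest.raises(ValidationError):
            build_chain("AAA", [(None, None), (-200.0, 0.0), (None, None)])
        with pytest.raises(ValidationError):
            build_chain("AAA", [(None, None)] * 2)

    def test_proline_has_no_amide_h_glycine_has_ha(self):
        s = build_chain("APG", [(None, None), (-70.0, 150.0), (None, None)])
        assert not s.has_atom(2, "H")
        assert s.has_atom(3, "HA") and s.has_atom(3, "H")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(-179.9, 180.0), st.floats(-179.9, 180.0)),
        min_size=1, max_size=6))
    def test_round_trip_property(self, interior):
        seq = "A" * (len(interior) + 2)
        s = build_chain(seq, [(None, None)] + list(interior) + [(None, None)])
        got = extract_torsions(s)[1:-1]
        for want, have in zip(interior, got):
            assert math.isclose(have.phi, want[0], abs_tol=1e-8)
            assert math.isclose(have.psi, want[1], abs_tol=1e-8)


class TestExtendFragment:
    def test_fold_equivalence_and_locality(self):
        torsions = [(None, None), (-60.0, -45.0), (-120.0, 120.0),
                    (-75.0, -15.0), (None, None)]
        whole = build_chain("ADKLE", torsions)
        grown = build_chain("A", [torsions[0]])
        for letter, tp in zip("DKLE", torsions[1:]):
            grown = extend_fragment(grown, letter, tp)
        assert np.allclose(whole.coords, grown.coords, atol=1e-9,
                           equal_nan=True)

        a = extend_fragment(whole, "A", (-60.0, -45.0))
        b = extend_fragment(whole, "A", (-120.0, 120.0))
        # prefix untouched, only the appended residue differs
        assert np.array_equal(a.coords[:5], whole.coords)
        assert np.array_equal(b.coords[:5], whole.coords)
        assert not np.allclose(a.coords[5], b.coords[5], equal_nan=True)

    def test_appended_torsions_recovered(self):
        s = build_chain("AA", [(None, None), (None, None)])
        s = extend_fragment(s, "A", (-63.0, -41.0))
        s = extend_fragment(s, "A", (57.0, 44.0))
        tor = extract_torsions(s)
        # the appended pair is recovered exactly once the following plane
        # pins psi; the final psi only orients the terminal O
        assert tor[2].phi == pytest.approx(-63.0, abs=1e-9)
        assert tor[2].psi == pytest.approx(-41.0, abs=1e-9)
        assert tor[3].phi == pytest.approx(57.0, abs=1e-9)

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValidationError):
            extend_fragment(Structure("", np.zeros((0, 6, 3))), "A",
                            (-60.0, -45.0))


class TestExtractTorsions:
    def test_rigid_motion_invariance(self, rng):
        s = build_chain("ADKLEQ", [(None, None)] + [(-60.0, -45.0)] * 4
                        + [(None, None)])
        r = random_rotation(rng)
        moved = Structure(s.sequence, s.coords @ r.T + rng.normal(size=3))
        a = extract_torsions(s)
        b = extract_torsions(moved)
        for x, y in zip(a, b):
            if not math.isnan(x.phi):
                assert y.phi == pytest.approx(x.phi, abs=1e-9)

    def test_collinear_atoms_raise(self):
        coords = np.full((2, 6, 3), np.nan)
        # N, CA, C of residue 1 and N of residue 2 all on the x axis
        for i, (res, at) in enumerate([(0, "N"), (0, "CA"), (0, "C"),
                                       (1, "N"), (1, "CA"), (1, "C")]):
            coords[res, ATOM_INDEX[at]] = [float(i), 0.0, 0.0]
        with pytest.raises(DataError):
            extract_torsions(Structure("AA", coords))

    def test_missing_backbone_atom_raises(self):
        s = build_chain("AAA", [(None, None)] * 1 + [(-60.0, -45.0)]
                        + [(None, None)])
        s.coords[1, ATOM_INDEX["CA"]] = np.nan
        with pytest.raises(DataError):
            extract_torsions(s)


class TestInternuclearVector:
    def test_unit_norm_and_bond_alignment(self, helix15):
        s = helix15.structure
        v = internuclear_vector(s, 3, "N", 3, "H")
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
        bond = s.atom(3, "H") - s.atom(3, "N")
        cos = v @ (bond / np.linalg.norm(bond))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_new_vector_types_resolvable(self, helix15):
        for pair in [(3, "N", 3, "CA"), (3, "HA", 3, "CA")]:
            v = internuclear_vector(helix15.structure, *pair)
            assert np.isfinite(v).all()
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_atom_name_lists_supported(self, helix15):
        with pytest.raises(ValidationError, match="N, H, CA"):
            internuclear_vector(helix15.structure, 3, "CB", 3, "CA")


class TestBbRmsd:
    def test_identity_symmetry_nonnegative(self, helix15, hairpin12):
        a = helix15.structure
        assert bb_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
        b = build_chain(a.sequence, [(None, None)] + [(-70.0, -35.0)] * 13
                        + [(None, None)])
        assert bb_rmsd(a, b) == pytest.approx(bb_rmsd(b, a), abs=1e-12)
        assert bb_rmsd(a, b) > 0
        with pytest.raises(ValidationError):
            bb_rmsd(a, hairpin12.structure)

    def test_superposition_invariance(self, helix15, rng):
        s = helix15.structure
        moved = Structure(s.sequence,
                          s.coords @ random_rotation(rng).T
                          + rng.normal(scale=5.0, size=3))
        assert bb_rmsd(s, moved) < 1e-9

    def test_three_atom_toys_match_brute_force(self, rng):
        """Kabsch result equals the rotation-space minimum found by a
        coarse grid plus local polish (independent oracle)."""
        for _ in range(2):
            p = rng.normal(size=(3, 3))
            q = rng.normal(size=(3, 3))
            coords_a = np.full((1, 6, 3), np.nan)
            coords_b = np.full((1, 6, 3), np.nan)
            for k, at in enumerate(("N", "CA", "C")):
                coords_a[0, ATOM_INDEX[at]] = p[k]
                coords_b[0, ATOM_INDEX[at]] = q[k]
            got = bb_rmsd(Structure("A", coords_a), Structure("A", coords_b))

            pc = p - p.mean(axis=0)
            qc = q - q.mean(axis=0)

            def cost(rv):
                rot = Rotation.from_rotvec(rv).as_matrix()
                return np.sqrt(np.mean(np.sum((pc @ rot.T - qc) ** 2,
                                              axis=1)))

            best = np.inf
            for a1 in np.radians(np.arange(0, 360, 60)):
                for a2 in np.radians(np.arange(0, 180, 45)):
                    for a3 in np.radians(np.arange(0, 360, 60)):
                        rv = Rotation.from_euler(
                            "zyz", [a1, a2, a3]).as_rotvec()
                        res = minimize(cost, rv, method="Nelder-Mead",
                                       options={"fatol": 1e-12,
                                                "xatol": 1e-10})
                        best = min(best, res.fun)
            assert got == pytest.approx(best, abs=1e-3)


class TestPdbIO:
    def test_round_trip(self, hairpin12, tmp_path):
        path = tmp_path / "s.pdb"
        write_pdb(hairpin12.structure, path)
        back = read_pdb(path)
        assert back.sequence == hairpin12.structure.sequence
        assert np.allclose(back.coords, hairpin12.structure.coords,
                           atol=2e-3, equal_nan=True)

    def test_protons_rebuilt_when_absent(self, helix15, tmp_path):
        s = helix15.structure
        stripped = Structure(s.sequence, s.coords.copy())
        stripped.coords[:, ATOM_INDEX["H"]] = np.nan
        stripped.coords[:, ATOM_INDEX["HA"]] = np.nan
        path = tmp_path / "noh.pdb"
        write_pdb(stripped, path)
        back = read_pdb(path, rebuild_protons=True)
        for i in range(2, len(s)):
            for at in ("H", "HA"):
                ref = s.atom(i, at)
                got = back.atom(i, at)
                assert np.linalg.norm(ref - got) < 5e-3
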