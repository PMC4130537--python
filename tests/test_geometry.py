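import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from abmut.structure import (
    Atom,
    StructureModel,
    dihedral,
    hydrogen_bonds,
    phi_psi,
    ramachandran_code,
    rmsd,
    rmsf,
    superpose,
    takeoff_codes,
    vdw_contacts,
)
from abmut.synthetic import GeometrySpec, generate_toy_complex, generate_toy_trajectory


def _pair(d, elem_a="C", elem_b="C", res_a="ALA", res_b="LIG", name_a="CA", name_b="C1"):
    a = Atom(1, name_a, elem_a, res_a, 1, "A", np.zeros(3))
    b = Atom(2, name_b, elem_b, res_b, 1, "B", np.array([d, 0.0, 0.0]))
    return StructureModel([a]), StructureModel([b])


class TestContacts:
    def test_beyond_cutoff_empty(self):
        assert vdw_contacts(*_pair(5.0), cutoff=4.0) == []

    def test_boundary_is_inclusive(self):
        assert len(vdw_contacts(*_pair(3.999), cutoff=4.0)) == 1
        assert len(vdw_contacts(*_pair(4.0), cutoff=4.0)) == 1

    def test_hydrogens_excluded_by_default(self):
        a, b = _pair(3.0, elem_b="H")
        assert vdw_contacts(a, b) == []
        assert len(vdw_contacts(a, b, include_hydrogens=True)) == 1

    def test_matches_brute_force_oracle(self, toy_complex):
        rec, lig = toy_complex
        got = {
            (r.atom_a.serial, r.atom_b.serial)
            for r in vdw_contacts(rec, lig, cutoff=4.0)
        }
        d = cdist(rec.coords, lig.coords)
        want = {
            (rec.atoms[i].serial, lig.atoms[j].serial)
            for i in range(len(rec))
            for j in range(len(lig))
            if d[i, j] <= 4.0
        }
        assert got == want

    def test_monotone_in_cutoff(self, toy_complex):
        rec, lig = toy_complex
        sizes = [len(vdw_contacts(rec, lig, cutoff=c)) for c in (2.0, 4.0, 6.0, 10.0)]
        assert sizes == sorted(sizes)

    def test_empty_selection_rejected(self, toy_complex):
        rec, _ = toy_complex
        with pytest.raises(ValueError):
            vdw_contacts(rec, StructureModel([]))


def _hbond_fixture(d_oa, h_along=True):
    """SER OG donor (with hydrogen) facing a backbone carbonyl O acceptor."""
    og = Atom(1, "OG", "O", "SER", 1, "A", np.zeros(3))
    hg = Atom(2, "HG", "H", "SER", 1, "A",
              np.array([1.0, 0.0, 0.0]) if h_along else np.array([-1.0, 0.0, 0.0]))
    o = Atom(3, "O", "O", "ALA", 2, "B", np.array([d_oa, 0.0, 0.0]))
    return StructureModel([og, hg]), StructureModel([o])


class TestHydrogenBonds:
    def test_canonical_collinear_geometry(self):
        donor_sel, acc_sel = _hbond_fixture(2.9)
        bonds = hydrogen_bonds(donor_sel, acc_sel)
        assert len(bonds) == 1
        hb = bonds[0]
        assert hb.donor.name == "OG" and hb.acceptor.name == "O"
        assert hb.angle == pytest.approx(180.0, abs=1e-6)
        assert not hb.distance_only

    def test_distance_gate(self):
        assert hydrogen_bonds(*_hbond_fixture(4.2)) == []

    def test_angle_gate(self):
        # hydrogen pointing away: D-H...A angle 0
        assert hydrogen_bonds(*_hbond_fixture(2.9, h_along=False)) == []

    def test_distance_only_mode_without_hydrogens(self):
        og = Atom(1, "OG", "O", "SER", 1, "A", np.zeros(3))
        o = Atom(2, "O", "O", "ALA", 2, "B", np.array([2.9, 0.0, 0.0]))
        bonds = hydrogen_bonds(StructureModel([og]), StructureModel([o]))
        # OG is both donor and acceptor, O is acceptor only -> one record
        assert len(bonds) == 1 and bonds[0].distance_only

    def test_unknown_atoms_are_neither(self):
        x = Atom(1, "XX", "O", "UNK", 1, "A", np.zeros(3))
        o = Atom(2, "O", "O", "ALA", 2, "B", np.array([2.9, 0.0, 0.0]))
        assert hydrogen_bonds(StructureModel([x]), StructureModel([o])) == []

    def test_fuzzed_geometries_match_oracle(self, rng):
        """Random sugar-hydroxyl/backbone geometries against a brute-force
        oracle applying the same distance and angle criteria.  Donors sit on
        a coarse grid (spacing 4 A) so each hydrogen is unambiguously
        bonded to its own donor."""
        for trial in range(20):
            donors, hyds, accs = [], [], []
            grid = [(i, j) for i in range(3) for j in range(2)]
            for k, (i, j) in enumerate(grid):
                pos = np.array([4.0 * i, 4.0 * j, 0.0]) + rng.normal(0, 0.3, 3)
                donors.append(Atom(10 + 2 * k, "O2", "O", "FUC", k + 1, "A", pos))
                if k % 2 == 0:  # half the donors carry an explicit hydrogen
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    hyds.append(Atom(11 + 2 * k, "HO2", "H", "FUC", k + 1, "A",
                                     pos + 1.0 * u))
            for i in range(8):
                accs.append(Atom(50 + i, "O", "O", "ALA", i + 1, "B",
                                 rng.uniform(-2, 10, 3)))
            sel_a = StructureModel(donors + hyds)
            sel_b = StructureModel(accs)
            got = {(b.donor.serial, b.acceptor.serial)
                   for b in hydrogen_bonds(sel_a, sel_b)}
            h_of = {h.serial - 1: h for h in hyds}
            want = set()
            for d_at in donors:
                h_at = h_of.get(d_at.serial)
                for a_at in accs:
                    dist = np.linalg.norm(d_at.xyz - a_at.xyz)
                    if dist > 3.5:
                        continue
                    if h_at is not None:
                        v1 = d_at.xyz - h_at.xyz
                        v2 = a_at.xyz - h_at.xyz
                        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= 120:
                            want.add((d_at.serial, a_at.serial))
                    else:
                        want.add((d_at.serial, a_at.serial))
            assert got == want


def _quaternion_rmsd(P, Q):
    """Horn's quaternion method: independent oracle for superposed RMSD."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] @ Q[:, 0], P[:, 0] @ Q[:, 1], P[:, 0] @ Q[:, 2])
    Syx, Syy, Syz = (P[:, 1] @ Q[:, 0], P[:, 1] @ Q[:, 1], P[:, 1] @ Q[:, 2])
    Szx, Szy, Szz = (P[:, 2] @ Q[:, 0], P[:, 2] @ Q[:, 1], P[:, 2] @ Q[:, 2])
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    msd = (np.sum(P**2) + np.sum(Q**2) - 2 * lam) / len(P)
    return math.sqrt(max(msd, 0.0))


class TestRMSD:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(size=(25, 3))
        R = Rotation.from_euler("xyz", [31, -47, 102], degrees=True).as_matrix()
        y = x @ R.T + np.array([5.0, -2.0, 11.0])
        assert rmsd(x, y) == pytest.approx(0.0, abs=1e-8)
        assert rmsd(x, y, superpose_first=False) > 1.0

    def test_matches_quaternion_oracle_on_tabulated_points(self):
        P = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 1.0]])
        Q = np.array([[0.1, 0, 0], [1.4, 0.2, 0], [1.6, 1.4, 0.1], [0, 1.6, 0.9]])
        assert rmsd(P, Q) == pytest.approx(_quaternion_rmsd(P, Q), abs=1e-10)

    def test_matches_quaternion_oracle_on_random_sets(self, rng):
        for _ in range(25):
            P = rng.normal(size=(8, 3))
            Q = P + rng.normal(scale=0.4, size=(8, 3))
            assert rmsd(P, Q) == pytest.approx(_quaternion_rmsd(P, Q), abs=1e-9)

    def test_symmetry(self, rng):
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        assert rmsd(P, Q) == pytest.approx(rmsd(Q, P), abs=1e-9)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((2, 3)), np.ones((2, 3)))


class TestRMSF:
    def test_constant_trajectory_is_zero(self, toy_complex):
        rec, _ = toy_complex
        traj = generate_toy_trajectory(rec, 10, 0.0, seed=1)
        np.testing.assert_allclose(rmsf(traj, fit_selection=None), 0.0, atol=1e-12)

    def test_single_oscillating_atom(self):
        """One atom swinging +/-d about its mean has RMSF exactly d when no
        superposition can absorb the motion (fit on the static atoms)."""
        atoms = [
            Atom(i + 1, "CA", "C", "ALA", i + 1, "A", xyz)
            for i, xyz in enumerate(
                [np.zeros(3), np.array([5.0, 0, 0]), np.array([0, 5.0, 0]),
                 np.array([0, 0, 5.0]), np.array([3.0, 3.0, 0.0])]
            )
        ]
        model = StructureModel(atoms)
        d = 0.8
        f0 = model.coords
        f1 = f0.copy()
        f1[4, 2] += d
        f2 = f0.copy()
        f2[4, 2] -= d
        from abmut.structure import Trajectory

        traj = Trajectory(model, np.stack([f1, f2]))
        values = rmsf(traj, fit_selection=lambda a: a.residue_seq <= 4)
        np.testing.assert_allclose(values[:4], 0.0, atol=1e-10)
        assert values[4] == pytest.approx(d, abs=1e-10)

    def test_gaussian_noise_matches_closed_form(self, toy_complex):
        """Isotropic jitter of scale s about a rigid frame: RMSF per atom
        approaches sqrt(3)*s*sqrt((F-1)/F)."""
        rec, _ = toy_complex
        s, frames = 0.3, 500
        traj = generate_toy_trajectory(rec, frames, s, seed=9)
        values = rmsf(traj, fit_selection=None)
        expected = math.sqrt(3) * s * math.sqrt((frames - 1) / frames)
        assert np.mean(values) == pytest.approx(expected, rel=0.10)

    def test_single_frame_warns_zero(self, toy_complex):
        rec, _ = toy_complex
        traj = generate_toy_trajectory(rec, 1, 0.3, seed=1)
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(rmsf(traj), 0.0)


def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place a fourth point with prescribed internal coordinates."""
    angle, dih = math.radians(angle_deg), math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array(
        [-math.cos(angle), math.sin(angle) * math.cos(dih), -math.sin(angle) * math.sin(dih)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phis, psis, omega=180.0):
    """Ideal-geometry backbone (N, CA, C per residue) with given dihedrals."""
    coords = [
        np.array([0.0, 0.0, 0.0]),        # N1
        np.array([1.46, 0.0, 0.0]),       # CA1
        _nerf(np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0]),
              np.array([1.46, 0.0, 0.0]), 1.52, 111.0, 180.0),  # C1
    ]
    n_res = len(psis) + 1
    for k in range(1, n_res):
        N, CA, C = coords[-3], coords[-2], coords[-1]
        n_next = _nerf(N, CA, C, 1.33, 116.0, psis[k - 1])
        ca_next = _nerf(CA, C, n_next, 1.46, 122.0, omega)
        c_next = _nerf(C, n_next, ca_next, 1.52, 111.0, phis[k - 1])
        coords.extend([n_next, ca_next, c_next])
    atoms = []
    serial = 1
    for r in range(n_res):
        for name, xyz in zip(("N", "CA", "C"), coords[3 * r : 3 * r + 3]):
            atoms.append(Atom(serial, name, name[0], "ALA", r + 1, "H", xyz))
            serial += 1
    return StructureModel(atoms)


class TestDihedralsAndRamachandran:
    def test_nerf_round_trip(self):
        a, b, c = (np.array([0.0, 0, 0]), np.array([1.5, 0, 0]),
                   np.array([2.2, 1.3, 0.0]))
        for want in (-57.0, -47.0, 60.0, 150.0, -120.0, 180.0):
            d = _nerf(a, b, c, 1.5, 109.5, want)
            assert dihedral(a, b, c, d) == pytest.approx(want, abs=1e-9)

    def test_reversal_preserves_and_mirror_negates(self, rng):
        p = rng.normal(size=(4, 3))
        ang = dihedral(*p)
        assert dihedral(*p[::-1]) == pytest.approx(ang, abs=1e-9)
        mirrored = p * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-ang, abs=1e-9)

    def test_alpha_helix_geometry_codes_a(self):
        """phi/psi recovered from constructed ideal helix coordinates land
        in the alpha quadrant."""
        model = _build_backbone(phis=[-57.0] * 4, psis=[-47.0] * 4)
        angles = phi_psi(model, "H")
        inner = [pp for pp in angles if pp.complete]
        assert inner, "expected interior residues"
        for pp in inner:
            assert pp.phi == pytest.approx(-57.0, abs=1e-6)
            assert pp.psi == pytest.approx(-47.0, abs=1e-6)
            assert ramachandran_code(pp.phi, pp.psi) == "a"

    def test_termini_flagged(self):
        model = _build_backbone(phis=[-57.0] * 2, psis=[-47.0] * 2)
        angles = phi_psi(model, "H")
        assert math.isnan(angles[0].phi) and math.isnan(angles[-1].psi)

    @pytest.mark.parametrize(
        "phi,psi,code",
        [
            (-57.0, -47.0, "a"),
            (60.0, 40.0, "l"),     # positive-phi rule
            (-120.0, 130.0, "b"),  # beta sheet region
            (-60.0, -150.0, "b"),  # psi below the alpha band
            (60.0, 170.0, "e"),    # extended positive-phi band
        ],
    )
    def test_quadrant_codes(self, phi, psi, code):
        assert ramachandran_code(phi, psi) == code

    def test_takeoff_code_detects_bab(self):
        # beta, alpha, beta at three consecutive interior residues
        model = _build_backbone(
            phis=[-120.0, -120.0, -57.0, -120.0, -120.0],
            psis=[130.0, 130.0, 130.0, -47.0, 130.0],
        )
        # residues 3,4,5 have (phi,psi) = (b, a, b) by construction
        codes, kplus = takeoff_codes(model, "H", [3, 4, 5])
        assert codes == "bab" and kplus

    def test_takeoff_missing_residue_dash(self):
        model = _build_backbone(phis=[-57.0] * 3, psis=[-47.0] * 3)
        codes, kplus = takeoff_codes(model, "H", [1, 2, 99])
        assert codes.endswith("-") and not kplus
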