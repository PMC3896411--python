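"""Superposition, fluctuations, torsions and rotamer operations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barotraj import geometry as geo
from barotraj.model_io import Structure, SubdomainMap, Trajectory
from barotraj.synthetic_data import (
    HarmonicEnsembleSpec,
    build_lysine_rotamer,
    gen_harmonic_trajectory,
)

from conftest import make_atom, random_rotation


def quaternion_rmsd_oracle(mobile, reference):
    """Independent quaternion-eigenvalue superposition (Kearsley)."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sm, sp = y - x, y + x
    k = np.zeros((4, 4))
    xm, ym, zm = sm[:, 0], sm[:, 1], sm[:, 2]
    xp, yp, zp = sp[:, 0], sp[:, 1], sp[:, 2]
    k[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    k[1, 1] = np.sum(xm**2 + yp**2 + zp**2)
    k[2, 2] = np.sum(xp**2 + ym**2 + zp**2)
    k[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    k[0, 1] = k[1, 0] = np.sum(yp * zm - ym * zp)
    k[0, 2] = k[2, 0] = np.sum(xm * zp - xp * zm)
    k[0, 3] = k[3, 0] = np.sum(xp * ym - xm * yp)
    k[1, 2] = k[2, 1] = np.sum(xm * ym - xp * yp)
    k[1, 3] = k[3, 1] = np.sum(xm * zm - xp * zp)
    k[2, 3] = k[3, 2] = np.sum(ym * zm - yp * zp)
    lam = np.linalg.eigvalsh(k)[0]
    return np.sqrt(max(lam, 0.0) / len(mobile))


class TestSuperpose:
    def test_identity(self, rng):
        coords = rng.normal(0, 5, (10, 3))
        t, rmsd = geo.superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)

    def test_recovers_90_degree_turn(self, rng):
        coords = rng.normal(0, 5, (10, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t, rmsd = geo.superpose(coords, coords @ rot90.T)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation, rot90, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        ref = rng.normal(0, 6, (50, 3))
        mobile = ref @ random_rotation(rng).T + rng.normal(0, 0.5, (50, 3))
        _, rmsd = geo.superpose(mobile, ref)
        assert rmsd == pytest.approx(
            quaternion_rmsd_oracle(mobile, ref), abs=1e-6
        )

    def test_degenerate_selections(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(geo.DegenerateSelectionError, match="collinear"):
            geo.superpose(line, line)
        two = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(geo.DegenerateSelectionError):
            geo.superpose(two, two)


class TestPairwiseRmsd:
    def test_unique_pair_count_for_12_structures(self, rng):
        base = rng.normal(0, 5, (10, 3))
        structs = []
        for k in range(12):
            atoms = [
                make_atom(i + 1, residue_id=i + 1,
                          position=base[i] + rng.normal(0, 0.2, 3))
                for i in range(10)
            ]
            structs.append(Structure(atoms=atoms))
        mat = geo.pairwise_rmsd_matrix(structs)
        iu = np.triu_indices(12, k=1)
        assert len(iu[0]) == 66
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 0.0)

    def test_identical_pair_zero(self, cloud_structure):
        mat = geo.pairwise_rmsd_matrix([cloud_structure, cloud_structure])
        assert mat.max() == pytest.approx(0.0, abs=1e-9)

    def test_matrix_equals_per_pair_superpose(self, rng):
        base = rng.normal(0, 5, (8, 3))
        structs = []
        for k in range(4):
            atoms = [
                make_atom(i + 1, residue_id=i + 1,
                          position=base[i] + rng.normal(0, 0.4, 3))
                for i in range(8)
            ]
            structs.append(Structure(atoms=atoms))
        mat = geo.pairwise_rmsd_matrix(structs)
        for i in range(4):
            for j in range(i + 1, 4):
                _, r = geo.superpose(structs[i].coords, structs[j].coords)
                assert mat[i, j] == pytest.approx(r, abs=1e-12)


class TestAverageStructure:
    def test_identical_frames_fixed_point(self, still_trajectory):
        avg = geo.average_structure(still_trajectory)
        np.testing.assert_allclose(
            avg.coords, still_trajectory.topology.coords, atol=1e-9
        )

    def test_pure_translation_equidistant(self, cloud_structure):
        c = cloud_structure.coords
        frames = np.stack([c, c + np.array([3.0, -1.0, 2.0])])
        traj = Trajectory(topology=cloud_structure, frames=frames)
        avg = geo.average_structure(traj)
        _, r0 = geo.superpose(frames[0], avg.coords)
        _, r1 = geo.superpose(frames[1], avg.coords)
        assert r0 == pytest.approx(r1, abs=1e-9)
        assert r0 == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_mean_recovers_reference(self, rng):
        ref = rng.normal(0, 5, (20, 3))
        spec = HarmonicEnsembleSpec(
            reference=ref, masses=np.full(20, 12.0), n_frames=2000,
            isotropic_variance=0.04, seed=3,
        )
        traj, _ = gen_harmonic_trajectory(spec)
        avg = geo.average_structure(traj)
        sem = np.sqrt(0.04 / 2000)
        _, rmsd = geo.superpose(avg.coords, ref)
        assert rmsd < 3.0 * sem * np.sqrt(3)


class TestRmsf:
    def test_identical_frames_zero(self, still_trajectory):
        vals = geo.rmsf(still_trajectory)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in vals.values())

    def test_two_point_oscillator_closed_form(self, rng):
        # one atom alternating +-a along x in an otherwise rigid body:
        # RMSF of that residue tends to a
        base = rng.normal(0, 8, (30, 3))
        a = 0.6
        frames = np.repeat(base[None], 400, axis=0)
        frames[::2, 0, 0] += a
        frames[1::2, 0, 0] -= a
        traj = Trajectory(
            topology=Structure(
                atoms=[make_atom(i + 1, residue_id=i + 1, position=base[i])
                       for i in range(30)]
            ),
            frames=frames,
        )
        # fit on the rigid part so the oscillator does not drag the frame
        vals = geo.rmsf(traj, fit_selection=np.arange(1, 30))
        assert vals[1] == pytest.approx(a, rel=1e-3)
        assert max(vals[r] for r in range(2, 31)) < 1e-9

    def test_harmonic_variances_recovered(self, rng):
        # best-fitting removes the 6 rigid degrees of freedom, scaling the
        # pooled variance by (3N-6)/3N for an isotropic equal-mass ensemble
        n_atoms, sigma2 = 15, 0.09
        ref = rng.normal(0, 6, (n_atoms, 3))
        spec = HarmonicEnsembleSpec(
            reference=ref, masses=np.full(n_atoms, 12.0), n_frames=20000,
            isotropic_variance=sigma2, seed=9,
        )
        traj, _ = gen_harmonic_trajectory(spec)
        vals = geo.rmsf(traj)
        got = np.array([vals[r] for r in sorted(vals)])
        expect = np.sqrt(3 * sigma2 * (3 * n_atoms - 6) / (3 * n_atoms))
        assert np.sqrt(np.mean(got**2)) == pytest.approx(expect, rel=0.02)
        assert np.all(np.abs(got - expect) / expect < 0.10)

    def test_rigid_body_motion_invariance(self, rng, cloud_structure):
        base = cloud_structure.coords
        frames = np.stack(
            [base + rng.normal(0, 0.3, base.shape) for _ in range(20)]
        )
        traj = Trajectory(topology=cloud_structure, frames=frames)
        ref_vals = geo.rmsf(traj)
        rot = random_rotation(rng)
        moved = np.stack([f @ rot.T + np.array([5.0, 1, -2]) for f in frames])
        vals = geo.rmsf(Trajectory(topology=cloud_structure, frames=moved))
        for r in ref_vals:
            assert vals[r] == pytest.approx(ref_vals[r], abs=1e-8)


def _four_centroid_structure(points):
    atoms = [
        make_atom(i + 1, residue_id=i + 1, position=p)
        for i, p in enumerate(points)
    ]
    return Structure(atoms=atoms), SubdomainMap({1: 1, 2: 2, 3: 3, 4: 4})


class TestPropellerAngle:
    def test_cis_zero(self):
        pts = [(1, 1, 0), (0, 0, 0), (2, 0, 0), (3, 1, 0)]
        s, sd = _four_centroid_structure(pts)
        ang = geo.propeller_angle(s, sd, order=(1, 2, 3, 4),
                                  selection=np.arange(4))
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_trans_180(self):
        pts = [(1, 1, 0), (0, 0, 0), (2, 0, 0), (1, -1, 0)]
        s, sd = _four_centroid_structure(pts)
        ang = geo.propeller_angle(s, sd, order=(1, 2, 3, 4),
                                  selection=np.arange(4))
        assert abs(ang) == pytest.approx(180.0, abs=1e-9)

    def test_matches_normal_vector_oracle(self, rng):
        pts = rng.normal(0, 4, (4, 3))
        s, sd = _four_centroid_structure(pts)
        ang = geo.propeller_angle(s, sd, order=(1, 2, 3, 4),
                                  selection=np.arange(4))
        # brute-force torsion from explicit plane normals
        b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
        sign = np.sign(np.dot(np.cross(n1, n2), b2))
        expect = sign * np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert ang == pytest.approx(expect, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(0, 4, (4, 3))
        s, sd = _four_centroid_structure(pts)
        ref = geo.propeller_angle(s, sd, order=(1, 2, 3, 4),
                                  selection=np.arange(4))
        rot = random_rotation(r)
        s2, _ = _four_centroid_structure(pts @ rot.T + r.normal(0, 10, 3))
        moved = geo.propeller_angle(s2, sd, order=(1, 2, 3, 4),
                                    selection=np.arange(4))
        assert moved == pytest.approx(ref, abs=1e-8)

    def test_empty_subdomain_errors(self):
        pts = [(1, 1, 0), (0, 0, 0), (2, 0, 0), (3, 1, 0)]
        s, _ = _four_centroid_structure(pts)
        sd = SubdomainMap({1: 1, 2: 2, 3: 3, 4: 3})
        with pytest.raises(ValueError, match="subdomain 4"):
            geo.propeller_angle(s, sd, order=(1, 2, 3, 4),
                                selection=np.arange(4))


class TestRotamers:
    @pytest.mark.parametrize(
        "residue,count",
        [("LYS", 81), ("SER", 3), ("GLN", 27), ("ARG", 81), ("VAL", 3)],
    )
    def test_enumeration_counts(self, residue, count):
        assert len(geo.enumerate_rotamers(residue)) == count

    def test_cardinality_is_power_of_three_for_all_types(self):
        for residue, chis in geo.CHI_ATOMS.items():
            assert len(geo.enumerate_rotamers(residue)) == 3 ** len(chis)

    def test_glycine_empty_with_warning(self):
        with pytest.warns(UserWarning):
            assert geo.enumerate_rotamers("GLY") == []

    def test_two_state_selection(self):
        s5 = geo.RotamerState(chi=(60.0,))
        s7 = geo.RotamerState(chi=(180.0,))
        states = [
            (s5, {"NZ": np.array([5.0, 0, 0])}),
            (s7, {"NZ": np.array([7.0, 0, 0])}),
        ]
        best = geo.select_rotamer_max_distance(states, "NZ", np.zeros(3))
        assert best is s7

    def test_tie_breaks_lexicographic(self):
        states = [
            (geo.RotamerState(chi=(c,)), {"NZ": np.array([0.0, 0, 5.0])})
            for c in (180.0, 60.0, -60.0)
        ]
        best = geo.select_rotamer_max_distance(states, "NZ", np.zeros(3))
        assert best.chi == (-60.0,)

    def test_81_lysine_states_match_exhaustive_scan(self):
        n = np.array([0.0, 0, 0])
        ca = np.array([1.46, 0, 0])
        cb = np.array([2.0, 1.3, 0])
        anchor = np.array([4.0, -3.0, 2.0])
        states = [
            (r, build_lysine_rotamer(n, ca, cb, r.chi))
            for r in geo.enumerate_rotamers("LYS")
        ]
        best = geo.select_rotamer_max_distance(states, "NZ", anchor)
        brute = max(
            states, key=lambda sc: np.linalg.norm(sc[1]["NZ"] - anchor)
        )[0]
        assert best.chi == brute.chi

    def test_clash_only_states_warn(self):
        states = [
            (geo.RotamerState(chi=(60.0,)), {"NZ": np.array([0.3, 0, 0])}),
            (geo.RotamerState(chi=(180.0,)), {"NZ": np.array([0.5, 0, 0])}),
        ]
        with pytest.warns(UserWarning, match="clash"):
            best = geo.select_rotamer_max_distance(states, "NZ", np.zeros(3))
        assert best.chi == (180.0,)


def _lysine_trajectory(chi_per_frame):
    n = np.array([0.0, 0, 0])
    ca = np.array([1.46, 0, 0])
    cb = np.array([2.0, 1.3, 0])
    frames = []
    for chi in chi_per_frame:
        sc = build_lysine_rotamer(n, ca, cb, chi)
        frames.append(
            np.stack([n, ca, sc["CB"], sc["CG"], sc["CD"], sc["CE"], sc["NZ"]])
        )
    names = ["N", "CA", "CB", "CG", "CD", "CE", "NZ"]
    elements = ["N", "C", "C", "C", "C", "C", "N"]
    atoms = [
        make_atom(i + 1, name=nm, element=el, residue_name="LYS",
                  residue_id=137, position=frames[0][i])
        for i, (nm, el) in enumerate(zip(names, elements))
    ]
    return Trajectory(topology=Structure(atoms=atoms), frames=np.stack(frames))


class TestDihedralHistogram:
    def test_single_state_single_bin(self):
        traj = _lysine_trajectory([(-60.0, 60.0, 180.0, 60.0)] * 20)
        hists = geo.dihedral_histogram(traj, 137, [1])
        edges, density = hists[1]
        occupied = np.nonzero(density)[0]
        assert len(occupied) == 1
        assert density[occupied[0]] == pytest.approx(1.0 / 5.0)
        assert edges[occupied[0]] <= -60.0 < edges[occupied[0] + 1]

    def test_uniform_angles_flat(self, rng):
        chis = [(float(a), 60.0, 180.0, 60.0)
                for a in rng.uniform(-179.999, 180.0, 20000)]
        traj = _lysine_trajectory(chis)
        _, density = geo.dihedral_histogram(traj, 137, [1])[1]
        assert density.max() / density[density > 0].min() < 1.5

    def test_mass_conserved_across_wrap(self, rng):
        # angles hugging the +-180 boundary: integral still 1
        chis = [(float(a), 60.0, 180.0, 60.0)
                for a in 178.0 + rng.uniform(0.0, 4.0, 500) - 360.0 * 0]
        chis = [((c[0] + 180.0) % 360.0 - 180.0,) + c[1:] for c in chis]
        traj = _lysine_trajectory(chis)
        _, density = geo.dihedral_histogram(traj, 137, [1])[1]
        assert density.sum() * 5.0 == pytest.approx(1.0, abs=1e-9)

    def test_missing_sidechain_errors(self, still_trajectory):
        with pytest.raises(ValueError):
            geo.dihedral_histogram(still_trajectory, 1, [1])


class TestMinSidechainDistance:
    def test_rigid_single_carbon_pair(self):
        atoms = [
            make_atom(1, name="CA", residue_name="ALA", residue_id=1,
                      position=(0, 0, 0)),
            make_atom(2, name="CB", residue_name="ALA", residue_id=1,
                      position=(1.5, 0, 0)),
            make_atom(3, name="CA", residue_name="ALA", residue_id=2,
                      position=(6.9, 0, 0)),
            make_atom(4, name="CB", residue_name="ALA", residue_id=2,
                      position=(5.4, 0, 0)),
        ]
        s = Structure(atoms=atoms)
        traj = Trajectory(topology=s, frames=np.repeat(s.coords[None], 3, 0))
        series = geo.min_sidechain_distance(traj, 1, 2)
        assert series.mean == pytest.approx(3.9)
        assert series.sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        atoms = []
        serial = 1
        for rid, nsc in ((1, 4), (2, 3)):
            atoms.append(make_atom(serial, name="CA", residue_id=rid,
                                   position=rng.normal(rid * 8, 1, 3)))
            serial += 1
            for k in range(nsc):
                atoms.append(
                    make_atom(serial, name=f"CB{k}" if k else "CB",
                              residue_id=rid,
                              position=rng.normal(rid * 8, 2, 3))
                )
                serial += 1
        s = Structure(atoms=atoms)
        frames = np.stack(
            [s.coords + rng.normal(0, 0.5, s.coords.shape) for _ in range(5)]
        )
        traj = Trajectory(topology=s, frames=frames)
        series = geo.min_sidechain_distance(traj, 1, 2)
        sc1 = [i for i, a in enumerate(s.atoms)
               if a.residue_id == 1 and a.name != "CA"]
        sc2 = [i for i, a in enumerate(s.atoms)
               if a.residue_id == 2 and a.name != "CA"]
        for f in range(5):
            brute = min(
                np.linalg.norm(frames[f, i] - frames[f, j])
                for i, j in itertools.product(sc1, sc2)
            )
            assert series.values[f] == pytest.approx(brute, abs=1e-12)

    def test_glycine_side_errors(self):
        atoms = [
            make_atom(1, name="CA", residue_name="GLY", residue_id=1),
            make_atom(2, name="CA", residue_name="ALA", residue_id=2,
                      position=(5, 0, 0)),
            make_atom(3, name="CB", residue_name="ALA", residue_id=2,
                      position=(6, 0, 0)),
        ]
        s = Structure(atoms=atoms)
        traj = Trajectory(topology=s, frames=s.coords[None])
        with pytest.raises(ValueError, match="no side-chain"):
            geo.min_sidechain_distance(traj, 1, 2)

    def test_constructed_alanine_valine_closest_approach(self):
        atoms = [
            make_atom(1, name="CA", residue_name="ALA", residue_id=1,
                      position=(0, 0, 0)),
            make_atom(2, name="CB", residue_name="ALA", residue_id=1,
                      position=(1.5, 0, 0)),
            make_atom(3, name="CA", residue_name="VAL", residue_id=2,
                      position=(8.0, 0, 0)),
            make_atom(4, name="CB", residue_name="VAL", residue_id=2,
                      position=(6.6, 0, 0)),
            make_atom(5, name="CG1", residue_name="VAL", residue_id=2,
                      position=(5.9, 1.2, 0)),
            make_atom(6, name="CG2", residue_name="VAL", residue_id=2,
                      position=(7.0, -1.2, 0)),
        ]
        s = Structure(atoms=atoms)
        traj = Trajectory(topology=s, frames=s.coords[None])
        series = geo.min_sidechain_distance(traj, 1, 2)
        expect = np.linalg.norm(np.array([5.9, 1.2, 0]) - np.array([1.5, 0, 0]))
        assert series.mean == pytest.approx(expect)
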