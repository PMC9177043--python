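"""Structural CVs: torsions, pairing distances, solvation, classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pathmetad.errors import GeometryError, ParameterError, SelectionError
from pathmetad.structcv import (
    AtomGroupSpec,
    CVRecord,
    StructureFrame,
    atomic_mass,
    classify_state,
    com_pseudo_dihedral,
    compute_cvs,
    dihedral,
    make_fixture,
    n_water,
    pair_distances,
)


def quaternion_dihedral(p1, p2, p3, p4):
    """Independent torsion oracle: rotate so the central bond lies on +z,
    then read the azimuth from the first outer arm to the last one."""
    b2 = np.asarray(p3) - np.asarray(p2)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [b2])
    u = rot.apply(np.asarray(p1) - np.asarray(p2))
    w = rot.apply(np.asarray(p4) - np.asarray(p3))
    ang = np.arctan2(w[1], w[0]) - np.arctan2(u[1], u[0])
    return (ang + np.pi) % (2 * np.pi) - np.pi


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_pi(self):
        ang = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert abs(ang) == pytest.approx(np.pi)

    def test_rotation_invariance_vs_quaternion_oracle(self, rng):
        base = rng.normal(0, 2, (4, 3))
        ref = dihedral(*base)
        assert ref == pytest.approx(quaternion_dihedral(*base), abs=1e-10)
        for _ in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0, 5, 3)
            moved = base @ R.T + t
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-10)

    def test_matches_mdanalysis(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(20):
            p = rng.normal(0, 2, (4, 3))
            ours = dihedral(*p)
            theirs = float(calc_dihedrals(p[0], p[1], p[2], p[3]))
            assert ours == pytest.approx(theirs, abs=1e-5)

    def test_degenerate_geometry(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))  # collinear
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))  # coincident


def tiny_frame(extra=()):
    chain = ["A", "A", "A", "A"]
    res_id = [1, 1, 1, 1]
    res_name = ["DA"] * 4
    name = ["N1", "C2", "N3", "C4"]
    coord = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
    for i, (nm, xyz) in enumerate(extra):
        chain.append("A")
        res_id.append(2)
        res_name.append("DA")
        name.append(nm)
        coord.append(xyz)
    return StructureFrame(chain, res_id, res_name, name, np.array(coord, dtype=float))


class TestComPseudoDihedral:
    def test_singleton_groups_reduce_to_dihedral(self):
        frame = tiny_frame()
        spec = AtomGroupSpec(tuple((("A", 1, n),) for n in ("N1", "C2", "N3", "C4")))
        assert com_pseudo_dihedral(frame, spec) == pytest.approx(
            dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)), abs=1e-12
        )

    def test_symmetric_pairs_share_the_singleton_com(self):
        # two same-element atoms placed symmetrically about each reference
        # point give the same pseudo-dihedral as the single atoms
        frame = tiny_frame(extra=[("C5", (0, 1, 0.3)), ("C6", (0, 1, -0.3))])
        spec = AtomGroupSpec((
            (("A", 2, "C5"), ("A", 2, "C6")),
            (("A", 1, "C2"),),
            (("A", 1, "N3"),),
            (("A", 1, "C4"),),
        ))
        ref = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        assert com_pseudo_dihedral(frame, spec) == pytest.approx(ref, abs=1e-12)

    def test_unresolved_selector_names_the_culprit(self):
        frame = tiny_frame()
        spec = AtomGroupSpec(tuple((("A", 1, n),) for n in ("N1", "C2", "N3", "XX")))
        with pytest.raises(SelectionError, match="XX"):
            com_pseudo_dihedral(frame, spec)

    def test_group_spec_validation(self):
        with pytest.raises(ParameterError):
            AtomGroupSpec(((("A", 1, "N1"),),) * 3)
        with pytest.raises(ParameterError):
            AtomGroupSpec(((("A", 1, "N1"),), (), (("A", 1, "N3"),), (("A", 1, "C4"),)))


class TestFixtureGeometry:
    @pytest.mark.parametrize("kind,target", [("WCF", 1.5), ("HG", -1.5)])
    def test_chi_prime_near_characteristic_values(self, kind, target):
        cv = compute_cvs(make_fixture(kind))
        d = abs((cv.chi_prime - target + np.pi) % (2 * np.pi) - np.pi)
        assert d < 0.3

    def test_glycosidic_rotation_shifts_chi_prime_by_pi(self):
        wcf = compute_cvs(make_fixture("WCF")).chi_prime
        hg = compute_cvs(make_fixture("HG")).chi_prime
        shift = abs((wcf - hg + np.pi) % (2 * np.pi) - np.pi)
        assert shift == pytest.approx(np.pi, abs=0.05)

    def test_pair_distances_by_state(self):
        wcf = compute_cvs(make_fixture("WCF"))
        assert wcf.d_cc == pytest.approx(10.6, abs=0.5)
        assert wcf.d_wcf < 3.5 and wcf.d_hb < 3.5
        hg = compute_cvs(make_fixture("HG"))
        assert hg.d_cc == pytest.approx(9.1, abs=0.5)
        assert hg.d_hg < 3.5 and hg.d_hb < 3.5

    def test_flipped_theta_negative_beyond_quarter_pi(self):
        cv = compute_cvs(make_fixture("flipped"))
        assert cv.theta < -np.pi / 4

    def test_mid_rotated_is_intermediate(self):
        assert classify_state(compute_cvs(make_fixture("mid-rotated"))) == "intermediate"

    def test_rigid_motion_invariance(self):
        frame = make_fixture("WCF")
        cv0 = compute_cvs(frame)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = frame.transformed(rotation=R, translation=np.array([5.0, -3.0, 11.0]))
        cv1 = compute_cvs(moved)
        for attr in ("chi", "chi_prime", "theta", "d_wcf", "d_hg", "d_hb", "d_cc", "d_nb"):
            assert getattr(cv1, attr) == pytest.approx(getattr(cv0, attr), abs=1e-10)

    def test_translation_leaves_distances_bit_close(self):
        frame = make_fixture("HG")
        moved = frame.transformed(translation=np.array([100.0, 0.0, 0.0]))
        d0 = pair_distances(frame)
        d1 = pair_distances(moved)
        assert np.allclose(d0, d1, atol=1e-12)

    def test_noise_is_deterministic_under_seed(self):
        a = make_fixture("WCF", noise=0.2, seed=3)
        b = make_fixture("WCF", noise=0.2, seed=3)
        assert np.array_equal(a.coord, b.coord)

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            make_fixture("syn-anti")


class TestClassification:
    def test_characteristic_records(self):
        assert classify_state(CVRecord(chi_prime=1.5, d_wcf=3.0)) == "WCF"
        assert classify_state(CVRecord(chi_prime=-1.5, d_hg=3.0)) == "HG"
        assert classify_state(CVRecord(chi_prime=0.0)) == "intermediate"
        assert classify_state(CVRecord(chi_prime=1.5, d_wcf=4.5)) == "intermediate"

    def test_round_trip_noiseless_and_noisy(self):
        for kind in ("WCF", "HG"):
            assert classify_state(compute_cvs(make_fixture(kind))) == kind
            for seed in range(20):
                cv = compute_cvs(make_fixture(kind, noise=0.2, seed=seed))
                assert classify_state(cv) == kind


class TestWater:
    def test_no_waters(self):
        assert n_water(make_fixture("WCF")) == 0

    def test_threshold_counting(self):
        frame = make_fixture("WCF")
        c = frame.position("A", 16, "N6")
        chain = list(frame.chain) + ["W"] * 8
        res_id = list(frame.res_id) + list(range(100, 108))
        res_name = list(frame.res_name) + ["HOH"] * 8
        name = list(frame.name) + ["O"] * 8
        offsets = [5.9] * 5 + [6.1] * 3
        waters = [c + np.array([d, 0, 0]) * (1 if i % 2 else -1)
                  for i, d in enumerate(offsets)]
        # avoid duplicate coordinates mattering: unique keys suffice
        coords = np.vstack([frame.coord, waters])
        f2 = StructureFrame(chain, res_id, res_name, name, coords)
        assert n_water(f2) == 5

    def test_minimum_image_matches_brute_force(self, rng):
        frame = make_fixture("WCF", n_waters=60, water_box=20.0, seed=5)
        count = n_water(frame)
        # brute force with explicit image enumeration
        c = frame.position("A", 16, "N6")
        mask = np.asarray(frame.res_name, dtype=object) == "HOH"
        waters = frame.coord[np.isin(frame.res_name, ["HOH"])]
        box = frame.box
        brute = 0
        for w in waters:
            best = np.inf
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    for iz in (-1, 0, 1):
                        img = w + box * np.array([ix, iy, iz])
                        best = min(best, np.linalg.norm(img - c))
            brute += best <= 6.0
        assert count == brute

    def test_missing_center_atom(self):
        with pytest.raises(SelectionError):
            n_water(make_fixture("WCF"), center=("A", 99, "N6"))

    def test_cutoff_validation(self):
        with pytest.raises(ParameterError):
            n_water(make_fixture("WCF"), cutoff=0.0)


class TestPDBRoundTrip:
    def test_coordinates_and_naming_survive(self, tmp_path):
        frame = make_fixture("HG", n_waters=5)
        f = tmp_path / "fixture.pdb"
        frame.to_pdb(f)
        back = StructureFrame.from_pdb(f, box=frame.box)
        assert len(back) == len(frame)
        assert list(back.name) == list(frame.name)
        assert list(back.chain) == list(frame.chain)
        # PDB stores 3 decimals
        assert np.max(np.abs(back.coord - frame.coord)) < 1e-3 + 1e-9
        cv0, cv1 = compute_cvs(frame), compute_cvs(back)
        assert cv1.chi_prime == pytest.approx(cv0.chi_prime, abs=1e-3)


def test_mass_inference_and_override():
    assert atomic_mass("O4'") == pytest.approx(15.999)
    assert atomic_mass("C1'") == pytest.approx(12.011)
    assert atomic_mass("N9") == pytest.approx(14.007)
    assert atomic_mass("N9", {"N9": 99.0}) == 99.0
    with pytest.raises(SelectionError):
        atomic_mass("123")


def test_cv_table_output(tmp_path):
    from pathmetad.structcv import write_cv_table

    recs = [compute_cvs(make_fixture(k)) for k in ("WCF", "HG")]
    f = tmp_path / "COLVAR"
    write_cv_table(recs, f)
    lines = f.read_text().splitlines()
    assert lines[0].startswith("# frame chi chi_prime")
    assert len(lines) == 3
    assert float(lines[1].split()[2]) == pytest.approx(recs[0].chi_prime)
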