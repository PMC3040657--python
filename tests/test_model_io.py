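"""Structure/trajectory I/O, selections and geometry primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unbend.model_io import (PDBParseError, Selection, Trajectory,
                             ValidationError, com,
                             default_integrin_domain_map, extension_series,
                             kabsch_superpose, read_pdb, read_trajectory_csv,
                             resolve_selection, rmsd_series, write_pdb,
                             write_trajectory_csv)

from conftest import make_atoms


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


MINIMAL_PDB = (
    "ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
    "ATOM      2  CA  MET A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
    "END\n"
)


def test_read_pdb_minimal(tmp_path):
    path = tmp_path / "two.pdb"
    path.write_text(MINIMAL_PDB)
    m = read_pdb(path)
    assert m.n_atoms == 2
    np.testing.assert_allclose(m.xyz[0], [11.104, 6.134, -6.504])
    np.testing.assert_allclose(m.xyz[1], [11.639, 6.071, -5.147])
    assert list(m.name) == ["N", "CA"]
    assert list(m.element) == ["N", "C"]


def test_read_pdb_reports_bad_line_number(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text("ATOM      1  N   MET A   1      11.104\n")
    with pytest.raises(PDBParseError, match="line 1"):
        read_pdb(path)


def test_read_pdb_duplicate_serial(tmp_path):
    dup = MINIMAL_PDB.replace("ATOM      2", "ATOM      1")
    path = tmp_path / "dup.pdb"
    path.write_text(dup)
    with pytest.raises(ValidationError, match="duplicate"):
        read_pdb(path)


def test_write_pdb_round_trip(tmp_path, model):
    """Round trip on the synthetic bent model is field-identical."""
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_pdb(model, p1)
    back = read_pdb(p1, annotations=None)
    # annotations are carried by the sidecar, not the PDB; compare via it
    from unbend.model_io import read_annotations, write_annotations
    ann = tmp_path / "ann.csv"
    write_annotations(model, ann)
    back = read_pdb(p1, annotations=ann)
    assert back == model
    write_pdb(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_write_pdb_ter_between_chains(tmp_path, atom_factory):
    m = atom_factory([[0, 0, 0], [1, 0, 0]], chains=["A", "B"])
    path = tmp_path / "ter.pdb"
    write_pdb(m, path)
    lines = path.read_text().splitlines()
    assert lines[1] == "TER"
    assert lines[0].startswith("ATOM") and lines[2].startswith("ATOM")


def test_write_pdb_serial_overflow(tmp_path, atom_factory):
    m = atom_factory([[0, 0, 0]])
    m.serial[0] = 100000
    with pytest.raises(ValueError, match="99999"):
        write_pdb(m, tmp_path / "x.pdb")


def test_read_pdb_against_biopython(tmp_path, model):
    """Coordinates written by write_pdb parse identically in Biopython."""
    from Bio.PDB import PDBParser
    path = tmp_path / "m.pdb"
    write_pdb(model, path)
    structure = PDBParser(QUIET=True).get_structure("m", str(path))
    coords = np.array([a.get_coord() for a in structure.get_atoms()])
    np.testing.assert_allclose(coords, model.xyz, atol=1e-3)


def test_hydrogen_link_validation(atom_factory):
    with pytest.raises(ValidationError, match="missing atom"):
        make_atoms([[0, 0, 0]], roles=["hydrogen"], donor_links=[42]).validate()


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------


def test_trajectory_csv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    traj = Trajectory(times=np.array([0.0, 0.5, 1.25]),
                      coords=rng.normal(size=(3, 4, 3)))
    path = tmp_path / "t.csv"
    write_trajectory_csv(traj, path)
    back = read_trajectory_csv(path)
    np.testing.assert_array_equal(back.times, traj.times)
    np.testing.assert_array_equal(back.coords, traj.coords)


def test_trajectory_requires_increasing_times():
    with pytest.raises(ValidationError, match="increasing"):
        Trajectory(times=np.array([0.0, 0.0]), coords=np.zeros((2, 1, 3)))


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def _poly_ca_model(chain: str, n_res: int):
    """One CA pseudo-atom per residue along a line."""
    pos = np.column_stack([np.arange(n_res, dtype=float),
                           np.zeros(n_res), np.zeros(n_res)])
    return make_atoms(pos, chains=[chain] * n_res,
                      resids=np.arange(1, n_res + 1))


def test_betaA_pull_selection_has_35_residues():
    """The βA COM-pulling group resolves to 35 Cα atoms."""
    model = _poly_ca_model("B", 690)
    dmap = default_integrin_domain_map()
    sel = Selection(composites=("pull_betaA",), ca_only=True)
    assert len(resolve_selection(model, dmap, sel)) == 35


def test_propeller_pull_selection_has_35_residues():
    """The β-propeller pulling group (seven 5-residue ranges) → 35 Cα."""
    model = _poly_ca_model("A", 956)
    dmap = default_integrin_domain_map()
    sel = Selection(composites=("pull_propeller",), ca_only=True)
    assert len(resolve_selection(model, dmap, sel)) == 35


def test_empty_selection_is_empty_not_error(model, domain_map):
    sel = Selection(chain="Z")
    assert len(resolve_selection(model, domain_map, sel)) == 0


def test_unknown_domain_name_lists_known(model, domain_map):
    with pytest.raises(KeyError, match="known domains"):
        resolve_selection(model, domain_map,
                          Selection(domains=(("A", "flagellum"),)))


def test_selection_idempotent_and_order_stable(model, domain_map):
    a = resolve_selection(model, domain_map,
                          Selection(domains=(("B", "hybrid"), ("B", "betaTD"))))
    b = resolve_selection(model, domain_map,
                          Selection(domains=(("B", "betaTD"), ("B", "hybrid"))))
    np.testing.assert_array_equal(a, b)
    assert np.all(np.diff(a) > 0)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_com_simple_cases():
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    np.testing.assert_allclose(com(pos), [1, 0, 0])
    np.testing.assert_allclose(com(pos, indices=[1]), [2, 0, 0])
    with pytest.raises(ValueError):
        com(pos, indices=[])


def test_com_matches_brute_force_sum():
    rng = np.random.default_rng(3)
    pos = rng.normal(size=(10, 3))
    w = rng.uniform(0.5, 2.0, size=10)
    expected = sum(wi * p for wi, p in zip(w, pos)) / w.sum()
    np.testing.assert_allclose(com(pos, weights=w), expected, atol=1e-12)


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()


def test_kabsch_identity_and_translation():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(8, 3))
    rot, trans, rmsd = kabsch_superpose(ref, ref)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(trans, 0, atol=1e-10)
    assert rmsd < 1e-12
    _, _, rmsd2 = kabsch_superpose(ref + 5.0, ref)
    assert rmsd2 < 1e-12


def test_kabsch_recovers_generating_rotation():
    rng = np.random.default_rng(1)
    for _ in range(20):
        cloud = rng.normal(size=(20, 3))
        rot_true = _random_rotation(rng)
        mobile = cloud @ rot_true.T + rng.normal(size=3)
        rot, _, rmsd = kabsch_superpose(mobile, cloud)
        np.testing.assert_allclose(rot @ rot_true, np.eye(3), atol=1e-8)
        assert rmsd < 1e-8
        assert np.isclose(np.linalg.det(rot), 1.0)


def test_kabsch_rejects_collinear():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_kabsch_rmsd_rigid_invariance(seed):
    """RMSD is unchanged when both clouds get the same rigid transform."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(10, 3))
    b = a + 0.3 * rng.normal(size=(10, 3))
    _, _, r0 = kabsch_superpose(a, b)
    rot = _random_rotation(rng)
    shift = rng.normal(size=3) * 10
    _, _, r1 = kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift)
    assert abs(r0 - r1) < 1e-8


def test_rmsd_series_conventions():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(6, 3))
    frames = np.stack([base, base + [1.0, 0, 0], base])
    traj = Trajectory(times=np.array([0.0, 1.0, 2.0]), coords=frames)
    idx = np.arange(6)
    no_fit = rmsd_series(traj, base, idx, superpose=False)
    np.testing.assert_allclose(no_fit[:, 1], [0.0, 1.0, 0.0], atol=1e-12)
    fit = rmsd_series(traj, base, idx, superpose=True)
    assert np.all(fit[:, 1] < 1e-10)


def test_extension_series_against_direct_distances():
    rng = np.random.default_rng(4)
    coords = rng.normal(size=(5, 8, 3)) * 10
    traj = Trajectory(times=np.arange(5.0), coords=coords)
    pull, con = np.array([0, 1, 2]), np.array([5, 6, 7])
    ext = extension_series(traj, pull, con)
    direct = [np.linalg.norm(c[pull].mean(0) - c[con].mean(0)) for c in coords]
    expected = np.array(direct) - direct[0]
    assert ext[0, 1] == 0.0
    np.testing.assert_allclose(ext[:, 1], expected, atol=1e-12)


def test_extension_series_shifted_com():
    base = np.zeros((4, 3))
    base[2:] += [10.0, 0, 0]
    moved = base.copy()
    moved[2:] += [30.0, 0, 0]
    traj = Trajectory(times=np.array([0.0, 1.0]), coords=np.stack([base, moved]))
    ext = extension_series(traj, [2, 3], [0, 1])
    np.testing.assert_allclose(ext[:, 1], [0.0, 30.0], atol=1e-12)
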