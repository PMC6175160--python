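"""Frame, trajectory and file-format round trips and validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibotrace.basis import build_molecular_basis
from ibotrace.frame_io import (
    BundleIntegrityError,
    FrameValidationError,
    FrameWavefunction,
    Geometry,
    MoldenFormatError,
    ReactionTrajectory,
    SCHEMA_VERSION,
    SpinMismatchError,
    TrajectoryConsistencyError,
    read_frame_bundle,
    read_molden,
    read_xyz,
    write_frame_bundle,
    write_molden,
    write_xyz,
)
from ibotrace.scf import BOHR_PER_ANGSTROM, uhf

from conftest import WATER


# ----------------------------------------------------------------------------
# Geometry
# ----------------------------------------------------------------------------

def test_geometry_electron_bookkeeping():
    g = Geometry(elements=["O", "H"], coords=[[0, 0, 0], [0, 0, 0.97]],
                 total_charge=0, spin_multiplicity=2)
    assert g.n_electrons == 9
    assert (g.n_alpha, g.n_beta) == (5, 4)
    assert g.n_alpha - g.n_beta == g.spin_multiplicity - 1


@pytest.mark.parametrize("kwargs", [
    {"elements": ["Xx"], "coords": [[0, 0, 0]]},
    {"elements": ["H"], "coords": [[0, 0, np.inf]]},
    {"elements": ["H"], "coords": [[0, 0, 0]], "spin_multiplicity": 0},
    # one electron cannot make a singlet
    {"elements": ["H"], "coords": [[0, 0, 0]], "spin_multiplicity": 1},
])
def test_geometry_rejects_invalid(kwargs):
    kwargs.setdefault("spin_multiplicity", 2 if kwargs["elements"] == ["H"] else 1)
    with pytest.raises(FrameValidationError):
        Geometry(**kwargs)


def test_xyz_round_trip(tmp_path):
    g = Geometry(elements=["N", "H"], coords=[[0.0, 0.1, 0.2], [1.0, 1.1, 1.2]],
                 total_charge=0, spin_multiplicity=3)
    write_xyz(g, tmp_path / "a.xyz")
    g2 = read_xyz(tmp_path / "a.xyz")
    assert g2.elements == g.elements
    np.testing.assert_allclose(g2.coords, g.coords, atol=1e-9)


# ----------------------------------------------------------------------------
# Molden
# ----------------------------------------------------------------------------

MINIMAL_H_MOLDEN = """\
[Molden Format]
[Atoms] Angs
H 1 1 0.0 0.0 0.0
[GTO]
1 0
 s 3 1.00
  3.42525091E+00 1.5432897E-01
  6.2391373E-01 5.3532814E-01
  1.6885540E-01 4.4463454E-01

[MO]
 Sym= A
 Ene= -0.5
 Spin= Alpha
 Occup= 1.0
   1  1.0
"""


def test_molden_single_hydrogen_identity(tmp_path):
    """One normalized s function, one alpha electron: the 1x1 identity case."""
    p = tmp_path / "h.molden"
    p.write_text(MINIMAL_H_MOLDEN)
    frame = read_molden(p)
    np.testing.assert_allclose(frame.S1, [[1.0]], atol=1e-10)
    np.testing.assert_allclose(frame.C_occ_alpha, [[1.0]], atol=1e-8)
    assert frame.C_occ_beta.shape == (1, 0)
    assert frame.geometry.spin_multiplicity == 2


def test_molden_missing_basis_block_names_section(tmp_path):
    p = tmp_path / "bad.molden"
    p.write_text(MINIMAL_H_MOLDEN.replace("[GTO]", "[NOPE]"))
    with pytest.raises(MoldenFormatError, match="GTO"):
        read_molden(p)


def test_molden_restricted_open_shell_rejected(tmp_path):
    # occupation 1.0 without spin labels: restricted open shell input
    text = MINIMAL_H_MOLDEN.replace(" Spin= Alpha\n", "")
    p = tmp_path / "ro.molden"
    p.write_text(text)
    with pytest.raises(SpinMismatchError):
        read_molden(p)


def test_molden_unnormalizable_orbitals_rejected(tmp_path):
    p = tmp_path / "broken.molden"
    p.write_text(MINIMAL_H_MOLDEN.replace("   1  1.0", "   1  0.5"))
    with pytest.raises(FrameValidationError, match="deviation"):
        read_molden(p)


def test_molden_round_trip_water(tmp_path):
    """Adapter-written Molden file re-reads with orthonormal occupieds."""
    els, coords = WATER
    coords = np.asarray(coords)
    shells = build_molecular_basis(els, coords * BOHR_PER_ANGSTROM, "sto-3g")
    res = uhf(shells, els, coords, 0, 1)
    geom = Geometry(elements=els, coords=coords)
    p = tmp_path / "h2o.molden"
    occ = np.zeros(res.C_alpha.shape[1])
    occ[:res.n_alpha] = 1.0
    write_molden(p, geom, shells, res.C_alpha, res.C_beta, occ, occ,
                 res.eps_alpha, res.eps_beta)
    frame = read_molden(p)
    dev = np.abs(frame.C_occ_alpha.T @ frame.S1 @ frame.C_occ_alpha
                 - np.eye(5)).max()
    assert dev < 1e-8
    assert frame.geometry.total_charge == 0
    # density must match the adapter's, up to sign/rotation: compare projectors
    P_file = frame.C_occ_alpha @ frame.C_occ_alpha.T
    P_ref = res.C_occ_alpha @ res.C_occ_alpha.T
    assert np.abs(P_file - P_ref).max() < 1e-6


# ----------------------------------------------------------------------------
# Frame bundles
# ----------------------------------------------------------------------------

def _random_frame(rng, n_basis=6, n_min=4, arc=0.0):
    """Small synthetic frame with exact invariants (random orthonormal MOs)."""
    A = rng.normal(size=(n_basis, n_basis))
    S1 = A @ A.T + n_basis * np.eye(n_basis)
    S1 /= np.linalg.norm(S1)
    S1 += np.eye(n_basis)
    B = rng.normal(size=(n_min, n_min))
    S2 = B @ B.T + n_min * np.eye(n_min)
    S2 /= np.linalg.norm(S2)
    S2 += np.eye(n_min)
    # He2H+ bookkeeping: 4 electrons, singlet -> 2 occupied per spin
    w, U = np.linalg.eigh(S1)
    X = U @ np.diag(w ** -0.5) @ U.T
    Q, _ = np.linalg.qr(rng.normal(size=(n_basis, 2)))
    C = X @ Q
    return FrameWavefunction(
        geometry=Geometry(elements=["He", "He", "H"],
                          coords=rng.normal(size=(3, 3)),
                          total_charge=1, spin_multiplicity=1),
        arc_coord=arc, energy=float(rng.normal()),
        S1=S1, S12=rng.normal(size=(n_basis, n_min)), S2=S2,
        C_occ_alpha=C, C_occ_beta=C.copy(),
        minimal_basis_atom_map=np.array([0, 1, 2, 2]),
        metadata={"synthetic": True},
    )


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_bundle_round_trip_is_identity(tmp_path_factory, seed):
    """write then read returns field-for-field (bitwise) equal matrices."""
    rng = np.random.default_rng(seed)
    traj = ReactionTrajectory(frames=[_random_frame(rng, arc=float(i))
                                      for i in range(3)])
    path = tmp_path_factory.mktemp("bundle") / "t.h5"
    write_frame_bundle(traj, path)
    back = read_frame_bundle(path)
    assert back.n_frames == 3
    for f0, f1 in zip(traj.frames, back.frames):
        for name in ("S1", "S12", "S2", "C_occ_alpha", "C_occ_beta"):
            assert np.array_equal(getattr(f0, name), getattr(f1, name))
        assert f0.arc_coord == f1.arc_coord
        assert f0.energy == f1.energy
        assert f0.geometry.elements == f1.geometry.elements
        assert np.array_equal(f0.geometry.coords, f1.geometry.coords)
        assert f0.metadata == f1.metadata


def test_bundle_rejects_empty_trajectory(tmp_path):
    with pytest.raises(TrajectoryConsistencyError, match="1 frame"):
        write_frame_bundle(ReactionTrajectory(frames=[]), tmp_path / "e.h5")


def test_bundle_permuted_atoms_names_frame(tmp_path):
    rng = np.random.default_rng(0)
    frames = [_random_frame(rng, arc=float(i)) for i in range(3)]
    frames[2].geometry.elements = ["He", "H", "He"]
    frames[2].minimal_basis_atom_map = np.array([0, 1, 1, 2])
    traj = ReactionTrajectory(frames=frames)
    with pytest.raises(TrajectoryConsistencyError, match="frame 2"):
        write_frame_bundle(traj, tmp_path / "p.h5")


def test_bundle_schema_version_mismatch(tmp_path):
    import h5py

    rng = np.random.default_rng(1)
    traj = ReactionTrajectory(frames=[_random_frame(rng, arc=float(i))
                                      for i in range(2)])
    path = tmp_path / "v.h5"
    write_frame_bundle(traj, path)
    with h5py.File(path, "a") as h5:
        h5.attrs["schema_version"] = "somebody-else-9"
    with pytest.raises(BundleIntegrityError, match=SCHEMA_VERSION):
        read_frame_bundle(path)


def test_bundle_truncated_archive(tmp_path):
    rng = np.random.default_rng(2)
    traj = ReactionTrajectory(frames=[_random_frame(rng, arc=float(i))
                                      for i in range(2)])
    path = tmp_path / "t.h5"
    write_frame_bundle(traj, path)
    data = path.read_bytes()
    path.write_bytes(data[: len(data) // 3])
    with pytest.raises(BundleIntegrityError):
        read_frame_bundle(path)


def test_trajectory_rejects_non_monotone_arc():
    rng = np.random.default_rng(3)
    frames = [_random_frame(rng, arc=a) for a in (0.0, 1.0, 0.5)]
    with pytest.raises(TrajectoryConsistencyError, match="monotone"):
        ReactionTrajectory(frames=frames).validate()


def test_accepted_scf_frame_is_orthonormal(h2o_frame):
    for spin in ("alpha", "beta"):
        C = h2o_frame.occupied(spin)
        dev = np.abs(C.T @ h2o_frame.S1 @ C - np.eye(C.shape[1])).max()
        assert dev < 1e-8


def test_frame_validation_catches_bad_occupation_counts(h2o_frame):
    bad = dataclasses.replace(
        h2o_frame, C_occ_beta=h2o_frame.C_occ_beta[:, :4])
    with pytest.raises(FrameValidationError, match="occupied counts"):
        bad.validate()
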