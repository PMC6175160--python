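"""Shared fixtures: small SCF frames and toy reaction trajectories.

Everything is generated at test time; the heavier trajectories are
session-scoped so the SCF work runs once per test session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ibotrace import integrals
from ibotrace.basis import build_molecular_basis
from ibotrace.frame_io import FrameWavefunction, Geometry
from ibotrace.fixtures import run_toy_reaction
from ibotrace.scf import BOHR_PER_ANGSTROM, uhf


def make_scf_frame(elements, coords, charge=0, multiplicity=1,
                   basis="sto-3g", minimal_basis="sto-3g",
                   arc_coord=0.0) -> FrameWavefunction:
    """Converge an SCF and package the result as a wavefunction frame."""
    coords = np.asarray(coords, dtype=float)
    shells = build_molecular_basis(elements, coords * BOHR_PER_ANGSTROM, basis)
    res = uhf(shells, elements, coords, charge, multiplicity)
    min_shells = build_molecular_basis(elements, coords * BOHR_PER_ANGSTROM,
                                       minimal_basis)
    frame = FrameWavefunction(
        geometry=Geometry(elements=list(elements), coords=coords,
                          total_charge=charge,
                          spin_multiplicity=multiplicity),
        arc_coord=arc_coord, energy=res.energy,
        S1=res.S,
        S12=integrals.overlap_cross(shells, min_shells),
        S2=integrals.overlap(min_shells),
        C_occ_alpha=res.C_occ_alpha, C_occ_beta=res.C_occ_beta,
        minimal_basis_atom_map=np.array(
            [sh.atom_index for sh in min_shells
             for _ in range(sh.n_funcs)], dtype=int),
        computational_basis_name=basis, minimal_basis_name=minimal_basis,
    )
    frame.validate()
    return frame


WATER = (["O", "H", "H"],
         [[0.0, 0.0, 0.1173],
          [0.0, 0.7572, -0.4692],
          [0.0, -0.7572, -0.4692]])


@pytest.fixture(scope="session")
def h2_frame():
    return make_scf_frame(["H", "H"], [[0, 0, 0], [0, 0, 0.7414]])


@pytest.fixture(scope="session")
def he2_frame():
    # two closed-shell atoms: the textbook two-orbital localization case
    return make_scf_frame(["He", "He"], [[0, 0, 0], [0, 0, 3.0]])


@pytest.fixture(scope="session")
def h2o_frame():
    return make_scf_frame(*WATER)


@pytest.fixture(scope="session")
def h2o_frame_631g():
    return make_scf_frame(*WATER, basis="6-31g")


@pytest.fixture(scope="session")
def hat_toy_trajectory():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_toy_reaction("methane_plus_oh", n_frames=9)


@pytest.fixture(scope="session")
def pt_toy_trajectory():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_toy_reaction("ammonia_pt", n_frames=9)


@pytest.fixture(scope="session")
def exchange_toy_trajectory():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_toy_reaction("methyl_exchange", n_frames=7)
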