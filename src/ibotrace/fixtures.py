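"""Test-input generators: synthetic charge trajectories and toy reactions.

Two tiers of inputs exercise the pipeline:

* :func:`make_synthetic` builds per-orbital atomic-charge trajectories with
  the exact flow pattern of each mechanism class (HAT, cPCET, PT,
  closed-shell transfer, flat spectators) — smooth sigmoid interpolation
  between hand-set endpoint distributions, optional Gaussian noise, exact
  ground truth attached.  No wavefunctions involved; these probe tracking,
  metrics and classification in isolation.

* :func:`run_toy_reaction` produces genuine unrestricted-SCF wavefunction
  sequences for desk-scale reactions (hydrogen abstraction from methane by
  hydroxyl radical, symmetric methyl H exchange, proton transfer between
  ammonia and ammonium) along linear-synchronous-transit paths.  These are
  small stand-ins with the same electronic signatures as the enzyme-scale
  systems the method targets; the analysis consumes any ordered path, so a
  transit path serves in place of a true steepest-descent coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals
from .basis import build_molecular_basis
from .frame_io import FrameWavefunction, Geometry, ReactionTrajectory
from .scf import BOHR_PER_ANGSTROM, uhf

__all__ = ["SyntheticScenario", "SyntheticDataset", "make_synthetic",
           "run_toy_reaction", "TOY_REACTIONS", "SYNTHETIC_KINDS"]

SYNTHETIC_KINDS = ("HAT", "cPCET", "PT", "closed_shell_transfer", "flat")
TOY_REACTIONS = ("methane_plus_oh", "methyl_exchange", "ammonia_pt")

DEFAULT_SEED = 20180829


@dataclass(frozen=True)
class SyntheticScenario:
    """Recipe for one synthetic charge-flow trajectory.

    Atom roles are fixed: 0 = donor X, 1 = transferred H, 2 = acceptor
    site Y, 3 = metal centre M, 4.. = spectators.  ``smoothness`` is the
    logistic steepness of the flows; ``noise_sd`` is per-entry Gaussian
    noise (e-) applied before renormalization.
    """

    kind: str
    n_frames: int = 21
    n_atoms: int = 6
    smoothness: float = 8.0
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.kind not in SYNTHETIC_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; "
                             f"choose from {SYNTHETIC_KINDS}")
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5")
        if self.n_atoms < 5:
            raise ValueError("n_atoms must be >= 5")
        if not 0 <= self.noise_sd < 0.05:
            raise ValueError("noise_sd must be in [0, 0.05)")


@dataclass
class SyntheticDataset:
    """Generated charge trajectories plus the generating ground truth."""

    scenario: SyntheticScenario
    charges: dict[str, list[np.ndarray]]   # spin -> per-frame (n_orb, n_atoms)
    arc_coords: np.ndarray
    h_atom: int = 1
    donor_atom: int = 0
    acceptor_atom: int = 2
    metal_atom: int = 3
    expected_verdict: str | None = None
    migrating_spin: str | None = None


X, H, Y, M = 0, 1, 2, 3


def _q(n_atoms: int, **weights: float) -> np.ndarray:
    """Charge vector from named atom weights, remainder spread on spectators."""
    q = np.zeros(n_atoms)
    name_to_idx = {"X": X, "H": H, "Y": Y, "M": M}
    for name, w in weights.items():
        q[name_to_idx[name]] = w
    rest = 1.0 - q.sum()
    spectators = np.arange(4, n_atoms)
    q[spectators] += rest / len(spectators)
    return q


def _orbital_plan(kind: str, n_atoms: int):
    """Per-spin list of (start_q, end_q) pairs implementing the pattern."""
    xh = _q(n_atoms, X=0.55, H=0.42)
    yh = _q(n_atoms, Y=0.55, H=0.42, X=0.01)
    y_lp = _q(n_atoms, Y=0.97)
    yh_from_lp = _q(n_atoms, Y=0.56, H=0.42)
    x_lp = _q(n_atoms, X=0.95, H=0.02)
    m_lp = _q(n_atoms, M=0.98)
    m_gained = _q(n_atoms, M=0.90, Y=0.05, X=0.01, H=0.01)
    spec = _q(n_atoms)

    flat = [(xh, xh), (y_lp, y_lp), (m_lp, m_lp), (spec, spec)]
    plans = {
        "flat": {"alpha": flat, "beta": flat},
        "HAT": {
            "alpha": [(xh, yh), (y_lp, y_lp), (m_lp, m_lp), (spec, spec)],
            "beta": [(xh, x_lp), (y_lp, yh_from_lp), (m_lp, m_lp), (spec, spec)],
        },
        "cPCET": {
            "alpha": [(xh, x_lp), (y_lp, yh_from_lp), (m_lp, m_lp), (spec, spec)],
            "beta": [(xh, m_gained), (y_lp, yh_from_lp), (m_lp, m_lp), (spec, spec)],
        },
        "PT": {
            "alpha": [(xh, x_lp), (y_lp, yh_from_lp), (m_lp, m_lp), (spec, spec)],
            "beta": [(xh, x_lp), (y_lp, yh_from_lp), (m_lp, m_lp), (spec, spec)],
        },
        "closed_shell_transfer": {
            "alpha": [(xh, yh), (y_lp, y_lp), (m_lp, m_lp), (spec, spec)],
            "beta": [(xh, yh), (y_lp, y_lp), (m_lp, m_lp), (spec, spec)],
        },
    }
    return plans[kind]


def _sigmoid_path(t: np.ndarray, k: float) -> np.ndarray:
    """Logistic ramp rescaled to hit exactly 0 at t=0 and 1 at t=1."""
    raw = 1.0 / (1.0 + np.exp(-k * (t - 0.5)))
    lo, hi = raw[0], raw[-1]
    return (raw - lo) / (hi - lo)


def make_synthetic(scenario: SyntheticScenario) -> SyntheticDataset:
    """Generate the charge trajectories of one mechanism scenario.

    At ``noise_sd = 0`` the trajectories realize the scenario's
    decision-table pattern exactly; with noise, entries are perturbed,
    clipped to be non-negative and renormalized to unit orbital charge.
    Reproducible per seed.
    """
    plan = _orbital_plan(scenario.kind, scenario.n_atoms)
    t = np.linspace(0.0, 1.0, scenario.n_frames)
    s = _sigmoid_path(t, scenario.smoothness)
    rng = np.random.default_rng(scenario.seed)
    charges: dict[str, list[np.ndarray]] = {}
    for spin in ("alpha", "beta"):
        per_frame = []
        for st in s:
            mat = np.vstack([
                (1.0 - st) * start + st * end for start, end in plan[spin]
            ])
            if scenario.noise_sd > 0:
                mat = mat + rng.normal(0.0, scenario.noise_sd, mat.shape)
                mat = np.clip(mat, 0.0, None)
            mat = mat / mat.sum(axis=1, keepdims=True)
            per_frame.append(mat)
        charges[spin] = per_frame

    verdict = {"flat": None, "HAT": "HAT", "cPCET": "cPCET", "PT": "PT",
               "closed_shell_transfer": "closed_shell_transfer"}[scenario.kind]
    migrating = {"HAT": "alpha", "cPCET": "beta"}.get(scenario.kind)
    return SyntheticDataset(
        scenario=scenario, charges=charges, arc_coords=t,
        expected_verdict=verdict, migrating_spin=migrating,
    )


# ----------------------------------------------------------------------------
# Toy unrestricted-SCF reactions
# ----------------------------------------------------------------------------

def _ring(n: int, theta_deg: float, r: float, phase: float = 0.0) -> np.ndarray:
    """n bond vectors at polar angle theta from +z, length r."""
    theta = np.deg2rad(theta_deg)
    out = []
    for k in range(n):
        phi = phase + 2.0 * np.pi * k / n
        out.append(r * np.array([np.sin(theta) * np.cos(phi),
                                 np.sin(theta) * np.sin(phi),
                                 np.cos(theta)]))
    return np.array(out)


def _methane_plus_oh_endpoints():
    d_co = 2.90
    tet = 109.4712206
    # C0, H1 (transferred, on +z), H2-4 (methyl umbrella), O5, H6 (hydroxyl)
    def frame(r_ch1, umbrella_deg, r_cme):
        coords = np.zeros((7, 3))
        coords[1] = [0.0, 0.0, r_ch1]
        coords[2:5] = _ring(3, umbrella_deg, r_cme)
        coords[5] = [0.0, 0.0, d_co]
        a = np.deg2rad(104.5)
        coords[6] = coords[5] + 0.97 * np.array([np.sin(a), 0.0, -np.cos(a)])
        return coords

    reactant = frame(1.09, tet, 1.09)
    product = frame(d_co - 0.96, 93.0, 1.08)
    elements = ["C", "H", "H", "H", "H", "O", "H"]
    return elements, reactant, product, 0, 2, {
        "h_atom": 1, "donor_atom": 0, "acceptor_atom": 5}


def _methyl_exchange_endpoints():
    d_cc = 2.75
    tet = 109.4712206

    def frame(r_ch1, donor_deg, acceptor_deg):
        coords = np.zeros((9, 3))
        coords[1] = [0.0, 0.0, r_ch1]
        coords[2:5] = _ring(3, donor_deg, 1.085)
        coords[5] = [0.0, 0.0, d_cc]
        coords[6:9] = coords[5] + _ring(3, acceptor_deg, 1.085, phase=np.pi / 3)
        return coords

    reactant = frame(1.09, tet, 90.0)
    product = frame(d_cc - 1.09, 90.0, 180.0 - tet)
    elements = ["C", "H", "H", "H", "H", "C", "H", "H", "H"]
    return elements, reactant, product, 0, 2, {
        "h_atom": 1, "donor_atom": 0, "acceptor_atom": 5}


def _ammonia_pt_endpoints():
    d_nn = 2.73
    tet = 109.4712206

    def frame(r_nh1, donor_deg, acceptor_deg, r_donor, r_acceptor):
        coords = np.zeros((9, 3))
        coords[1] = [0.0, 0.0, r_nh1]
        coords[2:5] = _ring(3, donor_deg, r_donor)
        coords[5] = [0.0, 0.0, d_nn]
        coords[6:9] = coords[5] + _ring(3, acceptor_deg, r_acceptor,
                                        phase=np.pi / 3)
        return coords

    reactant = frame(1.04, tet, 68.0, 1.03, 1.01)
    product = frame(d_nn - 1.04, 112.0, 180.0 - tet, 1.01, 1.03)
    elements = ["N", "H", "H", "H", "H", "N", "H", "H", "H"]
    return elements, reactant, product, 1, 1, {
        "h_atom": 1, "donor_atom": 0, "acceptor_atom": 5}


_TOY_BUILDERS = {
    "methane_plus_oh": _methane_plus_oh_endpoints,
    "methyl_exchange": _methyl_exchange_endpoints,
    "ammonia_pt": _ammonia_pt_endpoints,
}


def run_toy_reaction(
    name: str,
    n_frames: int = 11,
    basis: str = "sto-3g",
    minimal_basis: str = "sto-3g",
    method: str = "hf",
) -> ReactionTrajectory:
    """Run one toy reaction path and return its wavefunction trajectory.

    The path is a linear synchronous transit between reactant-like and
    product-like structures; each frame's unrestricted SCF starts from the
    previous frame's converged density so the whole sequence stays on one
    electronic branch.  A spin contamination warning is recorded in frame
    metadata when <S^2> deviates by more than 0.8 from the nominal value.
    Classifier atom indices travel in ``trajectory.frames[0].metadata``.
    """
    if name not in _TOY_BUILDERS:
        raise ValueError(f"unknown toy reaction {name!r}; "
                         f"choose from {TOY_REACTIONS}")
    if method not in ("hf", "uhf"):
        raise ValueError("only Hartree-Fock ('hf') determinants are "
                         "implemented for toy reactions")
    elements, reactant, product, charge, multiplicity, roles = _TOY_BUILDERS[name]()
    ts = np.linspace(0.0, 1.0, n_frames)
    s_nominal = (multiplicity - 1) / 2.0
    s2_nominal = s_nominal * (s_nominal + 1.0)

    def chain(order):
        # chained-guess SCF sweep over the given frame order
        results = {}
        guess = None
        for i in order:
            coords = (1.0 - ts[i]) * reactant + ts[i] * product
            shells = build_molecular_basis(elements,
                                           coords * BOHR_PER_ANGSTROM, basis)
            try:
                res = uhf(shells, elements, coords, charge, multiplicity,
                          guess=guess)
            except Exception as exc:
                raise RuntimeError(
                    f"{name}: SCF failed at frame {i} (t={ts[i]:.3f}): {exc}"
                ) from exc
            guess = (res.D_alpha, res.D_beta)
            results[i] = res
        return results

    # sweep from both ends and keep the lower-energy solution per frame:
    # a one-directional chain can stay on an excited (charge-transfer)
    # branch past the avoided crossing
    fwd = chain(range(n_frames))
    bwd = chain(range(n_frames - 1, -1, -1))

    frames = []
    for i, t in enumerate(ts):
        coords = (1.0 - t) * reactant + t * product
        res = fwd[i] if fwd[i].energy <= bwd[i].energy else bwd[i]
        shells = build_molecular_basis(elements, coords * BOHR_PER_ANGSTROM,
                                       basis)
        min_shells = build_molecular_basis(elements,
                                           coords * BOHR_PER_ANGSTROM,
                                           minimal_basis)
        S12 = integrals.overlap_cross(shells, min_shells)
        S2 = integrals.overlap(min_shells)
        atom_map = np.array([sh.atom_index for sh in min_shells
                             for _ in range(sh.n_funcs)], dtype=int)
        metadata = {"s_squared": res.s_squared, "scf_iterations": res.n_iter,
                    "path_parameter": float(t)}
        if i == 0:
            metadata.update(roles)
        if abs(res.s_squared - s2_nominal) > 0.8:
            metadata["spin_contamination_warning"] = (
                f"<S^2>={res.s_squared:.3f} deviates from nominal "
                f"{s2_nominal:.3f}"
            )
        frames.append(FrameWavefunction(
            geometry=Geometry(elements=list(elements), coords=coords,
                              total_charge=charge,
                              spin_multiplicity=multiplicity),
            arc_coord=float(t), energy=res.energy,
            S1=res.S, S12=S12, S2=S2,
            C_occ_alpha=res.C_occ_alpha, C_occ_beta=res.C_occ_beta,
            minimal_basis_atom_map=atom_map,
            computational_basis_name=basis, minimal_basis_name=minimal_basis,
            metadata=metadata,
        ))
    traj = ReactionTrajectory(frames=frames)
    traj.validate()
    return traj
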