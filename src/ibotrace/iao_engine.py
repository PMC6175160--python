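"""Intrinsic atomic orbitals and per-orbital atomic partial charges.

Intrinsic atomic orbitals (IAOs) are polarized, orthonormal atom-centered
orbitals constructed so that the occupied molecular orbitals of a single
determinant are *exactly* expressible in them.  They are built by projecting
the occupied space onto a free-atom minimal reference basis and back
("depolarization"), combining the occupied and complementary projectors
applied to the reference functions, and symmetrically (Löwdin)
orthogonalizing the result.

Because the IAOs are orthonormal, Mulliken-style populations in the IAO
basis are sums of squared expansion coefficients — non-negative by
construction and essentially basis-set independent.  The per-orbital atomic
charge vector q_A(i) = sum over IAOs on atom A of |<iao|phi_i>|^2 is the
quantity every downstream module (localization, tracking, the change metric
and the mechanism classifier) works with.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .frame_io import FrameWavefunction

__all__ = [
    "IAOSet",
    "OrbitalChargeVector",
    "build_iaos",
    "orbital_charges",
    "charges_to_frame_table",
    "charge_table_to_csv",
    "charge_table_from_csv",
    "NumericalConditioningError",
    "SpanError",
]

COND_LIMIT = 1e10
EIG_FLOOR = 1e-10


class NumericalConditioningError(np.linalg.LinAlgError):
    """A metric matrix of the IAO construction is numerically singular."""


class SpanError(ValueError):
    """An orbital does not lie in the span of the supplied IAO set."""


@dataclass
class IAOSet:
    """Orthonormalized intrinsic atomic orbitals of one frame and spin."""

    coeffs: np.ndarray            # computational basis x n_iao
    atom_of_iao: np.ndarray       # iao index -> atom index
    minimal_basis_label: str
    spin: str = "alpha"
    frame_index: int = 0

    @property
    def n_iao(self) -> int:
        return self.coeffs.shape[1]

    def charge_operator(self, S1: np.ndarray) -> np.ndarray:
        """Rows of <iao_rho | . > under the S1 metric: (n_iao, n_basis)."""
        return self.coeffs.T @ S1


@dataclass
class OrbitalChargeVector:
    """Atomic partial-charge distribution of one orbital (sums to 1 e-)."""

    q: np.ndarray
    orbital_id: int
    spin: str
    frame_index: int = 0

    def validate(self, tol: float = 1e-6) -> None:
        if self.q.min() < -1e-10:
            raise ValueError(f"negative orbital charge {self.q.min():.3e}")
        if abs(self.q.sum() - 1.0) > tol:
            raise ValueError(
                f"orbital charges sum to {self.q.sum():.8f}, expected 1"
            )


def _lowdin(M: np.ndarray) -> np.ndarray:
    """M^{-1/2} by symmetric orthogonalization with a hard eigenvalue floor."""
    w, U = np.linalg.eigh((M + M.T) / 2)
    if w.min() < EIG_FLOOR:
        raise NumericalConditioningError(
            f"metric eigenvalue {w.min():.3e} below floor {EIG_FLOOR:g}"
        )
    if w.max() / w.min() > COND_LIMIT:
        raise NumericalConditioningError(
            f"metric condition number {w.max() / w.min():.3e} exceeds "
            f"{COND_LIMIT:g}"
        )
    return U @ np.diag(w ** -0.5) @ U.T


def _sym_orth(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    return C @ _lowdin(C.T @ S @ C)


def build_iaos(frame: FrameWavefunction, spin: str = "alpha") -> IAOSet:
    """Construct the IAO set of one spin channel of a frame.

    Follows the depolarization construction: with C the occupied MOs,
    P12 = S1^-1 S12 the minimal-basis functions expressed in the
    computational basis, and C~ the occupied MOs depolarized through the
    minimal basis, the IAOs are the Löwdin orthonormalization of

        A = (O S1 O~ S1 + (1 - O S1)(1 - O~ S1)) P12,

    where O = C C^T and O~ = C~ C~^T.  The occupied space is contained in
    the span of the result by construction.
    """
    C = frame.occupied(spin)
    S1, S12, S2 = frame.S1, frame.S12, frame.S2
    S1_inv_S12 = np.linalg.solve(S1, S12)
    S2_inv_S21 = np.linalg.solve(S2, S12.T)

    # depolarized occupied orbitals: project to minimal basis and back
    Ct = _sym_orth(S1_inv_S12 @ (S2_inv_S21 @ C), S1)

    OS = C @ (C.T @ S1)          # O S1
    OtS = Ct @ (Ct.T @ S1)       # O~ S1
    n = S1.shape[0]
    A = (OS @ OtS + (np.eye(n) - OS) @ (np.eye(n) - OtS)) @ S1_inv_S12
    A = _sym_orth(A, S1)
    return IAOSet(
        coeffs=A,
        atom_of_iao=frame.minimal_basis_atom_map.copy(),
        minimal_basis_label=frame.minimal_basis_name,
        spin=spin,
    )


def orbital_charges(
    orbital_coeffs: np.ndarray,
    iaos: IAOSet,
    S1: np.ndarray,
    orbital_id: int = 0,
    spin: str | None = None,
    frame_index: int = 0,
    n_atoms: int | None = None,
    span_tol: float = 1e-6,
) -> OrbitalChargeVector:
    """Atomic partial-charge vector q_A = sum_{rho in A} |<iao_rho|phi>|^2."""
    phi = np.asarray(orbital_coeffs, dtype=float).ravel()
    proj = iaos.charge_operator(S1) @ phi          # <iao|phi>
    # residual outside the IAO span signals a frame/IAOSet mismatch
    residual = phi.T @ S1 @ phi - proj @ proj
    if residual > span_tol:
        raise SpanError(
            f"orbital lies outside the IAO span (residual norm^2 "
            f"{residual:.3e}); frame and IAO set are mismatched"
        )
    if n_atoms is None:
        n_atoms = int(iaos.atom_of_iao.max()) + 1
    q = np.zeros(n_atoms)
    np.add.at(q, iaos.atom_of_iao, proj ** 2)
    q = np.clip(q, -1e-10, None)
    return OrbitalChargeVector(
        q=q, orbital_id=orbital_id,
        spin=spin if spin is not None else iaos.spin,
        frame_index=frame_index,
    )


def charges_matrix(C_occ: np.ndarray, iaos: IAOSet, S1: np.ndarray,
                   n_atoms: int | None = None) -> np.ndarray:
    """Charge vectors of a whole occupied set at once: (n_occ, n_atoms)."""
    proj = iaos.charge_operator(S1) @ C_occ       # (n_iao, n_occ)
    if n_atoms is None:
        n_atoms = int(iaos.atom_of_iao.max()) + 1
    Q = np.zeros((C_occ.shape[1], n_atoms))
    for rho, atom in enumerate(iaos.atom_of_iao):
        Q[:, atom] += proj[rho, :] ** 2
    return Q


# ----------------------------------------------------------------------------
# CSV charge tables
# ----------------------------------------------------------------------------

def charges_to_frame_table(charge_vectors, arc_coords=None) -> pd.DataFrame:
    """Long-format table (frame, spin, orbital_id, atom, q) from charge vectors."""
    rows = []
    for cv in charge_vectors:
        for atom, qa in enumerate(cv.q):
            rows.append({
                "frame": cv.frame_index, "spin": cv.spin,
                "orbital_id": cv.orbital_id, "atom": atom, "q": qa,
            })
    df = pd.DataFrame(rows)
    if arc_coords is not None:
        df["arc_coord"] = df["frame"].map(
            {i: a for i, a in enumerate(arc_coords)})
    return df


def charge_table_to_csv(df: pd.DataFrame, path, provenance: str = "") -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False)


def charge_table_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def table_to_charge_vectors(df: pd.DataFrame) -> dict[str, list[list[OrbitalChargeVector]]]:
    """Invert the long table: spin -> per-frame lists of charge vectors."""
    n_atoms = int(df["atom"].max()) + 1
    out: dict[str, list[list[OrbitalChargeVector]]] = {}
    for spin, dspin in df.groupby("spin"):
        frames = []
        for f, dframe in dspin.groupby("frame"):
            vecs = []
            for oid, dorb in dframe.groupby("orbital_id"):
                q = np.zeros(n_atoms)
                q[dorb["atom"].to_numpy()] = dorb["q"].to_numpy()
                vecs.append(OrbitalChargeVector(
                    q=q, orbital_id=int(oid), spin=str(spin),
                    frame_index=int(f)))
            frames.append(vecs)
        out[str(spin)] = frames
    return out
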