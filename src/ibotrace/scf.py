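"""Minimal unrestricted Hartree–Fock for toy fixture molecules.

Single-determinant wavefunctions along a reaction path are all the analysis
pipeline needs; this solver produces them for molecules of a handful of
atoms in small s/p bases.  It supports chained initial guesses (the converged
density of the previous path point), which keeps consecutive frames on the
same electronic branch the way an IRC wavefunction sequence behaves.

Closed-shell molecules are treated as the spin-restricted special case of
the same UHF equations (identical alpha and beta orbitals at convergence
from a spin-symmetric guess).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals
from .basis import BasisShell, ELEMENTS

__all__ = ["SCFResult", "uhf", "BOHR_PER_ANGSTROM"]

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFResult:
    energy: float                 # total energy, Hartree
    C_alpha: np.ndarray           # full MO coefficient matrices
    C_beta: np.ndarray
    eps_alpha: np.ndarray
    eps_beta: np.ndarray
    n_alpha: int
    n_beta: int
    S: np.ndarray
    D_alpha: np.ndarray
    D_beta: np.ndarray
    n_iter: int
    s_squared: float              # UHF <S^2> expectation

    @property
    def C_occ_alpha(self) -> np.ndarray:
        return self.C_alpha[:, : self.n_alpha]

    @property
    def C_occ_beta(self) -> np.ndarray:
        return self.C_beta[:, : self.n_beta]


def nuclear_repulsion(Z: np.ndarray, coords_bohr: np.ndarray) -> float:
    e = 0.0
    for i in range(len(Z)):
        for j in range(i):
            e += Z[i] * Z[j] / np.linalg.norm(coords_bohr[i] - coords_bohr[j])
    return e


def _density(C: np.ndarray, nocc: int) -> np.ndarray:
    Co = C[:, :nocc]
    return Co @ Co.T


def _spin_squared(Ca, Cb, S, na, nb):
    # <S^2> = Sz(Sz+1) + Nb - sum_ij |<a_i|S|b_j>|^2
    sz = (na - nb) / 2.0
    ov = Ca[:, :na].T @ S @ Cb[:, :nb]
    return sz * (sz + 1.0) + nb - np.sum(ov * ov)


def uhf(
    shells: list[BasisShell],
    elements: list[str],
    coords_angstrom: np.ndarray,
    charge: int = 0,
    multiplicity: int = 1,
    guess: tuple[np.ndarray, np.ndarray] | None = None,
    conv_tol: float = 1e-9,
    max_iter: int = 200,
) -> SCFResult:
    """Solve the UHF equations; ``guess`` is an optional (D_alpha, D_beta)."""
    coords_bohr = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM
    Z = np.array([ELEMENTS[e] for e in elements], dtype=float)
    nelec = int(Z.sum()) - charge
    n_alpha = (nelec + multiplicity - 1) // 2
    n_beta = nelec - n_alpha
    if n_alpha - n_beta != multiplicity - 1 or n_beta < 0:
        raise ValueError(
            f"charge={charge}, multiplicity={multiplicity} inconsistent with "
            f"{nelec} electrons"
        )

    S = integrals.overlap(shells)
    T = integrals.kinetic(shells)
    V = integrals.nuclear_attraction(shells, Z, coords_bohr)
    eri = integrals.electron_repulsion(shells)
    H = T + V
    E_nuc = nuclear_repulsion(Z, coords_bohr)

    # symmetric orthogonalizer
    w, U = np.linalg.eigh(S)
    if w.min() < 1e-10:
        raise np.linalg.LinAlgError("overlap matrix is numerically singular")
    X = U @ np.diag(w ** -0.5) @ U.T

    if guess is not None:
        Da, Db = guess
    else:
        # core-Hamiltonian guess, spin symmetry broken by tiny alpha bias
        eps, C = np.linalg.eigh(X @ H @ X)
        C = X @ C
        Da = _density(C, n_alpha)
        Db = _density(C, n_beta)

    def fock(Da, Db):
        J = np.einsum("pqrs,rs->pq", eri, Da + Db, optimize=True)
        Ka = np.einsum("prqs,rs->pq", eri, Da, optimize=True)
        Kb = np.einsum("prqs,rs->pq", eri, Db, optimize=True)
        return H + J - Ka, H + J - Kb

    diis_F: list[tuple[np.ndarray, np.ndarray]] = []
    diis_e: list[np.ndarray] = []
    E_old = None
    for it in range(1, max_iter + 1):
        Fa, Fb = fock(Da, Db)
        E = E_nuc + 0.5 * (np.sum((H + Fa) * Da) + np.sum((H + Fb) * Db))

        err_a = X.T @ (Fa @ Da @ S - S @ Da @ Fa) @ X
        err_b = X.T @ (Fb @ Db @ S - S @ Db @ Fb) @ X
        err = np.concatenate([err_a.ravel(), err_b.ravel()])
        err_norm = np.abs(err).max()

        if E_old is not None and abs(E - E_old) < conv_tol and err_norm < 1e-6:
            break
        E_old = E

        diis_F.append((Fa, Fb))
        diis_e.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_e.pop(0)
        if len(diis_F) >= 2:
            n = len(diis_e)
            B = np.empty((n + 1, n + 1))
            B[-1, :] = -1.0
            B[:, -1] = -1.0
            B[-1, -1] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = diis_e[i] @ diis_e[j]
            rhs = np.zeros(n + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:n]
                Fa = sum(ci * Fi[0] for ci, Fi in zip(c, diis_F))
                Fb = sum(ci * Fi[1] for ci, Fi in zip(c, diis_F))
            except np.linalg.LinAlgError:
                pass

        eps_a, Ca = np.linalg.eigh(X @ Fa @ X)
        eps_b, Cb = np.linalg.eigh(X @ Fb @ X)
        Ca = X @ Ca
        Cb = X @ Cb
        Da_new = _density(Ca, n_alpha)
        Db_new = _density(Cb, n_beta)
        # light damping in the first iterations stabilizes radical cases
        lam = 0.3 if it <= 3 and guess is None else 1.0
        Da = lam * Da_new + (1 - lam) * Da
        Db = lam * Db_new + (1 - lam) * Db
    else:
        raise SCFConvergenceError(
            f"SCF not converged in {max_iter} iterations "
            f"(last |dE|={abs(E - E_old):.3e})"
        )

    # final clean diagonalization from converged Fock
    Fa, Fb = fock(Da, Db)
    eps_a, Ca = np.linalg.eigh(X @ Fa @ X)
    eps_b, Cb = np.linalg.eigh(X @ Fb @ X)
    Ca = X @ Ca
    Cb = X @ Cb
    Da = _density(Ca, n_alpha)
    Db = _density(Cb, n_beta)
    E = E_nuc + 0.5 * (np.sum((H + Fa) * Da) + np.sum((H + Fb) * Db))
    return SCFResult(
        energy=E, C_alpha=Ca, C_beta=Cb, eps_alpha=eps_a, eps_beta=eps_b,
        n_alpha=n_alpha, n_beta=n_beta, S=S, D_alpha=Da, D_beta=Db,
        n_iter=it, s_squared=_spin_squared(Ca, Cb, S, n_alpha, n_beta),
    )
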