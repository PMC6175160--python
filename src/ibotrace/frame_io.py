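"""Reading, validating and persisting reaction-path wavefunction data.

A *frame* is one point of a reaction path: geometry, overlap matrices and
the occupied molecular-orbital coefficients of both spin channels.  Frames
arrive either from Molden files exported by a quantum-chemistry program or
from this project's frame-bundle archive (an HDF5 container storing every
matrix at full precision, schema tag ``ibotrace-frame-1``).

The overlap matrices are part of the frame contract: S1 is the overlap of
the computational basis, S2 that of the minimal reference basis used for
the intrinsic-atomic-orbital construction, and S12 the cross overlap
between the two.  When a Molden file carries no sidecar overlaps they are
computed once on read through the built-in integral engine.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import integrals
from .basis import ELEMENTS, BasisShell, build_molecular_basis
from .scf import BOHR_PER_ANGSTROM

__all__ = [
    "Geometry",
    "FrameWavefunction",
    "ReactionTrajectory",
    "read_molden",
    "write_molden",
    "read_frame_bundle",
    "write_frame_bundle",
    "read_xyz",
    "write_xyz",
    "SCHEMA_VERSION",
    "MoldenFormatError",
    "SpinMismatchError",
    "FrameValidationError",
    "TrajectoryConsistencyError",
    "BundleIntegrityError",
]

SCHEMA_VERSION = "ibotrace-frame-1"

ORTHO_TOL = 1e-8          # orthonormality every accepted frame must satisfy
MOLDEN_ORTHO_REJECT = 1e-4  # beyond this a Molden file is considered broken


class MoldenFormatError(ValueError):
    """Molden file is missing a required section or cannot be parsed."""


class SpinMismatchError(ValueError):
    """Restricted orbitals supplied where an open-shell frame was requested."""


class FrameValidationError(ValueError):
    """A frame violates its mathematical invariants."""


class TrajectoryConsistencyError(ValueError):
    """Frames of one trajectory disagree on atoms, basis or electron count."""


class BundleIntegrityError(RuntimeError):
    """Frame-bundle archive is truncated, corrupt, or of a foreign schema."""


# ----------------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------------

@dataclass
class Geometry:
    """Molecular geometry with charge and spin state.

    Coordinates are stored in Å.  ``spin_multiplicity`` is 2S+1; together
    with the total charge it fixes the per-spin electron counts.
    """

    elements: list[str]
    coords: np.ndarray
    total_charge: int = 0
    spin_multiplicity: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return int(sum(ELEMENTS[e] for e in self.elements)) - self.total_charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.spin_multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    def validate(self) -> None:
        for e in self.elements:
            if e not in ELEMENTS:
                raise FrameValidationError(f"unknown element symbol {e!r}")
        if len(self.elements) != len(self.coords):
            raise FrameValidationError("element and coordinate counts differ")
        if not np.all(np.isfinite(self.coords)):
            raise FrameValidationError("non-finite coordinates")
        if self.spin_multiplicity < 1:
            raise FrameValidationError("spin multiplicity must be >= 1")
        excess = self.n_electrons - (self.spin_multiplicity - 1)
        if excess < 0 or excess % 2 != 0:
            raise FrameValidationError(
                f"spin multiplicity {self.spin_multiplicity} impossible for "
                f"{self.n_electrons} electrons"
            )


@dataclass
class FrameWavefunction:
    """One reaction-path point: geometry, overlaps, occupied MOs per spin."""

    geometry: Geometry
    arc_coord: float
    S1: np.ndarray
    S12: np.ndarray
    S2: np.ndarray
    C_occ_alpha: np.ndarray
    C_occ_beta: np.ndarray
    minimal_basis_atom_map: np.ndarray
    energy: float | None = None
    computational_basis_name: str | None = None
    minimal_basis_name: str = "sto-3g"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("S1", "S12", "S2", "C_occ_alpha", "C_occ_beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.minimal_basis_atom_map = np.asarray(self.minimal_basis_atom_map,
                                                 dtype=int)

    @property
    def n_occ_alpha(self) -> int:
        return self.C_occ_alpha.shape[1]

    @property
    def n_occ_beta(self) -> int:
        return self.C_occ_beta.shape[1]

    @property
    def n_basis(self) -> int:
        return self.S1.shape[0]

    def validate(self, ortho_tol: float = ORTHO_TOL) -> None:
        g = self.geometry
        g.validate()
        for name, S in (("S1", self.S1), ("S2", self.S2)):
            if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
                raise FrameValidationError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise FrameValidationError(f"{name} is not positive definite")
        if self.S12.shape != (self.S1.shape[0], self.S2.shape[0]):
            raise FrameValidationError("S12 shape inconsistent with S1/S2")
        if self.minimal_basis_atom_map.shape != (self.S2.shape[0],):
            raise FrameValidationError("minimal_basis_atom_map length != dim(S2)")
        if self.n_occ_alpha != g.n_alpha or self.n_occ_beta != g.n_beta:
            raise FrameValidationError(
                f"occupied counts ({self.n_occ_alpha}a/{self.n_occ_beta}b) do "
                f"not match charge/multiplicity ({g.n_alpha}a/{g.n_beta}b)"
            )
        if self.n_occ_alpha < self.n_occ_beta:
            raise FrameValidationError("n_occ_alpha < n_occ_beta")
        for spin, C in (("alpha", self.C_occ_alpha), ("beta", self.C_occ_beta)):
            if C.size == 0:
                continue
            dev = np.abs(C.T @ self.S1 @ C - np.eye(C.shape[1])).max()
            if dev > ortho_tol:
                raise FrameValidationError(
                    f"{spin} occupied orbitals not orthonormal "
                    f"(worst deviation {dev:.3e})"
                )

    def occupied(self, spin: str) -> np.ndarray:
        if spin in ("alpha", "a"):
            return self.C_occ_alpha
        if spin in ("beta", "b"):
            return self.C_occ_beta
        raise ValueError(f"spin must be 'alpha' or 'beta', got {spin!r}")


@dataclass
class ReactionTrajectory:
    """Ordered frames of one reaction path (reactant towards product)."""

    frames: list[FrameWavefunction]
    direction_label: str = "reactant->product"

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def arc_coords(self) -> np.ndarray:
        return np.array([f.arc_coord for f in self.frames])

    def validate(self) -> None:
        if not self.frames:
            raise TrajectoryConsistencyError("trajectory must contain >= 1 frame")
        arcs = self.arc_coords()
        if len(arcs) > 1 and not np.all(np.diff(arcs) > 0):
            raise TrajectoryConsistencyError("arc_coord must be strictly monotone")
        ref = self.frames[0]
        for i, f in enumerate(self.frames):
            f.validate()
            if f.geometry.elements != ref.geometry.elements:
                raise TrajectoryConsistencyError(
                    f"frame {i}: atom identity/order differs from frame 0"
                )
            if f.n_basis != ref.n_basis or f.S2.shape != ref.S2.shape:
                raise TrajectoryConsistencyError(
                    f"frame {i}: basis dimensions differ from frame 0"
                )
            if (f.n_occ_alpha, f.n_occ_beta) != (ref.n_occ_alpha, ref.n_occ_beta):
                raise TrajectoryConsistencyError(
                    f"frame {i}: electron counts differ from frame 0"
                )


# ----------------------------------------------------------------------------
# XYZ
# ----------------------------------------------------------------------------

def read_xyz(path) -> Geometry:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return Geometry(elements=elements, coords=np.array(coords))


def write_xyz(geometry: Geometry, path, comment: str = "") -> None:
    lines = [str(geometry.n_atoms), comment]
    for e, xyz in zip(geometry.elements, geometry.coords):
        lines.append(f"{e:2s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------------
# Molden
# ----------------------------------------------------------------------------

_MOLDEN_SECTION = re.compile(r"^\s*\[([A-Za-z0-9 _]+)\]\s*(.*)$")


def _molden_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        m = _MOLDEN_SECTION.match(raw)
        if m:
            current = m.group(1).strip().lower()
            sections[current] = []
            rest = m.group(2).strip()
            if rest:
                sections[current].append(rest)
        elif current is not None:
            if raw.strip():
                sections[current].append(raw.rstrip())
    return sections


def read_molden(
    path,
    minimal_basis: str = "sto-3g",
    arc_coord: float = 0.0,
    energy: float | None = None,
    expected_multiplicity: int | None = None,
    overlaps: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FrameWavefunction:
    """Read one wavefunction frame from a Molden file.

    Occupations above 0.5 electrons count an orbital as occupied; genuinely
    fractional occupations are rejected because the analysis is defined for
    single determinants only.  Spherical (``[5D]``) and Cartesian d shells
    are both accepted and the detected dialect is recorded in the frame
    metadata.  Overlap matrices are computed from the basis specification
    unless supplied via ``overlaps`` (S1, S12, S2).
    """
    text = Path(path).read_text()
    sec = _molden_sections(text)
    for required in ("atoms", "gto", "mo"):
        if required not in sec:
            raise MoldenFormatError(
                f"{path}: missing required Molden section [{required.upper()}]"
            )

    # --- geometry ------------------------------------------------------
    head = sec["atoms"]
    unit = "angs"
    if head and head[0].lower() in ("angs", "au", "(angs)", "(au)"):
        unit = head[0].lower().strip("()")
        atom_lines = head[1:]
    else:
        # unit may have been written on the section line itself
        atom_lines = head
    elements, coords = [], []
    for ln in atom_lines:
        parts = ln.split()
        elements.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[3:6]])
    coords_arr = np.array(coords)
    if unit == "au":
        coords_arr = coords_arr / BOHR_PER_ANGSTROM

    # --- basis ---------------------------------------------------------
    pure_d = "5d" in sec or "5d7f" in sec or "5d10f" in sec
    pure_f = "7f" in sec or "5d7f" in sec
    if pure_f:
        raise MoldenFormatError(
            f"{path}: spherical f shells ([7F]) are not supported; "
            "export Cartesian f functions or drop f shells"
        )
    shells = _parse_gto(sec["gto"], coords_arr * BOHR_PER_ANGSTROM, pure_d)

    # --- molecular orbitals --------------------------------------------
    nbf = sum(sh.n_funcs for sh in shells)
    mos = _parse_mo(sec["mo"], nbf, path)
    occ_a = [m for m in mos if m["spin"] == "alpha" and m["occ"] > 0.5]
    occ_b = [m for m in mos if m["spin"] == "beta" and m["occ"] > 0.5]
    # explicit Spin= labels mark an unrestricted file even when every MO is
    # alpha (e.g. one-electron systems); bare files are restricted exports
    restricted = not any(m["spin_explicit"] for m in mos)
    if restricted:
        for m in occ_a:
            if abs(m["occ"] - 2.0) > 1e-6 and abs(m["occ"] - 1.0) > 1e-6:
                raise MoldenFormatError(
                    f"{path}: fractional occupation {m['occ']} unsupported"
                )
        if any(abs(m["occ"] - 1.0) < 1e-6 for m in occ_a):
            raise SpinMismatchError(
                f"{path}: restricted open-shell orbitals found; this reader "
                "requires unrestricted (spin-labelled) orbitals for "
                "open-shell frames"
            )
        occ_b = occ_a
    else:
        for m in occ_a + occ_b:
            if abs(m["occ"] - 1.0) > 1e-6:
                raise MoldenFormatError(
                    f"{path}: fractional occupation {m['occ']} unsupported"
                )

    n_alpha, n_beta = len(occ_a), len(occ_b)
    multiplicity = n_alpha - n_beta + 1
    if expected_multiplicity is not None and multiplicity != expected_multiplicity:
        raise SpinMismatchError(
            f"{path}: file implies multiplicity {multiplicity}, "
            f"caller requested {expected_multiplicity}"
        )
    nelec = n_alpha + n_beta
    charge = int(sum(ELEMENTS[e] for e in elements)) - nelec
    geometry = Geometry(elements=elements, coords=coords_arr,
                        total_charge=charge, spin_multiplicity=multiplicity)

    Ca = np.column_stack([m["coeffs"] for m in occ_a]) if occ_a else np.zeros((nbf, 0))
    Cb = np.column_stack([m["coeffs"] for m in occ_b]) if occ_b else np.zeros((nbf, 0))

    # --- overlaps ------------------------------------------------------
    if overlaps is not None:
        S1, S12, S2 = (np.asarray(x, dtype=float) for x in overlaps)
    else:
        S1 = integrals.overlap(shells)
        min_shells = build_molecular_basis(elements, coords_arr * BOHR_PER_ANGSTROM,
                                           minimal_basis)
        S12 = integrals.overlap_cross(shells, min_shells)
        S2 = integrals.overlap(min_shells)
    min_shells = build_molecular_basis(elements, coords_arr * BOHR_PER_ANGSTROM,
                                       minimal_basis)
    atom_map = np.array([sh.atom_index for sh in min_shells
                         for _ in range(sh.n_funcs)], dtype=int)

    # --- orthonormality: reject broken files, repair print truncation ---
    reortho = False
    for C in (Ca, Cb):
        if C.size == 0:
            continue
        dev = np.abs(C.T @ S1 @ C - np.eye(C.shape[1])).max()
        if dev > MOLDEN_ORTHO_REJECT:
            raise FrameValidationError(
                f"{path}: occupied orbitals not normalizable under the "
                f"declared basis (worst deviation {dev:.3e})"
            )
        if dev > ORTHO_TOL:
            reortho = True
    if reortho:
        Ca = _symmetric_reorthonormalize(Ca, S1)
        Cb = _symmetric_reorthonormalize(Cb, S1)

    frame = FrameWavefunction(
        geometry=geometry, arc_coord=arc_coord, energy=energy,
        S1=S1, S12=S12, S2=S2, C_occ_alpha=Ca, C_occ_beta=Cb,
        minimal_basis_atom_map=atom_map,
        minimal_basis_name=minimal_basis,
        metadata={
            "source": str(path),
            "dialect": "spherical-d" if pure_d else "cartesian",
            "restricted_input": restricted,
            "reorthonormalized": reortho,
        },
    )
    frame.validate()
    return frame


def _symmetric_reorthonormalize(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Löwdin orthonormalization within the span of the given orbitals."""
    if C.size == 0:
        return C
    M = C.T @ S @ C
    w, U = np.linalg.eigh(M)
    return C @ (U @ np.diag(w ** -0.5) @ U.T)


def _parse_gto(lines: list[str], coords_bohr: np.ndarray,
               pure_d: bool) -> list[BasisShell]:
    shells: list[BasisShell] = []
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        atom_idx = int(parts[0]) - 1
        i += 1
        while i < len(lines):
            head = lines[i].split()
            if len(head) >= 2 and head[0].isdigit():
                break  # next atom header
            if not head:
                i += 1
                break
            ltag = head[0].lower()
            nprim = int(head[1])
            i += 1
            rows = []
            for _ in range(nprim):
                rows.append([float(x.replace("D", "E").replace("d", "e"))
                             for x in lines[i].split()])
                i += 1
            rows_arr = np.array(rows)
            if ltag == "sp":
                for l, col in ((0, 1), (1, 2)):
                    shells.append(BasisShell(
                        atom_index=atom_idx, angular_momentum=l,
                        exponents=rows_arr[:, 0],
                        contraction_coeffs=rows_arr[:, col],
                        center=coords_bohr[atom_idx]))
            else:
                l = "spdfg".index(ltag)
                shells.append(BasisShell(
                    atom_index=atom_idx, angular_momentum=l,
                    exponents=rows_arr[:, 0], contraction_coeffs=rows_arr[:, 1],
                    pure=pure_d and l >= 2,
                    center=coords_bohr[atom_idx]))
    return shells


def _parse_mo(lines: list[str], nbf: int, path) -> list[dict]:
    mos: list[dict] = []
    cur: dict | None = None
    for ln in lines:
        stripped = ln.strip()
        m = re.match(r"^(Sym|Ene|Spin|Occup)\s*=\s*(\S+)", stripped, re.I)
        if m:
            key = m.group(1).lower()
            if key == "sym" or (key == "ene" and cur is not None and cur["rows"]):
                if cur is not None and cur["rows"]:
                    mos.append(_finish_mo(cur, nbf, path))
                    cur = None
            if cur is None:
                cur = {"spin": "alpha", "occ": 0.0, "energy": 0.0,
                       "rows": [], "spin_explicit": False}
            if key == "spin":
                cur["spin"] = m.group(2).lower()
                cur["spin_explicit"] = True
            elif key == "occup":
                cur["occ"] = float(m.group(2))
            elif key == "ene":
                cur["energy"] = float(m.group(2))
        else:
            parts = stripped.split()
            if len(parts) == 2 and cur is not None:
                cur["rows"].append((int(parts[0]) - 1, float(parts[1])))
    if cur is not None and cur["rows"]:
        mos.append(_finish_mo(cur, nbf, path))
    if not mos:
        raise MoldenFormatError(f"{path}: [MO] section contains no orbitals")
    return mos


def _finish_mo(cur: dict, nbf: int, path) -> dict:
    coeffs = np.zeros(nbf)
    for idx, val in cur["rows"]:
        if idx >= nbf:
            raise MoldenFormatError(
                f"{path}: MO coefficient index {idx + 1} exceeds basis size {nbf}"
            )
        coeffs[idx] = val
    cur["coeffs"] = coeffs
    return cur


def write_molden(
    path,
    geometry: Geometry,
    shells: list[BasisShell],
    C_alpha: np.ndarray,
    C_beta: np.ndarray,
    occ_alpha: np.ndarray,
    occ_beta: np.ndarray,
    energies_alpha: np.ndarray | None = None,
    energies_beta: np.ndarray | None = None,
) -> None:
    """Write an unrestricted Molden file (Cartesian shells, full precision)."""
    lines = ["[Molden Format]", "[Atoms] Angs"]
    for i, (e, xyz) in enumerate(zip(geometry.elements, geometry.coords), 1):
        lines.append(f"{e:2s} {i:4d} {ELEMENTS[e]:3d} "
                     f"{xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}")
    lines.append("[GTO]")
    by_atom: dict[int, list[BasisShell]] = {}
    for sh in shells:
        if sh.pure:
            raise ValueError("write_molden only emits Cartesian shells")
        by_atom.setdefault(sh.atom_index, []).append(sh)
    for ia in range(geometry.n_atoms):
        lines.append(f"{ia + 1} 0")
        for sh in by_atom.get(ia, []):
            lines.append(f" {sh.letter} {len(sh.exponents)} 1.00")
            for a, c in zip(sh.exponents, sh.contraction_coeffs):
                lines.append(f"  {a:20.10E} {c:20.10E}")
        lines.append("")
    lines.append("[MO]")

    def emit(C, occs, energies, spin):
        for k in range(C.shape[1]):
            e = 0.0 if energies is None else energies[k]
            lines.append(" Sym= A")
            lines.append(f" Ene= {e:.10f}")
            lines.append(f" Spin= {spin}")
            lines.append(f" Occup= {occs[k]:.6f}")
            for ib in range(C.shape[0]):
                lines.append(f" {ib + 1:4d} {C[ib, k]: .16E}")

    emit(C_alpha, occ_alpha, energies_alpha, "Alpha")
    emit(C_beta, occ_beta, energies_beta, "Beta")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------------
# Frame bundle (HDF5)
# ----------------------------------------------------------------------------

def write_frame_bundle(trajectory: ReactionTrajectory, path) -> None:
    """Persist a validated trajectory to an HDF5 frame bundle."""
    trajectory.validate()
    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["n_frames"] = trajectory.n_frames
        h5.attrs["direction_label"] = trajectory.direction_label
        for i, f in enumerate(trajectory.frames):
            g = h5.create_group(f"frame_{i:04d}")
            g.attrs["elements"] = json.dumps(f.geometry.elements)
            g.attrs["total_charge"] = f.geometry.total_charge
            g.attrs["spin_multiplicity"] = f.geometry.spin_multiplicity
            g.attrs["arc_coord"] = f.arc_coord
            g.attrs["energy"] = np.nan if f.energy is None else f.energy
            g.attrs["computational_basis_name"] = f.computational_basis_name or ""
            g.attrs["minimal_basis_name"] = f.minimal_basis_name
            g.attrs["metadata"] = json.dumps(f.metadata)
            g.create_dataset("coords", data=f.geometry.coords)
            for name in ("S1", "S12", "S2", "C_occ_alpha", "C_occ_beta"):
                g.create_dataset(name, data=getattr(f, name))
            g.create_dataset("minimal_basis_atom_map",
                             data=f.minimal_basis_atom_map)


def read_frame_bundle(path) -> ReactionTrajectory:
    """Read a frame bundle back; exact inverse of :func:`write_frame_bundle`."""
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise BundleIntegrityError(f"{path}: unreadable or truncated archive "
                                   f"({exc})") from exc
    with h5:
        version = h5.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise BundleIntegrityError(
                f"{path}: schema version {version!r} != expected "
                f"{SCHEMA_VERSION!r}"
            )
        n = int(h5.attrs["n_frames"])
        frames = []
        for i in range(n):
            key = f"frame_{i:04d}"
            if key not in h5:
                raise BundleIntegrityError(f"{path}: missing group {key}")
            g = h5[key]
            energy = float(g.attrs["energy"])
            frames.append(FrameWavefunction(
                geometry=Geometry(
                    elements=json.loads(g.attrs["elements"]),
                    coords=g["coords"][()],
                    total_charge=int(g.attrs["total_charge"]),
                    spin_multiplicity=int(g.attrs["spin_multiplicity"]),
                ),
                arc_coord=float(g.attrs["arc_coord"]),
                energy=None if np.isnan(energy) else energy,
                S1=g["S1"][()], S12=g["S12"][()], S2=g["S2"][()],
                C_occ_alpha=g["C_occ_alpha"][()],
                C_occ_beta=g["C_occ_beta"][()],
                minimal_basis_atom_map=g["minimal_basis_atom_map"][()],
                computational_basis_name=(
                    g.attrs["computational_basis_name"] or None),
                minimal_basis_name=str(g.attrs["minimal_basis_name"]),
                metadata=json.loads(g.attrs["metadata"]),
            ))
    traj = ReactionTrajectory(frames=frames)
    traj.validate()
    return traj
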