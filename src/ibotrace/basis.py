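"""Gaussian basis-set handling.

Basis sets are read from plain-text files in the Gaussian94 exchange format
(``*.gbs``) shipped under :mod:`ibotrace.data`, or parsed from Molden ``[GTO]``
blocks.  A molecular basis is a flat list of :class:`BasisShell` objects; every
shell knows which atom owns it, so the AO -> atom map needed for atomic charge
partitioning falls out directly.

Angular momentum conventions
----------------------------
Shells are stored as contracted Cartesian Gaussians.  A shell may be flagged
``pure`` (real solid-harmonic / spherical), in which case the AO functions it
contributes are the 2l+1 spherical components obtained from the Cartesian ones
by the standard transformation (supported for l <= 2; spherical f/g shells
raise).  Cartesian component ordering follows the Molden convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "BasisShell",
    "load_basis",
    "available_bases",
    "build_molecular_basis",
    "n_ao",
    "ao_atom_map",
    "cart_components",
    "c2s_matrix",
    "UnsupportedElementError",
]

_ANGMOM_LETTERS = "spdfghi"

#: elements -> atomic number, restricted to what ships with the package plus
#: the heavier elements that may appear in externally produced trajectories.
ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Sc": 21, "Ti": 22,
    "V": 23, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29,
    "Zn": 30, "Br": 35, "I": 53,
}


class UnsupportedElementError(ValueError):
    """An element is absent from the requested basis-set file."""


@dataclass
class BasisShell:
    """One contracted shell of Gaussian primitives on one atom.

    Parameters mirror the usual quantum-chemistry conventions: ``exponents``
    are the primitive Gaussian exponents (bohr^-2, strictly positive) and
    ``contraction_coeffs`` the contraction coefficients referring to
    normalized primitives.
    """

    atom_index: int
    angular_momentum: int
    exponents: np.ndarray
    contraction_coeffs: np.ndarray
    pure: bool = False
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))  # bohr

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.contraction_coeffs = np.asarray(self.contraction_coeffs, dtype=float)
        if self.angular_momentum < 0:
            raise ValueError("angular momentum must be >= 0")
        if self.exponents.shape != self.contraction_coeffs.shape:
            raise ValueError("exponents and contraction_coeffs must have equal length")
        if not np.all(self.exponents > 0):
            raise ValueError("primitive exponents must be strictly positive")

    @property
    def n_funcs(self) -> int:
        l = self.angular_momentum
        return 2 * l + 1 if self.pure else (l + 1) * (l + 2) // 2

    @property
    def letter(self) -> str:
        return _ANGMOM_LETTERS[self.angular_momentum]


def cart_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian (lx, ly, lz) exponent triples of a shell, Molden ordering."""
    if l == 0:
        return [(0, 0, 0)]
    if l == 1:
        return [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    if l == 2:
        return [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
    if l == 3:
        return [(3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 2, 0), (2, 1, 0),
                (2, 0, 1), (1, 0, 2), (0, 1, 2), (0, 2, 1), (1, 1, 1)]
    if l == 4:
        return [(4, 0, 0), (0, 4, 0), (0, 0, 4), (3, 1, 0), (3, 0, 1),
                (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3), (2, 2, 0),
                (2, 0, 2), (0, 2, 2), (2, 1, 1), (1, 2, 1), (1, 1, 2)]
    raise NotImplementedError(f"Cartesian ordering not defined for l={l}")


# Spherical d components in Molden order m = 0, +1, -1, +2, -2, expressed in
# normalized Cartesians (xx, yy, zz, xy, xz, yz).
_SQRT3_2 = np.sqrt(3.0) / 2.0
_C2S_D = np.array([
    [-0.5, -0.5, 1.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    [_SQRT3_2, -_SQRT3_2, 0.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
])


def c2s_matrix(l: int) -> np.ndarray:
    """Spherical-from-Cartesian coefficient matrix for one shell.

    Rows are spherical components (Molden m ordering), columns normalized
    Cartesian components.  Only s, p and d shells are supported; spherical
    f and higher shells raise :class:`NotImplementedError`.
    """
    if l == 0:
        return np.eye(1)
    if l == 1:
        return np.eye(3)
    if l == 2:
        return _C2S_D.copy()
    raise NotImplementedError(
        f"spherical shells with l={l} are not supported; "
        "use Cartesian functions for f and higher"
    )


# ----------------------------------------------------------------------------
# Gaussian94 format parsing
# ----------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("ibotrace").joinpath("data", name)))


def available_bases() -> list[str]:
    """Names of the basis sets shipped with the package."""
    data_dir = _data_path("")
    return sorted(p.stem for p in Path(data_dir).glob("*.gbs"))


def load_basis(name_or_path: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse a Gaussian94 basis file into per-element shell templates.

    Returns a mapping ``element symbol -> list of (l, exponents, coeffs)``.
    ``name_or_path`` may be the name of a shipped basis (e.g. ``"sto-3g"``)
    or a path to a ``.gbs`` file.
    """
    path = Path(name_or_path)
    if not path.exists():
        path = _data_path(f"{name_or_path.lower()}.gbs")
    if not path.exists():
        raise FileNotFoundError(
            f"basis set {name_or_path!r} not found (shipped: {available_bases()})"
        )
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("!")]
    shells: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    i = 0
    while i < len(lines):
        if lines[i] == "****":
            i += 1
            continue
        m = re.match(r"^([A-Z][a-z]?)\s+0$", lines[i])
        if not m:
            raise ValueError(f"cannot parse basis file line: {lines[i]!r}")
        elem = m.group(1)
        i += 1
        elem_shells: list[tuple[int, np.ndarray, np.ndarray]] = []
        while i < len(lines) and lines[i] != "****":
            head = lines[i].split()
            ltag, nprim = head[0].upper(), int(head[1])
            i += 1
            rows = []
            for _ in range(nprim):
                rows.append([float(x.replace("D", "E").replace("d", "e"))
                             for x in lines[i].split()])
                i += 1
            rows_arr = np.array(rows)
            if ltag == "SP":
                elem_shells.append((0, rows_arr[:, 0], rows_arr[:, 1]))
                elem_shells.append((1, rows_arr[:, 0], rows_arr[:, 2]))
            else:
                l = _ANGMOM_LETTERS.index(ltag.lower())
                elem_shells.append((l, rows_arr[:, 0], rows_arr[:, 1]))
        shells[elem] = elem_shells
        i += 1
    return shells


def build_molecular_basis(
    elements: list[str],
    coords_bohr: np.ndarray,
    basis_name: str,
    pure: bool = False,
) -> list[BasisShell]:
    """Instantiate shells of a named basis on every atom of a molecule."""
    templates = load_basis(basis_name)
    coords_bohr = np.asarray(coords_bohr, dtype=float)
    shells: list[BasisShell] = []
    for ia, elem in enumerate(elements):
        if elem not in templates:
            raise UnsupportedElementError(
                f"element {elem!r} is not available in basis {basis_name!r}"
            )
        for l, exps, coefs in templates[elem]:
            shells.append(BasisShell(
                atom_index=ia, angular_momentum=l,
                exponents=exps, contraction_coeffs=coefs,
                pure=pure and l >= 2, center=coords_bohr[ia],
            ))
    return shells


def n_ao(shells: list[BasisShell]) -> int:
    return sum(sh.n_funcs for sh in shells)


def ao_atom_map(shells: list[BasisShell]) -> np.ndarray:
    """AO index -> atom index for a shell list."""
    return np.array([sh.atom_index for sh in shells for _ in range(sh.n_funcs)],
                    dtype=int)
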