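"""Molecular integrals over contracted Cartesian Gaussians.

A compact McMurchie–Davidson implementation sized for the small fixture
molecules this package analyses (a few heavy atoms, s/p/d shells).  It
provides overlap, kinetic, nuclear-attraction and electron-repulsion
integrals, plus cross overlaps between two different basis sets — the
ingredient the intrinsic-atomic-orbital construction needs.

All geometry input here is in bohr; conversion from the Å world of the
trajectory containers happens at the call sites.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import BasisShell, c2s_matrix, cart_components, n_ao

__all__ = [
    "overlap",
    "kinetic",
    "nuclear_attraction",
    "electron_repulsion",
    "overlap_cross",
    "pure_transform",
]


def _df_from_l(lx: int) -> float:
    # (2*lx - 1)!!
    out = 1.0
    for k in range(1, 2 * lx, 2):
        out *= k
    return out


def _component_factor(comp: tuple[int, int, int]) -> float:
    lx, ly, lz = comp
    return 1.0 / np.sqrt(_df_from_l(lx) * _df_from_l(ly) * _df_from_l(lz))


def _common_prim_norm(alpha: np.ndarray, l: int) -> np.ndarray:
    return (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)


def _contracted_scale(shell: BasisShell) -> float:
    """Scale making each normalized-Cartesian component self-overlap 1."""
    a = shell.exponents
    c = shell.contraction_coeffs * _common_prim_norm(a, shell.angular_momentum)
    p = a[:, None] + a[None, :]
    l = shell.angular_momentum
    s = np.sum(c[:, None] * c[None, :] * (np.pi / p) ** 1.5 / (2.0 * p) ** l)
    # the (2l-1)!!-type component product cancels against the component
    # normalization factors, so one scalar serves every component
    s *= _df_from_l(l)
    return 1.0 / np.sqrt(s)


def _eff_coeffs(shell: BasisShell) -> np.ndarray:
    return (_contracted_scale(shell)
            * shell.contraction_coeffs
            * _common_prim_norm(shell.exponents, shell.angular_momentum))


# ----------------------------------------------------------------------------
# Hermite expansion coefficients
# ----------------------------------------------------------------------------

def _hermite_E(la: int, lb: int, a: np.ndarray, b: np.ndarray,
               AB: float) -> dict[tuple[int, int, int], np.ndarray]:
    """E_t^{ij} coefficients for one Cartesian direction.

    ``a``/``b`` are flattened primitive-pair exponent grids; returns arrays
    over that grid for all 0 <= i <= la, 0 <= j <= lb, 0 <= t <= i+j.
    """
    p = a + b
    mu = a * b / p
    XPA = -b * AB / p
    XPB = a * AB / p
    E: dict[tuple[int, int, int], np.ndarray] = {}
    E[(0, 0, 0)] = np.exp(-mu * AB * AB)
    zeros = np.zeros_like(p)

    def get(i, j, t):
        if t < 0 or t > i + j or i < 0 or j < 0:
            return zeros
        return E[(i, j, t)]

    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            for t in range(i + j + 1):
                if j == 0:
                    E[(i, j, t)] = (get(i - 1, j, t - 1) / (2 * p)
                                    + XPA * get(i - 1, j, t)
                                    + (t + 1) * get(i - 1, j, t + 1))
                else:
                    E[(i, j, t)] = (get(i, j - 1, t - 1) / (2 * p)
                                    + XPB * get(i, j - 1, t)
                                    + (t + 1) * get(i, j - 1, t + 1))
    return E


class _ShellPair:
    """Cached per-direction Hermite coefficients for one shell pair."""

    def __init__(self, sh1: BasisShell, sh2: BasisShell,
                 extra_l2: int = 0) -> None:
        self.sh1, self.sh2 = sh1, sh2
        a = sh1.exponents[:, None]
        b = sh2.exponents[None, :]
        self.a = np.broadcast_to(a, (a.size, b.size)).ravel()
        self.b = np.broadcast_to(b, (a.size, b.size)).ravel()
        self.p = self.a + self.b
        A, B = sh1.center, sh2.center
        self.P = (self.a[:, None] * A[None, :]
                  + self.b[:, None] * B[None, :]) / self.p[:, None]
        self.cc = np.outer(_eff_coeffs(sh1), _eff_coeffs(sh2)).ravel()
        l1, l2 = sh1.angular_momentum, sh2.angular_momentum
        self.E = [_hermite_E(l1, l2 + extra_l2, self.a, self.b, A[d] - B[d])
                  for d in range(3)]


# ----------------------------------------------------------------------------
# Boys function and Hermite Coulomb integrals
# ----------------------------------------------------------------------------

def _boys(m_max: int, T: np.ndarray) -> np.ndarray:
    """F_m(T) for m = 0..m_max, vectorized; returns (m_max+1, n)."""
    T = np.asarray(T, dtype=float)
    out = np.empty((m_max + 1, T.size))
    Tf = T.ravel()
    small = Tf < 1e-12
    ms = np.arange(m_max + 1)[:, None]
    # series limit for tiny arguments
    out[:, :] = 1.0 / (2 * ms + 1) - Tf[None, :] / (2 * ms + 3)
    big = ~small
    if np.any(big):
        Tb = Tf[big]
        mm = ms + 0.5
        # regularized lower incomplete gamma: F_m(T) = g(m+1/2) P(m+1/2, T) / (2 T^{m+1/2})
        gam = np.exp(gammaln(mm))
        out[:, big] = gam * gammainc(mm, Tb[None, :]) / (2.0 * Tb[None, :] ** mm)
    return out


def _hermite_R(L: int, alpha: np.ndarray, PQ: np.ndarray
               ) -> dict[tuple[int, int, int], np.ndarray]:
    """Hermite Coulomb integrals R^0_{tuv} for t+u+v <= L over a prim grid."""
    T = alpha * np.einsum("ni,ni->n", PQ, PQ)
    F = _boys(L, T)
    base = ((-2.0 * alpha)[None, :] ** np.arange(L + 1)[:, None]) * F
    cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def R(m, t, u, v):
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (m, t, u, v)
        if key in cache:
            return cache[key]
        if t == u == v == 0:
            val = base[m]
        elif t > 0:
            val = (t - 1) * R(m + 1, t - 2, u, v) + PQ[:, 0] * R(m + 1, t - 1, u, v)
        elif u > 0:
            val = (u - 1) * R(m + 1, t, u - 2, v) + PQ[:, 1] * R(m + 1, t, u - 1, v)
        else:
            val = (v - 1) * R(m + 1, t, u, v - 2) + PQ[:, 2] * R(m + 1, t, u, v - 1)
        cache[key] = val
        return val

    out = {}
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for v in range(L + 1 - t - u):
                out[(t, u, v)] = np.asarray(R(0, t, u, v))
    return out


# ----------------------------------------------------------------------------
# One-electron matrices
# ----------------------------------------------------------------------------

def _pair_overlap_block(sp: _ShellPair) -> np.ndarray:
    sh1, sh2 = sp.sh1, sp.sh2
    comps1 = cart_components(sh1.angular_momentum)
    comps2 = cart_components(sh2.angular_momentum)
    pref = sp.cc * (np.pi / sp.p) ** 1.5
    block = np.empty((len(comps1), len(comps2)))
    for i, c1 in enumerate(comps1):
        for j, c2 in enumerate(comps2):
            val = pref.copy()
            for d in range(3):
                val = val * sp.E[d][(c1[d], c2[d], 0)]
            block[i, j] = val.sum() * _component_factor(c1) * _component_factor(c2)
    return block


def _pair_kinetic_block(sp: _ShellPair) -> np.ndarray:
    sh1, sh2 = sp.sh1, sp.sh2
    comps1 = cart_components(sh1.angular_momentum)
    comps2 = cart_components(sh2.angular_momentum)
    pref = sp.cc * (np.pi / sp.p) ** 1.5
    b = sp.b
    block = np.empty((len(comps1), len(comps2)))
    for i, c1 in enumerate(comps1):
        for j, c2 in enumerate(comps2):
            total = np.zeros_like(sp.p)
            for d in range(3):
                jd = c2[d]
                # 1-D kinetic factor: -2b^2 S(j+2) + b(2j+1) S(j) - j(j-1)/2 S(j-2)
                td = -2.0 * b * b * sp.E[d][(c1[d], jd + 2, 0)]
                td = td + b * (2 * jd + 1) * sp.E[d][(c1[d], jd, 0)]
                if jd >= 2:
                    td = td - 0.5 * jd * (jd - 1) * sp.E[d][(c1[d], jd - 2, 0)]
                val = td
                for d2 in range(3):
                    if d2 != d:
                        val = val * sp.E[d2][(c1[d2], c2[d2], 0)]
                total = total + val
            block[i, j] = (pref * total).sum() * _component_factor(c1) * _component_factor(c2)
    return block


def _assemble_one_electron(shells: list[BasisShell], pair_fn, extra_l2=0) -> np.ndarray:
    nb = n_ao_cart(shells)
    offs = _cart_offsets(shells)
    M = np.zeros((nb, nb))
    for i1, sh1 in enumerate(shells):
        for i2 in range(i1 + 1):
            sp = _ShellPair(sh1, shells[i2], extra_l2=extra_l2)
            blk = pair_fn(sp)
            o1, o2 = offs[i1], offs[i2]
            M[o1:o1 + blk.shape[0], o2:o2 + blk.shape[1]] = blk
            if i2 != i1:
                M[o2:o2 + blk.shape[1], o1:o1 + blk.shape[0]] = blk.T
    return M


def n_ao_cart(shells: list[BasisShell]) -> int:
    return sum(len(cart_components(sh.angular_momentum)) for sh in shells)


def _cart_offsets(shells: list[BasisShell]) -> list[int]:
    offs, o = [], 0
    for sh in shells:
        offs.append(o)
        o += len(cart_components(sh.angular_momentum))
    return offs


def pure_transform(shells: list[BasisShell]) -> np.ndarray | None:
    """Block-diagonal spherical-from-Cartesian matrix, or None if all-Cartesian."""
    if not any(sh.pure for sh in shells):
        return None
    nb_cart = n_ao_cart(shells)
    T = np.zeros((n_ao(shells), nb_cart))
    r, c = 0, 0
    for sh in shells:
        ncart = len(cart_components(sh.angular_momentum))
        if sh.pure:
            blk = c2s_matrix(sh.angular_momentum)
        else:
            blk = np.eye(ncart)
        T[r:r + blk.shape[0], c:c + ncart] = blk
        r += blk.shape[0]
        c += ncart
    return T


def _maybe_transform(M: np.ndarray, shells1, shells2) -> np.ndarray:
    T1 = pure_transform(shells1)
    T2 = pure_transform(shells2)
    if T1 is not None:
        M = T1 @ M
    if T2 is not None:
        M = M @ T2.T
    return M


def overlap(shells: list[BasisShell]) -> np.ndarray:
    S = _assemble_one_electron(shells, _pair_overlap_block)
    return _maybe_transform(S, shells, shells)


def kinetic(shells: list[BasisShell]) -> np.ndarray:
    T = _assemble_one_electron(shells, _pair_kinetic_block, extra_l2=2)
    return _maybe_transform(T, shells, shells)


def overlap_cross(shells1: list[BasisShell], shells2: list[BasisShell]) -> np.ndarray:
    """Overlap between two different basis sets on the same molecule."""
    nb1, nb2 = n_ao_cart(shells1), n_ao_cart(shells2)
    offs1, offs2 = _cart_offsets(shells1), _cart_offsets(shells2)
    M = np.zeros((nb1, nb2))
    for i1, sh1 in enumerate(shells1):
        for i2, sh2 in enumerate(shells2):
            blk = _pair_overlap_block(_ShellPair(sh1, sh2))
            M[offs1[i1]:offs1[i1] + blk.shape[0],
              offs2[i2]:offs2[i2] + blk.shape[1]] = blk
    return _maybe_transform(M, shells1, shells2)


def nuclear_attraction(shells: list[BasisShell], charges: np.ndarray,
                       centers_bohr: np.ndarray) -> np.ndarray:
    """Electron-nucleus attraction matrix (negative definite contribution)."""
    nb = n_ao_cart(shells)
    offs = _cart_offsets(shells)
    V = np.zeros((nb, nb))
    centers_bohr = np.asarray(centers_bohr, dtype=float)
    for i1, sh1 in enumerate(shells):
        for i2 in range(i1 + 1):
            sh2 = shells[i2]
            sp = _ShellPair(sh1, sh2)
            l1, l2 = sh1.angular_momentum, sh2.angular_momentum
            L = l1 + l2
            comps1, comps2 = cart_components(l1), cart_components(l2)
            blk = np.zeros((len(comps1), len(comps2)))
            for Z, Cc in zip(charges, centers_bohr):
                if Z == 0:
                    continue
                PQ = sp.P - Cc[None, :]
                Rt = _hermite_R(L, sp.p, PQ)
                pref = sp.cc * 2.0 * np.pi / sp.p
                for i, c1 in enumerate(comps1):
                    for j, c2 in enumerate(comps2):
                        acc = np.zeros_like(sp.p)
                        for t in range(c1[0] + c2[0] + 1):
                            Ex = sp.E[0][(c1[0], c2[0], t)]
                            for u in range(c1[1] + c2[1] + 1):
                                Exy = Ex * sp.E[1][(c1[1], c2[1], u)]
                                for v in range(c1[2] + c2[2] + 1):
                                    acc = acc + Exy * sp.E[2][(c1[2], c2[2], v)] * Rt[(t, u, v)]
                        blk[i, j] += -Z * (pref * acc).sum() \
                            * _component_factor(c1) * _component_factor(c2)
            o1, o2 = offs[i1], offs[i2]
            V[o1:o1 + blk.shape[0], o2:o2 + blk.shape[1]] = blk
            if i2 != i1:
                V[o2:o2 + blk.shape[1], o1:o1 + blk.shape[0]] = blk.T
    return _maybe_transform(V, shells, shells)


# ----------------------------------------------------------------------------
# Two-electron integrals
# ----------------------------------------------------------------------------

def _pair_hermite_density(sp: _ShellPair):
    """E-product tensor per component pair: (ncomp1*ncomp2, npp, t, u, v)."""
    l1, l2 = sp.sh1.angular_momentum, sp.sh2.angular_momentum
    comps1, comps2 = cart_components(l1), cart_components(l2)
    nt = l1 + l2 + 1
    npp = sp.p.size
    out = np.zeros((len(comps1) * len(comps2), npp, nt, nt, nt))
    k = 0
    for c1 in comps1:
        f1 = _component_factor(c1)
        for c2 in comps2:
            f = f1 * _component_factor(c2) * sp.cc
            for t in range(c1[0] + c2[0] + 1):
                Ex = sp.E[0][(c1[0], c2[0], t)]
                for u in range(c1[1] + c2[1] + 1):
                    Exy = Ex * sp.E[1][(c1[1], c2[1], u)]
                    for v in range(c1[2] + c2[2] + 1):
                        out[k, :, t, u, v] = f * Exy * sp.E[2][(c1[2], c2[2], v)]
            k += 1
    return out, nt


def electron_repulsion(shells: list[BasisShell]) -> np.ndarray:
    """Full (ab|cd) tensor in chemists' notation. Sized for small molecules."""
    nb = n_ao_cart(shells)
    offs = _cart_offsets(shells)
    nsh = len(shells)
    eri = np.zeros((nb, nb, nb, nb))

    pairs = []
    pair_index = {}
    for i in range(nsh):
        for j in range(i + 1):
            sp = _ShellPair(shells[i], shells[j])
            dens, nt = _pair_hermite_density(sp)
            pairs.append((i, j, sp, dens, nt))
            pair_index[(i, j)] = len(pairs) - 1

    for ip in range(len(pairs)):
        i, j, sp1, D1, nt1 = pairs[ip]
        n1 = len(cart_components(shells[i].angular_momentum))
        n2 = len(cart_components(shells[j].angular_momentum))
        for jp in range(ip + 1):
            k, l, sp2, D2, nt2 = pairs[jp]
            n3 = len(cart_components(shells[k].angular_momentum))
            n4 = len(cart_components(shells[l].angular_momentum))
            npp1, npp2 = sp1.p.size, sp2.p.size
            p = sp1.p[:, None]
            q = sp2.p[None, :]
            alpha = (p * q) / (p + q)
            PQ = sp1.P[:, None, :] - sp2.P[None, :, :]
            L = (nt1 - 1) + (nt2 - 1)
            Rt = _hermite_R(L, alpha.ravel(), PQ.reshape(-1, 3))
            R6 = np.zeros((npp1, npp2, L + 1, L + 1, L + 1))
            for (t, u, v), arr in Rt.items():
                R6[:, :, t, u, v] = arr.reshape(npp1, npp2)
            pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
            R6 = R6 * pref[:, :, None, None, None]
            # contract ket side with (-1)^{tau+nu+phi}
            M = np.zeros((npp1, n3 * n4, nt1, nt1, nt1))
            for tau in range(nt2):
                for nu in range(nt2):
                    for phi in range(nt2):
                        w = D2[:, :, tau, nu, phi]
                        if not np.any(w):
                            continue
                        sign = (-1.0) ** (tau + nu + phi)
                        Rsub = R6[:, :, tau:tau + nt1, nu:nu + nt1, phi:phi + nt1]
                        M += sign * np.einsum("cq,pqtuv->pctuv", w, Rsub,
                                              optimize=True)
            block = np.einsum("bptuv,pctuv->bc", D1.reshape(n1 * n2, npp1, nt1, nt1, nt1),
                              M, optimize=True)
            block = block.reshape(n1, n2, n3, n4)
            _scatter_eri(eri, block, offs, i, j, k, l)
    return eri


def _scatter_eri(eri, block, offs, i, j, k, l):
    oi, oj, ok, ol = offs[i], offs[j], offs[k], offs[l]
    n1, n2, n3, n4 = block.shape
    sl = np.s_[oi:oi + n1, oj:oj + n2, ok:ok + n3, ol:ol + n4]
    eri[sl] = block
    eri[oj:oj + n2, oi:oi + n1, ok:ok + n3, ol:ol + n4] = block.transpose(1, 0, 2, 3)
    eri[oi:oi + n1, oj:oj + n2, ol:ol + n4, ok:ok + n3] = block.transpose(0, 1, 3, 2)
    eri[oj:oj + n2, oi:oi + n1, ol:ol + n4, ok:ok + n3] = block.transpose(1, 0, 3, 2)
    eri[ok:ok + n3, ol:ol + n4, oi:oi + n1, oj:oj + n2] = block.transpose(2, 3, 0, 1)
    eri[ol:ol + n4, ok:ok + n3, oi:oi + n1, oj:oj + n2] = block.transpose(3, 2, 0, 1)
    eri[ok:ok + n3, ol:ol + n4, oj:oj + n2, oi:oi + n1] = block.transpose(2, 3, 1, 0)
    eri[ol:ol + n4, ok:ok + n3, oj:oj + n2, oi:oi + n1] = block.transpose(3, 2, 1, 0)
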