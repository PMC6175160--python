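"""Chemical labelling of localized orbitals and mechanism classification.

The mechanism question for an X–H activation step is: when the proton
moves from donor X to acceptor Y, which spin channel's electron travels
with it?  With spin-resolved localized-orbital tracks in hand the answer
is read off the fate of each channel's X–H bond orbital:

* one channel's X–H orbital follows the H into the new Y–H bond while the
  other stays behind on X, and the opposite-spin acceptor lone pair
  completes the new bond  -> hydrogen atom transfer (HAT);
* one channel's X–H orbital leaves the substrate but lands on the acceptor
  heavy atoms (e.g. a metal centre) rather than on H, while acceptor lone
  pairs of *both* spins form the new Y–H bond  -> concerted proton-coupled
  electron transfer (cPCET);
* neither X–H orbital leaves the donor side, the proton binds to acceptor
  lone pairs of both spins and the donor keeps its pair  -> proton
  transfer (PT);
* both channels migrate together into the same new bond  -> closed-shell
  (hydride-like) transfer.

Anything else is reported as ambiguous together with the full per-spin
evidence trail.  All numeric thresholds that operationalize "travels
together" are explicit, configurable, and echoed in every report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .basis import ELEMENTS
from .tracker import OrbitalTrajectory

__all__ = [
    "Thresholds",
    "BondLabel",
    "MechanismReport",
    "label_orbital",
    "assign_core_labels",
    "classify",
    "SetupError",
]


class SetupError(ValueError):
    """The supplied atom indices do not match the orbital tracks."""


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds, all in electrons.

    bond:  minimum atomic charge for an atom to count as a bond partner.
    tail:  single-atom orbitals need q >= 1 - tail to be lone pairs/cores.
    h:     minimum final charge on the transferred H for the electron to
           count as travelling with the proton.
    leave: below this final donor-side charge an orbital has migrated.
    """

    bond: float = 0.20
    tail: float = 0.15
    h: float = 0.25
    leave: float = 0.30

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold {name}={v} outside (0, 1)")


@dataclass(frozen=True)
class BondLabel:
    """Chemical character of one orbital: bond, lone pair, core, or neither."""

    kind: str                      # two_center_bond | lone_pair | core | delocalized
    atoms: tuple[int, ...]
    weights: tuple[float, ...]

    def involves(self, atom: int) -> bool:
        return atom in self.atoms

    def __str__(self) -> str:
        inner = ", ".join(f"{a}:{w:.2f}" for a, w in zip(self.atoms, self.weights))
        return f"{self.kind}({inner})"


def label_orbital(q: np.ndarray, theta_bond: float = 0.20,
                  theta_tail: float = 0.15, core_hint: bool = False) -> BondLabel:
    """Label one charge vector as bond / lone pair / core / delocalized.

    ``core_hint`` marks an orbital independently identified as 1s-like
    (see :func:`assign_core_labels`); it upgrades a lone-pair label to core.
    """
    q = np.asarray(q, dtype=float)
    big = np.where(q >= theta_bond)[0]
    big = big[np.argsort(-q[big])]
    if len(big) == 2:
        return BondLabel("two_center_bond", tuple(int(a) for a in big),
                         tuple(float(q[a]) for a in big))
    if len(big) == 1 and q[big[0]] >= 1.0 - theta_tail:
        kind = "core" if core_hint else "lone_pair"
        return BondLabel(kind, (int(big[0]),), (float(q[big[0]]),))
    if len(big) >= 3:
        warnings.warn(
            f"orbital spreads over {len(big)} atoms above the bond "
            "threshold; labelling as delocalized",
            RuntimeWarning, stacklevel=2,
        )
    return BondLabel("delocalized", tuple(int(a) for a in big),
                     tuple(float(q[a]) for a in big))


_CORE_ORBITALS = {  # orbitals per atom that are chemically core shells
    (1, 2): 0,      # H, He
    (3, 10): 1,     # Li..Ne: 1s
    (11, 18): 5,    # Na..Ar: 1s2s2p
    (19, 36): 9,    # K..Kr main/3d block: 1s2s2p3s3p
}


#: minimum atomic purity for a single-atom orbital to qualify as a core
#: shell; genuine 1s-like cores sit essentially entirely on their atom
CORE_PURITY = 0.995


def _n_core(element: str) -> int:
    z = ELEMENTS[element]
    for (lo, hi), n in _CORE_ORBITALS.items():
        if lo <= z <= hi:
            return n
    return 9


def assign_core_labels(charge_matrix: np.ndarray, elements: list[str],
                       thresholds: Thresholds = Thresholds()) -> list[BondLabel]:
    """Label a whole frame's orbitals, separating cores from lone pairs.

    Core orbitals carry essentially the whole electron on one atom; among
    the single-atom orbitals of each heavy atom the most atom-pure ones are
    assigned as cores, as many as the element's core shells, and the rest
    remain lone pairs.
    """
    n_orb = charge_matrix.shape[0]
    prelim = [label_orbital(charge_matrix[i], thresholds.bond, thresholds.tail)
              for i in range(n_orb)]
    core_flags = [False] * n_orb
    for atom, elem in enumerate(elements):
        want = _n_core(elem)
        if want == 0:
            continue
        cands = [i for i, lab in enumerate(prelim)
                 if lab.kind == "lone_pair" and lab.atoms[0] == atom
                 and charge_matrix[i, atom] >= CORE_PURITY]
        cands.sort(key=lambda i: -charge_matrix[i, atom])
        for i in cands[:want]:
            core_flags[i] = True
    return [label_orbital(charge_matrix[i], thresholds.bond, thresholds.tail,
                          core_hint=core_flags[i]) for i in range(n_orb)]


# ----------------------------------------------------------------------------
# Mechanism classification
# ----------------------------------------------------------------------------

@dataclass
class SpinNarrative:
    """Fate of one spin channel's X–H bond orbital."""

    track_id: int
    initial_label: BondLabel
    final_label: BondLabel
    final_q_h: float
    final_q_donor_side: float
    final_q_acceptor_heavy: float
    migrated: bool


@dataclass
class MechanismReport:
    """Classification verdict plus the per-spin evidence trail."""

    verdict: str
    transferred_h: int
    donor_atom: int
    acceptor_atom: int
    thresholds: Thresholds
    narrative: dict[str, SpinNarrative]
    lone_pair_evidence: dict[str, list[int]]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def lab(x):
            return {"kind": x.kind, "atoms": list(x.atoms),
                    "weights": list(np.round(x.weights, 6))}

        return {
            "verdict": self.verdict,
            "transferred_h": self.transferred_h,
            "donor_atom": self.donor_atom,
            "acceptor_atom": self.acceptor_atom,
            "thresholds": asdict(self.thresholds),
            "narrative": {
                spin: {
                    "track_id": n.track_id,
                    "initial_label": lab(n.initial_label),
                    "final_label": lab(n.final_label),
                    "final_q_h": round(n.final_q_h, 6),
                    "final_q_donor_side": round(n.final_q_donor_side, 6),
                    "final_q_acceptor_heavy": round(n.final_q_acceptor_heavy, 6),
                    "migrated": n.migrated,
                } for spin, n in self.narrative.items()
            },
            "lone_pair_evidence": self.lone_pair_evidence,
            "notes": self.notes,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            f"verdict: {self.verdict}",
            f"transferred H: atom {self.transferred_h} "
            f"(donor {self.donor_atom} -> acceptor {self.acceptor_atom})",
            f"thresholds: {d['thresholds']}",
        ]
        for spin, n in self.narrative.items():
            lines.append(
                f"  {spin}: X-H track {n.track_id}: {n.initial_label} -> "
                f"{n.final_label}; q(H)={n.final_q_h:.3f}, "
                f"q(donor side)={n.final_q_donor_side:.3f}, "
                f"q(acceptor heavy)={n.final_q_acceptor_heavy:.3f}, "
                f"{'migrated' if n.migrated else 'stayed'}"
            )
        for spin, ids in self.lone_pair_evidence.items():
            lines.append(f"  {spin}: acceptor lone pair(s) joining new bond: "
                         f"{ids if ids else 'none'}")
        for note in self.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


def _final_labels(tracks: list[OrbitalTrajectory], elements, thresholds,
                  frame: int) -> list[BondLabel]:
    mat = np.vstack([tr.charges[frame] for tr in tracks])
    if elements is not None:
        return assign_core_labels(mat, elements, thresholds)
    return [label_orbital(q, thresholds.bond, thresholds.tail) for q in mat]


def detect_transferred_h(tracks_by_spin: dict[str, list[OrbitalTrajectory]],
                         elements: list[str], donor_atom: int,
                         acceptor_atom: int,
                         thresholds: Thresholds = Thresholds()) -> int:
    """Auto-detect the transferred H: the hydrogen whose strongest bond
    partner changes from the donor side to the acceptor side."""
    candidates = []
    some_spin = next(iter(tracks_by_spin))
    tracks = tracks_by_spin[some_spin]
    for atom, elem in enumerate(elements):
        if elem != "H":
            continue
        first = max(tracks, key=lambda tr: tr.initial_q[atom])
        last = max(tracks, key=lambda tr: tr.final_q[atom])
        mask0 = np.where(np.arange(len(first.initial_q)) == atom, -1.0,
                         first.initial_q)
        mask1 = np.where(np.arange(len(last.final_q)) == atom, -1.0,
                         last.final_q)
        part0, part1 = int(np.argmax(mask0)), int(np.argmax(mask1))
        if part0 == donor_atom and part1 == acceptor_atom:
            candidates.append(atom)
    if len(candidates) != 1:
        raise SetupError(
            f"could not auto-detect the transferred H (candidates: "
            f"{candidates}); pass the H atom index explicitly"
        )
    return candidates[0]


def classify(
    alpha_tracks: list[OrbitalTrajectory],
    beta_tracks: list[OrbitalTrajectory],
    donor_atom: int,
    acceptor_atom: int,
    h_atom: int | None = None,
    thresholds: Thresholds = Thresholds(),
    elements: list[str] | None = None,
    acceptor_heavy_atoms: set[int] | None = None,
    donor_side_atoms: set[int] | None = None,
) -> MechanismReport:
    """Classify the X–H activation mechanism from spin-resolved tracks.

    ``acceptor_heavy_atoms`` is where a transferred-without-the-proton
    electron may land (defaults to the acceptor atom; add the metal centre
    for acceptor complexes).  ``donor_side_atoms`` is the substrate region
    an orbital must leave to count as migrated (defaults to the donor
    atom; add the rest of the substrate when its radical may delocalize).
    """
    notes: list[str] = []
    tracks_by_spin = {"alpha": alpha_tracks, "beta": beta_tracks}
    if h_atom is None:
        if elements is None:
            raise SetupError("auto-detecting the transferred H requires "
                             "element symbols; pass h_atom or elements")
        h_atom = detect_transferred_h(tracks_by_spin, elements, donor_atom,
                                      acceptor_atom, thresholds)
        notes.append(f"transferred H auto-detected as atom {h_atom}")
    if acceptor_heavy_atoms is None:
        acceptor_heavy_atoms = {acceptor_atom}
    acceptor_heavy_atoms = set(acceptor_heavy_atoms) | {acceptor_atom}
    if donor_side_atoms is None:
        donor_side_atoms = {donor_atom}
    donor_side_atoms = set(donor_side_atoms) | {donor_atom}

    narrative: dict[str, SpinNarrative] = {}
    lp_evidence: dict[str, list[int]] = {}
    new_bond_from_lp: dict[str, bool] = {}
    xh_tracks: dict[str, OrbitalTrajectory] = {}
    for spin, tracks in tracks_by_spin.items():
        init_labels = _final_labels(tracks, elements, thresholds, 0)
        fin_labels = _final_labels(tracks, elements, thresholds, -1)
        for tr, lab in zip(tracks, init_labels):
            tr.label_initial = lab
        xh = [k for k, lab in enumerate(init_labels)
              if lab.kind == "two_center_bond"
              and set(lab.atoms) == {donor_atom, h_atom}]
        if len(xh) != 1:
            raise SetupError(
                f"{spin}: expected exactly one initial {donor_atom}-{h_atom} "
                f"bond track, found {len(xh)}; check the donor/H atom indices"
            )
        k = xh[0]
        tr = tracks[k]
        xh_tracks[spin] = tr
        fq = tr.final_q
        q_donor_side = float(sum(fq[a] for a in donor_side_atoms))
        q_acc_heavy = float(sum(fq[a] for a in acceptor_heavy_atoms))
        narrative[spin] = SpinNarrative(
            track_id=k,
            initial_label=init_labels[k],
            final_label=fin_labels[k],
            final_q_h=float(fq[h_atom]),
            final_q_donor_side=q_donor_side,
            final_q_acceptor_heavy=q_acc_heavy,
            migrated=q_donor_side < thresholds.leave,
        )
        # acceptor lone pairs that end up in the new Y-H bond; a genuine
        # core cannot become a bond, so any initially single-atom acceptor
        # orbital that does counts as lone-pair evidence
        lp_ids = [m for m, (il, fl) in enumerate(zip(init_labels, fin_labels))
                  if il.kind in ("lone_pair", "core")
                  and il.atoms[0] == acceptor_atom
                  and fl.kind == "two_center_bond"
                  and set(fl.atoms) == {acceptor_atom, h_atom}]
        lp_evidence[spin] = lp_ids
        new_bond_from_lp[spin] = len(lp_ids) > 0

    migrated = [s for s in ("alpha", "beta") if narrative[s].migrated]
    verdict = "ambiguous"
    if len(migrated) == 1:
        mig, other = migrated[0], ("beta" if migrated[0] == "alpha" else "alpha")
        n = narrative[mig]
        conflict = (abs(n.final_q_h - thresholds.h) <= 0.05
                    and abs(n.final_q_acceptor_heavy - thresholds.h) <= 0.05)
        if conflict:
            notes.append(
                "conflicting evidence: migrating orbital splits between the "
                "transferred H and the acceptor heavy atoms"
            )
        elif (n.final_label.kind == "two_center_bond"
                and set(n.final_label.atoms) == {acceptor_atom, h_atom}
                and n.final_q_h >= thresholds.h
                and new_bond_from_lp[other]):
            verdict = "HAT"
        elif (n.final_q_h < thresholds.h
                and n.final_q_acceptor_heavy >= 1.0 - thresholds.tail
                and new_bond_from_lp["alpha"] and new_bond_from_lp["beta"]):
            verdict = "cPCET"
    elif len(migrated) == 0:
        donor_keeps = all(
            narrative[s].final_q_h < thresholds.h
            and narrative[s].final_q_donor_side >= 1.0 - thresholds.tail
            for s in ("alpha", "beta")
        )
        if donor_keeps and new_bond_from_lp["alpha"] and new_bond_from_lp["beta"]:
            verdict = "PT"
        elif not any(new_bond_from_lp.values()) and all(
                narrative[s].final_label.kind == "two_center_bond"
                and set(narrative[s].final_label.atoms) == {donor_atom, h_atom}
                for s in ("alpha", "beta")):
            verdict = "ambiguous"
            notes.append("no reaction detected: X-H bonds unchanged and no "
                         "new bond formed at the acceptor")
    else:  # both spin channels migrated
        labs = [narrative[s].final_label for s in ("alpha", "beta")]
        if all(l.kind == "two_center_bond" and h_atom in l.atoms for l in labs) \
                and set(labs[0].atoms) == set(labs[1].atoms):
            verdict = "closed_shell_transfer"
    if verdict == "ambiguous" and not notes:
        notes.append("evidence pattern matches no decision-table row; "
                     "inspect the narrative")

    return MechanismReport(
        verdict=verdict, transferred_h=h_atom, donor_atom=donor_atom,
        acceptor_atom=acceptor_atom, thresholds=thresholds,
        narrative=narrative, lone_pair_evidence=lp_evidence, notes=notes,
    )
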