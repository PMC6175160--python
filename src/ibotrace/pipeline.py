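"""End-to-end analysis: trajectory in, mechanism report out.

Chains the library stages — intrinsic atomic orbitals, bond-orbital
localization, frame-to-frame tracking, change profiles, mechanism
classification — over both spin channels of a wavefunction trajectory.
The command-line ``analyze`` subcommand is a thin wrapper around
:func:`analyze_trajectory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics, tracker
from .classifier import MechanismReport, Thresholds, classify
from .frame_io import ReactionTrajectory
from .iao_engine import build_iaos
from .ibo_localizer import IBOSet, localize
from .metrics import ChangeProfile
from .tracker import OrbitalTrajectory

__all__ = ["AnalysisResult", "analyze_trajectory", "localize_trajectory"]


@dataclass
class AnalysisResult:
    """Everything the pipeline computed for one trajectory."""

    report: MechanismReport
    tracks: dict[str, list[OrbitalTrajectory]]
    profiles: dict[str, list[ChangeProfile]]
    ibosets: dict[str, list[IBOSet]]
    arc_coords: np.ndarray
    energies: np.ndarray
    active: list[tuple[str, int]] = field(default_factory=list)

    def all_profiles(self) -> list[ChangeProfile]:
        return [p for spin in self.profiles.values() for p in spin]


def localize_trajectory(
    trajectory: ReactionTrajectory,
    spin: str,
    p: int = 4,
    tol: float = 1e-8,
    max_sweeps: int = 60,
    seed: int | None = None,
) -> list[IBOSet]:
    """Localized orbital sets of one spin channel for every frame."""
    out = []
    for i, frame in enumerate(trajectory.frames):
        iaos = build_iaos(frame, spin)
        out.append(localize(frame, iaos, spin, p=p, tol=tol,
                            max_sweeps=max_sweeps, seed=seed, frame_index=i))
    return out


def analyze_trajectory(
    trajectory: ReactionTrajectory,
    donor_atom: int,
    acceptor_atom: int,
    h_atom: int | None = None,
    thresholds: Thresholds = Thresholds(),
    acceptor_heavy_atoms: set[int] | None = None,
    donor_side_atoms: set[int] | None = None,
    p: int = 4,
    tol: float = 1e-8,
    max_sweeps: int = 60,
    tracking_metric: str = "charge",
    change_convention: str = "l2_sum",
    active_threshold: float = metrics.DEFAULT_ACTIVE_THRESHOLD,
    seed: int | None = None,
) -> AnalysisResult:
    """Run the full spin-resolved analysis on a validated trajectory."""
    trajectory.validate()
    if trajectory.n_frames < 2:
        raise ValueError("analysis requires at least 2 frames")
    arcs = trajectory.arc_coords()
    ibosets: dict[str, list[IBOSet]] = {}
    tracks: dict[str, list[OrbitalTrajectory]] = {}
    profiles: dict[str, list[ChangeProfile]] = {}
    for spin in ("alpha", "beta"):
        sets = localize_trajectory(trajectory, spin, p=p, tol=tol,
                                   max_sweeps=max_sweeps, seed=seed)
        ibosets[spin] = sets
        kwargs = {}
        if tracking_metric == "overlap":
            kwargs = {"coeffs": [s.coeffs for s in sets],
                      "overlap": trajectory.frames[0].S1}
        tracks[spin] = tracker.track(sets, metric=tracking_metric,
                                     arc_coords=arcs, **kwargs)
        profiles[spin] = [metrics.orbital_change(tr, change_convention)
                          for tr in tracks[spin]]
    report = classify(
        tracks["alpha"], tracks["beta"],
        donor_atom=donor_atom, acceptor_atom=acceptor_atom, h_atom=h_atom,
        thresholds=thresholds,
        elements=trajectory.frames[0].geometry.elements,
        acceptor_heavy_atoms=acceptor_heavy_atoms,
        donor_side_atoms=donor_side_atoms,
    )
    active = metrics.active_orbitals(
        [p for spin in profiles.values() for p in spin], active_threshold)
    energies = np.array([np.nan if f.energy is None else f.energy
                         for f in trajectory.frames])
    return AnalysisResult(report=report, tracks=tracks, profiles=profiles,
                          ibosets=ibosets, arc_coords=arcs, energies=energies,
                          active=active)
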