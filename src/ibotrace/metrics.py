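"""Per-orbital change profiles along the reaction coordinate.

The change of a tracked orbital at path point t is the root of the summed
squared differences between its current and initial atomic partial-charge
distribution,

    delta(t) = sqrt( sum_A ( q_A(t) - q_A(0) )^2 )        [e-],

flat (~0) for spectator orbitals and approaching sqrt(2) for a complete
one-electron relocation from one atom to another.  This ``l2_sum``
convention is the default; ``rms_per_atom`` divides by sqrt(N_atoms) and is
kept as an alternative reading of "root-mean-square deviation among the
atoms".  Orbitals whose maximum change exceeds a threshold are the ones
participating in bond making and breaking; everything else needs no
inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracker import OrbitalTrajectory

__all__ = ["ChangeProfile", "orbital_change", "active_orbitals",
           "profiles_to_table"]

DEFAULT_ACTIVE_THRESHOLD = 0.2  # e-; above jitter, well below one electron

CONVENTIONS = ("l2_sum", "rms_per_atom")


@dataclass
class ChangeProfile:
    """Change-versus-path-coordinate curve of one tracked orbital."""

    track_id: int
    spin: str
    delta: np.ndarray
    arc_coords: np.ndarray | None
    convention: str

    @property
    def max_delta(self) -> float:
        return float(self.delta.max())

    @property
    def final_delta(self) -> float:
        return float(self.delta[-1])


def orbital_change(trajectory: OrbitalTrajectory,
                   convention: str = "l2_sum") -> ChangeProfile:
    """Change profile of one track relative to its first frame."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; "
                         f"choose from {CONVENTIONS}")
    q = trajectory.charges
    if q.ndim != 2:
        raise ValueError("trajectory charges must be (n_frames, n_atoms)")
    diff = q - q[0][None, :]
    delta = np.sqrt(np.sum(diff ** 2, axis=1))
    delta[0] = 0.0  # exact by self-reference
    if convention == "rms_per_atom":
        delta = delta / np.sqrt(q.shape[1])
    return ChangeProfile(
        track_id=trajectory.track_id, spin=trajectory.spin, delta=delta,
        arc_coords=trajectory.arc_coords, convention=convention,
    )


def active_orbitals(profiles: list[ChangeProfile],
                    threshold: float = DEFAULT_ACTIVE_THRESHOLD
                    ) -> list[tuple[str, int]]:
    """(spin, track_id) of tracks with max delta >= threshold, largest first."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hits = [p for p in profiles if p.max_delta >= threshold]
    hits.sort(key=lambda p: -p.max_delta)
    return [(p.spin, p.track_id) for p in hits]


def profiles_to_table(profiles: list[ChangeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, d in enumerate(p.delta):
            arc = np.nan if p.arc_coords is None else p.arc_coords[t]
            rows.append({"track_id": p.track_id, "spin": p.spin, "frame": t,
                         "arc_coord": arc, "delta": d,
                         "convention": p.convention})
    return pd.DataFrame(rows)
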