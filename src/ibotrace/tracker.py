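"""Threading orbital identities through consecutive reaction-path frames.

Localized orbitals come out of each frame in arbitrary order; to follow one
chemical orbital along the path its identity must be matched frame to
frame.  Matching is a linear assignment problem per consecutive frame pair:
the default cost between orbital i at frame t and orbital j at frame t+1 is
the Euclidean distance of their atomic charge vectors (phase-free and
basis-free); an orbital-overlap cost ``1 - |<phi_i|phi_j>|`` is available
when consecutive frames share a basis and the geometry change is small.
Assignments are chained greedily frame to frame, which is how such
orbital-change plots are produced in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["OrbitalTrajectory", "track", "tracks_to_table"]

AMBIGUITY_TOL = 1e-9
COARSE_STEP_LIMIT = 0.5  # e-; larger per-step jumps suggest too few frames


@dataclass
class OrbitalTrajectory:
    """One orbital identity threaded through all frames."""

    spin: str
    track_id: int
    orbital_ids: list[int]          # orbital index within each frame
    charges: np.ndarray             # (n_frames, n_atoms)
    arc_coords: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)
    label_initial: object | None = None   # set by the classifier module

    @property
    def n_frames(self) -> int:
        return self.charges.shape[0]

    @property
    def initial_q(self) -> np.ndarray:
        return self.charges[0]

    @property
    def final_q(self) -> np.ndarray:
        return self.charges[-1]

    def step_norms(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.charges, axis=0), axis=1)


def _charge_matrices(frames) -> list[np.ndarray]:
    mats = []
    for fr in frames:
        if hasattr(fr, "charge_matrix"):
            mats.append(np.asarray(fr.charge_matrix(), dtype=float))
        else:
            mats.append(np.asarray(fr, dtype=float))
    return mats


def track(
    frames,
    metric: str = "charge",
    spin: str = "alpha",
    arc_coords=None,
    coeffs=None,
    overlap=None,
) -> list[OrbitalTrajectory]:
    """Thread orbitals of consecutive frames into continuous trajectories.

    Parameters
    ----------
    frames:
        Per-frame localized orbital sets: either :class:`IBOSet` objects or
        plain (n_orbitals, n_atoms) charge matrices.
    metric:
        ``"charge"`` (default) matches on charge-vector distance;
        ``"overlap"`` requires ``coeffs`` (per-frame coefficient matrices)
        and ``overlap`` (a representative AO overlap matrix) and matches on
        1 - |<phi_i|phi_j>|.
    """
    mats = _charge_matrices(frames)
    if len(mats) < 2:
        raise ValueError("tracking requires at least 2 frames")
    n_orb = mats[0].shape[0]
    for t, m in enumerate(mats):
        if m.shape[0] != n_orb:
            raise ValueError(
                f"frame {t} has {m.shape[0]} orbitals, frame 0 has {n_orb}"
            )
    if metric not in ("charge", "overlap"):
        raise ValueError(f"unknown tracking metric {metric!r}")
    if metric == "overlap" and (coeffs is None or overlap is None):
        raise ValueError("overlap metric needs coeffs and overlap")

    if hasattr(frames[0], "spin"):
        spin = frames[0].spin

    # chained frame-to-frame assignments
    perms: list[np.ndarray] = []
    ambiguous_steps: list[int] = []
    for t in range(len(mats) - 1):
        if metric == "charge":
            diff = mats[t][:, None, :] - mats[t + 1][None, :, :]
            cost = np.linalg.norm(diff, axis=2)
        else:
            ov = np.abs(coeffs[t].T @ overlap @ coeffs[t + 1])
            cost = 1.0 - ov
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(n_orb, dtype=int)
        perm[rows] = cols
        total = cost[rows, cols].sum()
        # near-degenerate alternative: any 2-swap of targets within tolerance
        if n_orb >= 2:
            assigned = cost[np.arange(n_orb), perm]
            swap_delta = np.inf
            for a in range(n_orb):
                for b in range(a + 1, n_orb):
                    delta = (cost[a, perm[b]] + cost[b, perm[a]]
                             - assigned[a] - assigned[b])
                    swap_delta = min(swap_delta, delta)
            if swap_delta < AMBIGUITY_TOL:
                ambiguous_steps.append(t)
        perms.append(perm)

    # thread: track k starts at orbital k of frame 0
    tracks: list[OrbitalTrajectory] = []
    arc = None if arc_coords is None else np.asarray(arc_coords, dtype=float)
    max_jump = 0.0
    for k in range(n_orb):
        ids = [k]
        for perm in perms:
            ids.append(int(perm[ids[-1]]))
        charges = np.vstack([mats[t][ids[t]] for t in range(len(mats))])
        notes = []
        for t in ambiguous_steps:
            notes.append(f"near-degenerate assignment at step {t}")
        tr = OrbitalTrajectory(spin=spin, track_id=k, orbital_ids=ids,
                               charges=charges, arc_coords=arc, notes=notes)
        max_jump = max(max_jump, float(tr.step_norms().max(initial=0.0)))
        tracks.append(tr)

    if ambiguous_steps:
        warnings.warn(
            f"orbital assignment nearly degenerate at step(s) "
            f"{sorted(set(ambiguous_steps))}; tracks may be swapped",
            RuntimeWarning, stacklevel=2,
        )
    if max_jump > COARSE_STEP_LIMIT:
        warnings.warn(
            f"largest per-step charge jump {max_jump:.2f} e- exceeds "
            f"{COARSE_STEP_LIMIT} e-; the path sampling is probably too "
            "coarse — provide denser frames",
            RuntimeWarning, stacklevel=2,
        )
    return tracks


def tracks_to_table(tracks: list[OrbitalTrajectory]) -> pd.DataFrame:
    """Long-format track table (track_id, spin, frame, arc_coord, atom, q)."""
    rows = []
    for tr in tracks:
        for t in range(tr.n_frames):
            arc = np.nan if tr.arc_coords is None else tr.arc_coords[t]
            for atom, qa in enumerate(tr.charges[t]):
                rows.append({
                    "track_id": tr.track_id, "spin": tr.spin, "frame": t,
                    "arc_coord": arc, "orbital_id": tr.orbital_ids[t],
                    "atom": atom, "q": qa,
                })
    return pd.DataFrame(rows)


def tracks_from_table(df: pd.DataFrame) -> dict[str, list[OrbitalTrajectory]]:
    """Rebuild per-spin track lists from a long-format track table."""
    n_atoms = int(df["atom"].max()) + 1
    out: dict[str, list[OrbitalTrajectory]] = {}
    for spin, dspin in df.groupby("spin"):
        tracks = []
        for tid, dtr in dspin.groupby("track_id"):
            frames = sorted(dtr["frame"].unique())
            charges = np.zeros((len(frames), n_atoms))
            orbital_ids = []
            arcs = []
            for row_t, f in enumerate(frames):
                dfr = dtr[dtr["frame"] == f]
                charges[row_t, dfr["atom"].to_numpy()] = dfr["q"].to_numpy()
                orbital_ids.append(int(dfr["orbital_id"].iloc[0]))
                arcs.append(float(dfr["arc_coord"].iloc[0]))
            arc_arr = np.array(arcs)
            tracks.append(OrbitalTrajectory(
                spin=str(spin), track_id=int(tid), orbital_ids=orbital_ids,
                charges=charges,
                arc_coords=None if np.isnan(arc_arr).all() else arc_arr,
            ))
        out[str(spin)] = tracks
    return out
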