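"""Two-panel orbital-change figure: path energy above, orbital change below."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

HARTREE_TO_KCAL = 627.5094740631

__all__ = ["plot_change_profiles"]


def plot_change_profiles(arc_coords, energies, profiles, path,
                         title: str = "", only_tracks=None) -> None:
    """Save the energy / orbital-change two-panel figure.

    ``profiles`` is a flat list of :class:`~ibotrace.metrics.ChangeProfile`;
    ``only_tracks`` optionally restricts the lower panel to (spin, track_id)
    pairs (e.g. just the reactive X–H orbitals).
    """
    fig, (ax_e, ax_d) = plt.subplots(
        2, 1, sharex=True, figsize=(6, 6),
        gridspec_kw={"height_ratios": [1, 1.4]})
    energies = np.asarray(energies, dtype=float)
    if np.isfinite(energies).any():
        rel = (energies - np.nanmin(energies)) * HARTREE_TO_KCAL
        ax_e.plot(arc_coords, rel, "o-", color="black", ms=4)
        ax_e.set_ylabel("energy [kcal/mol]")
    else:
        ax_e.text(0.5, 0.5, "no energies available", ha="center",
                  transform=ax_e.transAxes)
    style = {"alpha": {"color": "tab:green", "marker": "s"},
             "beta": {"color": "tab:purple", "marker": "^"}}
    for p in profiles:
        if only_tracks is not None and (p.spin, p.track_id) not in only_tracks:
            continue
        st = style.get(p.spin, {"color": "gray", "marker": "o"})
        x = p.arc_coords if p.arc_coords is not None else np.arange(len(p.delta))
        ax_d.plot(x, p.delta, ms=4, lw=1.2,
                  label=f"{p.spin} #{p.track_id}", **st)
    ax_d.set_xlabel("reaction coordinate")
    ax_d.set_ylabel("orbital change [e$^-$]")
    ax_d.axhline(np.sqrt(2.0), color="lightgray", lw=0.8, zorder=0)
    if only_tracks is None or len(only_tracks) <= 8:
        ax_d.legend(fontsize=8, frameon=False)
    if title:
        ax_e.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
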