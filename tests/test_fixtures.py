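"""Synthetic-scenario generator and toy SCF reaction paths."""

import numpy as np
import pytest

from ibotrace.classifier import classify
from ibotrace.fixtures import (
    SyntheticScenario,
    make_synthetic,
    run_toy_reaction,
)
from ibotrace.pipeline import analyze_trajectory
from ibotrace.tracker import track


# ----------------------------------------------------------------------------
# synthetic generator
# ----------------------------------------------------------------------------

def test_scenario_validation():
    with pytest.raises(ValueError, match="kind"):
        SyntheticScenario(kind="teleportation")
    with pytest.raises(ValueError, match="n_frames"):
        SyntheticScenario(kind="HAT", n_frames=3)
    with pytest.raises(ValueError, match="noise_sd"):
        SyntheticScenario(kind="HAT", noise_sd=0.2)


def test_charges_normalized_and_nonnegative():
    ds = make_synthetic(SyntheticScenario(kind="cPCET", noise_sd=0.04,
                                          seed=11))
    for frames in ds.charges.values():
        for mat in frames:
            assert (mat >= 0).all()
            np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)


def test_generator_deterministic_per_seed():
    a = make_synthetic(SyntheticScenario(kind="HAT", noise_sd=0.01, seed=3))
    b = make_synthetic(SyntheticScenario(kind="HAT", noise_sd=0.01, seed=3))
    c = make_synthetic(SyntheticScenario(kind="HAT", noise_sd=0.01, seed=4))
    for spin in ("alpha", "beta"):
        for m1, m2 in zip(a.charges[spin], b.charges[spin]):
            np.testing.assert_array_equal(m1, m2)
    assert not np.array_equal(a.charges["alpha"][5], c.charges["alpha"][5])


def test_zero_noise_patterns_are_exact_at_endpoints():
    ds = make_synthetic(SyntheticScenario(kind="HAT"))
    q0 = ds.charges["alpha"][0][0]
    assert q0[ds.donor_atom] == pytest.approx(0.55)
    assert q0[ds.h_atom] == pytest.approx(0.42)
    qN = ds.charges["alpha"][-1][0]
    assert qN[ds.acceptor_atom] == pytest.approx(0.55)


@pytest.mark.parametrize("kind", ["HAT", "cPCET", "PT",
                                  "closed_shell_transfer"])
def test_classifier_recovers_every_scenario_at_zero_noise(kind):
    ds = make_synthetic(SyntheticScenario(kind=kind))
    trk = {s: track(ds.charges[s], spin=s) for s in ("alpha", "beta")}
    report = classify(trk["alpha"], trk["beta"], donor_atom=ds.donor_atom,
                      acceptor_atom=ds.acceptor_atom, h_atom=ds.h_atom,
                      acceptor_heavy_atoms={ds.metal_atom})
    assert report.verdict == kind


def test_noisy_recovery_rate_high():
    ok = 0
    n = 30
    for seed in range(n):
        ds = make_synthetic(SyntheticScenario(kind="cPCET", noise_sd=0.01,
                                              seed=seed))
        trk = {s: track(ds.charges[s], spin=s) for s in ("alpha", "beta")}
        report = classify(trk["alpha"], trk["beta"], donor_atom=0,
                          acceptor_atom=2, h_atom=1,
                          acceptor_heavy_atoms={3})
        ok += report.verdict == "cPCET"
    assert ok >= 0.95 * n


# ----------------------------------------------------------------------------
# toy reactions
# ----------------------------------------------------------------------------

def test_unknown_toy_reaction_rejected():
    with pytest.raises(ValueError, match="unknown toy reaction"):
        run_toy_reaction("cold_fusion")
    with pytest.raises(ValueError, match="Hartree"):
        run_toy_reaction("ammonia_pt", method="b3lyp")


def test_toy_trajectory_satisfies_frame_invariants(hat_toy_trajectory):
    traj = hat_toy_trajectory
    traj.validate()
    assert traj.n_frames == 9
    arcs = traj.arc_coords()
    assert (np.diff(arcs) > 0).all()
    for f in traj.frames:
        assert f.energy is not None
        assert abs(f.metadata["s_squared"] - 0.75) < 0.8


def test_methyl_exchange_symmetric_path(exchange_toy_trajectory):
    """A thermoneutral identity reaction: the energy profile must be
    mirror-symmetric about the midpoint, and the verdict is HAT."""
    traj = exchange_toy_trajectory
    e = np.array([f.energy for f in traj.frames])
    np.testing.assert_allclose(e, e[::-1], atol=2e-3)
    roles = traj.frames[0].metadata
    result = analyze_trajectory(traj, donor_atom=roles["donor_atom"],
                                acceptor_atom=roles["acceptor_atom"],
                                h_atom=roles["h_atom"])
    assert result.report.verdict == "HAT"


def test_ammonia_pt_has_no_heavy_atom_electron_transfer(pt_toy_trajectory):
    """Proton transfer moves no electron between heavy atoms: apart from
    the donor bond->lone-pair and acceptor lone-pair->bond reorganization,
    every track stays put."""
    traj = pt_toy_trajectory
    roles = traj.frames[0].metadata
    result = analyze_trajectory(traj, donor_atom=roles["donor_atom"],
                                acceptor_atom=roles["acceptor_atom"],
                                h_atom=roles["h_atom"])
    assert result.report.verdict == "PT"
    allowed = set()
    for spin in ("alpha", "beta"):
        allowed.add((spin, result.report.narrative[spin].track_id))
        for tid in result.report.lone_pair_evidence[spin]:
            allowed.add((spin, tid))
    for spin, profs in result.profiles.items():
        for p in profs:
            if (spin, p.track_id) not in allowed:
                assert p.max_delta < 0.2, (spin, p.track_id, p.max_delta)
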