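"""Orbital labels and the mechanism decision table."""

import numpy as np
import pytest

from ibotrace.classifier import (
    SetupError,
    Thresholds,
    classify,
    label_orbital,
)
from ibotrace.fixtures import SyntheticScenario, make_synthetic
from ibotrace.tracker import track


# ----------------------------------------------------------------------------
# label_orbital
# ----------------------------------------------------------------------------

def test_typical_ch_bond_label():
    q = np.array([0.55, 0.42, 0.01, 0.01, 0.005, 0.005])
    lab = label_orbital(q)
    assert lab.kind == "two_center_bond"
    assert set(lab.atoms) == {0, 1}
    assert lab.weights[0] == pytest.approx(0.55)


def test_pure_single_atom_is_lone_pair_or_core():
    q = np.array([0.99, 0.005, 0.005])
    assert label_orbital(q).kind == "lone_pair"
    assert label_orbital(q, core_hint=True).kind == "core"


def test_three_center_spread_is_delocalized_with_warning():
    q = np.array([0.35, 0.33, 0.30, 0.02])
    with pytest.warns(RuntimeWarning, match="delocalized"):
        lab = label_orbital(q)
    assert lab.kind == "delocalized"
    assert len(lab.atoms) == 3


def test_partial_single_atom_is_delocalized():
    # one atom above the bond threshold but far from lone-pair purity
    assert label_orbital(np.array([0.6, 0.15, 0.15, 0.1])).kind == "delocalized"


# ----------------------------------------------------------------------------
# classify on synthetic ground truth
# ----------------------------------------------------------------------------

def _tracks(ds):
    return {spin: track(ds.charges[spin], spin=spin,
                        arc_coords=ds.arc_coords)
            for spin in ("alpha", "beta")}


def _classify(ds, thresholds=Thresholds(), swap=False, h_atom=...):
    trk = _tracks(ds)
    a, b = trk["alpha"], trk["beta"]
    if swap:
        a, b = b, a
    return classify(a, b, donor_atom=ds.donor_atom,
                    acceptor_atom=ds.acceptor_atom,
                    h_atom=ds.h_atom if h_atom is ... else h_atom,
                    thresholds=thresholds,
                    acceptor_heavy_atoms={ds.metal_atom},
                    elements=["C", "H", "O", "Fe", "He", "He"])


@pytest.mark.parametrize("kind", ["HAT", "cPCET", "PT",
                                  "closed_shell_transfer"])
def test_decision_table_recovers_generating_mechanism(kind):
    ds = make_synthetic(SyntheticScenario(kind=kind))
    report = _classify(ds)
    assert report.verdict == ds.expected_verdict
    # narrative consistency: quoted charges match the underlying tracks
    for spin, n in report.narrative.items():
        tr = _tracks(ds)[spin][n.track_id]
        assert n.final_q_h == pytest.approx(tr.final_q[ds.h_atom], abs=1e-10)


def test_flat_scenario_fails_precondition():
    ds = make_synthetic(SyntheticScenario(kind="flat"))
    with pytest.raises(SetupError, match="bond track"):
        # atoms 4/5 carry no bond to H: no initial X-H track exists
        trk = _tracks(ds)
        classify(trk["alpha"], trk["beta"], donor_atom=4, acceptor_atom=2,
                 h_atom=1)


def test_spin_relabelling_leaves_verdict_unchanged():
    for kind in ("HAT", "cPCET"):
        ds = make_synthetic(SyntheticScenario(kind=kind))
        assert _classify(ds).verdict == _classify(ds, swap=True).verdict


@pytest.mark.parametrize("theta_h", [0.15, 0.20, 0.25, 0.30, 0.35])
def test_verdicts_stable_across_h_threshold_range(theta_h):
    th = Thresholds(h=theta_h)
    for kind in ("HAT", "cPCET"):
        ds = make_synthetic(SyntheticScenario(kind=kind))
        assert _classify(ds, thresholds=th).verdict == kind


def test_verdict_deterministic():
    ds = make_synthetic(SyntheticScenario(kind="cPCET", noise_sd=0.01,
                                          seed=5))
    d1 = _classify(ds).to_dict()
    d2 = _classify(ds).to_dict()
    assert d1 == d2


def test_transferred_h_auto_detected():
    ds = make_synthetic(SyntheticScenario(kind="HAT"))
    report = _classify(ds, h_atom=None)
    assert report.verdict == "HAT"
    assert report.transferred_h == ds.h_atom
    assert any("auto-detected" in note for note in report.notes)


def test_conflicting_split_orbital_gives_ambiguous():
    """A migrating orbital split evenly between H and metal is never
    silently assigned; the verdict is ambiguous with an explanatory note."""
    n_frames, n_atoms = 6, 5
    xh = np.array([0.55, 0.42, 0.01, 0.01, 0.01])
    # final: q(H) and q(acceptor-heavy) both inside the conflict window
    split = np.array([0.02, 0.24, 0.13, 0.13, 0.48])
    ylp = np.array([0.01, 0.0, 0.97, 0.01, 0.01])
    yh = np.array([0.01, 0.42, 0.55, 0.01, 0.01])
    t = np.linspace(0, 1, n_frames)[:, None]
    mig = [(np.vstack([(1 - s) * xh + s * split,
                       (1 - s) * ylp + s * yh])) for s in t[:, 0]]
    stay = [(np.vstack([(1 - s) * xh + s * np.array([0.95, 0.02, .01, .01, .01]),
                        (1 - s) * ylp + s * yh])) for s in t[:, 0]]
    a = track(mig, spin="alpha")
    b = track(stay, spin="beta")
    report = classify(a, b, donor_atom=0, acceptor_atom=2, h_atom=1,
                      acceptor_heavy_atoms={2, 3})
    assert report.verdict == "ambiguous"
    assert any("conflicting" in note for note in report.notes)


def test_thresholds_validated_and_echoed():
    with pytest.raises(ValueError, match="outside"):
        Thresholds(h=1.5)
    ds = make_synthetic(SyntheticScenario(kind="PT"))
    report = _classify(ds)
    assert report.to_dict()["thresholds"] == {
        "bond": 0.20, "tail": 0.15, "h": 0.25, "leave": 0.30}
    # the serialized forms mention verdict and thresholds
    assert "PT" in report.to_json()
    assert "thresholds" in report.to_text()
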