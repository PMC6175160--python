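# ibotrace

Spin-resolved intrinsic bond orbital (IBO) tracking along reaction paths,
for telling apart the mechanisms hiding behind a net hydrogen-atom
transfer:

* **HAT** — hydrogen atom transfer: one spin channel's X–H bond electron
  travels *with* the proton into the new Y–H bond;
* **cPCET** — concerted proton-coupled electron transfer: proton and
  electron move in the same elementary step but along different paths
  (e.g. the electron into a metal d shell, the proton onto an oxygen lone
  pair);
* **PT** — pure proton transfer (no redox change), and the closed-shell
  (hydride-like) transfer of an electron pair.

These cases produce the same reactants-to-products bookkeeping and cannot
be distinguished from endpoint properties alone.  They *can* be read
directly off the wavefunction sequence along the reaction path: `ibotrace`
consumes a series of unrestricted single-determinant frames (geometry,
overlap matrices, occupied MO coefficients per spin), localizes each spin
manifold into intrinsic bond orbitals, threads every orbital's identity
through the frames, and reports which spin channel's electron followed the
proton.  The intended users are computational chemists who already have an
IRC (or any ordered reaction path) from their quantum-chemistry program
and want a mechanism verdict with an auditable evidence trail.

## Method in brief

For each frame and spin channel σ:

1. **IAOs.** Build intrinsic atomic orbitals A from the occupied
   coefficients C, the computational-basis overlap S₁, the minimal
   free-atom reference overlap S₂ and the cross overlap S₁₂: depolarize
   the occupied space through the minimal basis, combine occupied and
   complementary projectors applied to the reference functions, and
   symmetrically orthogonalize.  Occupied MOs are exactly representable in
   the IAO span, and populations are squared expansion coefficients —
   non-negative and nearly basis-set independent.
2. **IBOs.** Maximize L = Σᵢ Σ_A q_A(i)ᵖ (default p = 4) over unitary
   mixings of the occupied orbitals by Jacobi 2×2 sweeps, where
   q_A(i) = Σ_{ρ∈A} |⟨iao_ρ|φᵢ⟩|² is orbital i's partial charge on atom A.
3. **Tracking.** Match orbitals of consecutive frames by solving the
   linear assignment problem on ‖qᵢ(t) − qⱼ(t+1)‖₂.
4. **Change metric.** δᵢ(t) = √Σ_A (q_A(i,t) − q_A(i,0))², in electrons:
   flat for spectators, √2 for a complete one-electron relocation.
5. **Classification.** Label orbitals chemically (two-center bond, lone
   pair, core) at the first and last frame and apply an explicit decision
   table to the fate of each spin channel's X–H bond orbital and of the
   acceptor lone pairs.  All thresholds are configurable and echoed in
   every report.

## Worked example

Hydrogen abstraction from methane by hydroxyl radical (a desk-scale HAT
prototype; 11 UHF/STO-3G frames along a linear-synchronous-transit path):

```python
from ibotrace import run_toy_reaction, analyze_trajectory

traj = run_toy_reaction("methane_plus_oh", n_frames=11)
roles = traj.frames[0].metadata
result = analyze_trajectory(traj, donor_atom=roles["donor_atom"],
                            acceptor_atom=roles["acceptor_atom"],
                            h_atom=roles["h_atom"])
print(result.report.to_text())
```

prints

```
verdict: HAT
transferred H: atom 1 (donor 0 -> acceptor 5)
thresholds: {'bond': 0.2, 'tail': 0.15, 'h': 0.25, 'leave': 0.3}
  alpha: X-H track 6: two_center_bond(0:0.54, 1:0.46) -> lone_pair(0:0.98); q(H)=0.016, q(donor side)=0.976, q(acceptor heavy)=0.008, stayed
  beta: X-H track 5: two_center_bond(0:0.54, 1:0.46) -> two_center_bond(5:0.55, 1:0.44); q(H)=0.444, q(donor side)=0.007, q(acceptor heavy)=0.550, migrated
  alpha: acceptor lone pair(s) joining new bond: [9]
  beta: acceptor lone pair(s) joining new bond: none
```

Reading the evidence: both spin channels start with the same C–H σ bond
(0.54 e⁻ on C, 0.46 e⁻ on the transferred H).  The β orbital migrates into
the new O–H bond still carrying 0.44 e⁻ on the proton — that electron
travelled with it — while the α orbital collapses to a carbon-centered
radical lone pair, and the α oxygen lone pair supplies the second electron
of the new bond.  That spin-resolved pattern is the HAT signature; in a
cPCET pattern the migrating orbital lands on the acceptor heavy atoms with
almost no weight on the proton, and the new Y–H bond is built from
acceptor lone pairs of *both* spins.

The same pipeline is available from the shell:

```bash
ibotrace fixtures methane_plus_oh -o out/toy        # writes a frame bundle
ibotrace analyze out/toy/methane_plus_oh.h5 -o out/analysis
ibotrace fixtures cPCET -o out/syn                  # synthetic charge tables
ibotrace track out/syn/charges.csv -o out/tracks
ibotrace classify out/tracks/tracks.csv -o out/rep \
    --donor 0 --acceptor 2 --h-atom 1 --metal 3
```

`analyze` writes per-orbital charge tables, track tables, change profiles,
a two-panel energy/orbital-change figure, and the mechanism report as JSON
and text, all stamped with the package version and a configuration hash.

## Layout

| module | role |
| --- | --- |
| `ibotrace.frame_io` | Molden / XYZ / frame-bundle reading and writing, frame validation |
| `ibotrace.iao_engine` | intrinsic atomic orbitals and per-orbital atomic charges |
| `ibotrace.ibo_localizer` | Jacobi-sweep bond-orbital localization |
| `ibotrace.tracker` | frame-to-frame orbital identity assignment |
| `ibotrace.metrics` | orbital-change profiles and active-orbital selection |
| `ibotrace.classifier` | chemical labels and the mechanism decision table |
| `ibotrace.fixtures` | synthetic mechanism scenarios and toy UHF reaction paths |
| `ibotrace.cli` | `ibotrace analyze / fixtures / track / classify` |
| `ibotrace.basis`, `.integrals`, `.scf` | minimal Gaussian basis/integral/UHF engine behind the fixtures |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
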