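# Methods

This note records what `ibotrace` computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the shipped tests
do and do not demonstrate.

## Scope and input model

The package analyzes *one concerted elementary step*: an ordered sequence
of single-determinant (Hartree–Fock or Kohn–Sham) wavefunctions along a
reaction coordinate, with fixed atom ordering, basis set and electron
counts.  Stepwise mechanisms (discrete electron-transfer or
proton-transfer intermediates) are out of scope — each elementary step
must be analyzed separately.  Fractional occupations are rejected: the
orbital bookkeeping below is only meaningful for a determinant.  The
path parameter (`arc_coord`) is treated as an opaque strictly monotone
label in whatever units the upstream IRC used; nothing downstream depends
on its scale.

Coordinates are stored in Å; integrals are evaluated in atomic units
internally.

## Intrinsic atomic orbitals and charges

For occupied coefficients C (one spin channel), computational-basis
overlap S₁, minimal-reference overlap S₂ and cross overlap S₁₂:

    P₁₂ = S₁⁻¹ S₁₂,     C̃ = orth(P₁₂ S₂⁻¹ S₁₂ᵀ C)
    A   = orth[ (O S₁ Õ S₁ + (1 − O S₁)(1 − Õ S₁)) P₁₂ ],   O = CCᵀ, Õ = C̃C̃ᵀ

where `orth` is Löwdin (symmetric) orthonormalization under S₁.
Symmetric orthogonalization is used throughout because it perturbs the
atomic character of the reference functions least; its metric eigenvalues
are floored at 1e−10 and a condition number above 1e10 is a hard error
rather than a silent loss of precision.

The minimal reference is a free-atom minimal basis shipped as plain-text
data (`data/sto-3g.gbs`), one function per occupied atomic shell — the
property the construction actually needs.  The reference identifier is
recorded in every `IAOSet`.  Charges are Mulliken-style populations in
the orthonormal IAO basis, q_A(i) = Σ_{ρ∈A} |⟨iao_ρ|φᵢ⟩|²: non-negative
by construction, summing to 1 per spin orbital, invariant under unitary
mixing of the occupied space, and stable to a few hundredths of an
electron across computational basis sets (measured at 0.043 e⁻ max
between two split-valence bases on water).

## Localization

The localization functional is L = Σᵢ Σ_A q_A(i)ᵖ with p = 4 by default;
p = 2 (the Pipek–Mezey form in the IAO basis) is available for
cross-checks.  The quartic exponent penalizes spuriously delocalized
50/50 mixtures that the quadratic functional tolerates.

Jacobi sweeps visit orbital pairs in fixed lexicographic order (a
seed-randomized order exists purely for robustness testing).  Each pair's
objective along the rotation angle is a trigonometric polynomial of order
≤ 2p with period π/2; it is maximized by a 49-point scan, bounded Brent
refinement, and an analytic Newton polish of the stationarity condition,
which drives residual pair gradients to machine precision.  Properties
maintained:

* the objective never decreases at an accepted rotation (asserted per
  rotation in `debug_monotone` mode);
* rotations that are flat within 1e−12 *and* have pair gradient below
  0.1·tol are skipped, which prevents phase churn between exactly
  degenerate orbitals on symmetric systems;
* convergence means the largest pairwise gradient < tol (default 1e−8);
  non-convergence returns a result flagged `converged=False` with a
  warning, never silently;
* phases are fixed by making each orbital's largest-magnitude IAO
  coefficient positive, so downstream comparisons are sign-stable.

Core orbitals are localized together with the valence; they trivially
collapse onto single atoms and are separated later by labelling, which
keeps the localization contract simple.

## Tracking

Orbital identity between consecutive frames is a linear assignment
problem solved exactly (`scipy.optimize.linear_sum_assignment`).  The
default cost ‖qᵢ(t) − qⱼ(t+1)‖₂ is phase-free and basis-free; an
orbital-overlap cost 1 − |⟨φᵢ|φⱼ⟩| is available when consecutive frames
share a basis and the geometry change per step is small.  Assignments are
chained frame to frame; no global multi-frame optimization and no
interpolation are attempted.  Two diagnostics guard the chain: a
recorded warning when a second assignment lies within 1e−9 of the optimum
(degenerate orbitals — tracks may be legitimately swapped), and a
coarse-grid warning when any per-step charge jump exceeds 0.5 e⁻, which
in practice means the path needs denser frames.  When two orbitals'
charge vectors genuinely cross, the continuity-optimal matching follows
the nearest-neighbour branch; this is the intended behaviour — identity
through a true crossing is not defined by charge data alone.

## Change metric

δ(t) = √Σ_A (q_A(t) − q_A(0))², reported in electrons (`l2_sum`).  With
this convention a complete one-electron relocation between two atoms
reads √2 ≈ 1.414 and a half transfer √0.5 ≈ 0.707.  An alternative
`rms_per_atom` convention (divided by √N_atoms) is provided because
"root-mean-square over atoms" admits both readings; `l2_sum` is the
default since it keeps the √2 landmark independent of system size.  The
first frame is the reference, so δ(0) = 0 exactly.  Orbitals with
max δ ≥ 0.2 e⁻ (configurable) are flagged active: the value sits well
above numerical jitter and well below any one-electron event.

## Classification

Thresholds (all configurable, all echoed in every report):

| name | default | meaning |
| --- | --- | --- |
| θ_bond | 0.20 e⁻ | minimum atomic charge to count as a bond partner |
| θ_tail | 0.15 e⁻ | single-atom orbitals need q ≥ 1 − θ_tail for lone-pair/core labels |
| θ_H | 0.25 e⁻ | minimum final charge on the transferred H for "the electron travelled with the proton" |
| θ_leave | 0.30 e⁻ | below this final donor-side charge the orbital has migrated |

A two-center bond has exactly two atoms above θ_bond; three or more gives
a delocalized label with a warning instead of an error, since bridged
transition-state orbitals legitimately spread.  Core shells are
identified per element count (1 for first-row atoms, 5 for second row, 9
through the 3d block) among single-atom orbitals of at least 0.995
atomic purity — genuine 1s-like cores are essentially entirely on their
atom, which cleanly separates them from valence lone pairs (~0.97).

The decision table inspects, per spin channel, the initial X–H σ-bond
track's fate (`migrate` if its final donor-side charge < θ_leave) and
the fate of acceptor lone pairs:

* one channel migrates into a Y–H bond carrying q(H) ≥ θ_H, and the
  opposite channel's acceptor lone pair becomes part of that bond → HAT;
* one channel migrates with q(H) < θ_H and ≥ 1 − θ_tail of its weight on
  the acceptor heavy atoms, and acceptor lone pairs of both spins form
  the new Y–H bond → cPCET;
* neither migrates, the donor keeps its pair, and both-spin acceptor
  lone pairs form the new bond → PT;
* both channels migrate into the same new bond → closed-shell
  (hydride-like) transfer;
* anything else → ambiguous, with the full per-spin narrative attached.
  In particular, a migrating orbital whose final q(H) and acceptor-heavy
  weight both fall within ±0.05 of θ_H is reported ambiguous rather than
  silently assigned.

An orbital that started as a single-atom acceptor orbital and ends in
the new Y–H bond counts as lone-pair evidence even if the labelling pass
called it a core — a genuine core cannot become a bond, so the trajectory
overrides the static label.  The transferred H may be auto-detected (the
hydrogen whose strongest bonding partner switches from the donor side to
the acceptor side); auto-detection is always stated in the report notes.
The verdict is deterministic given inputs and thresholds and invariant
under swapping the α/β labels.  On the shipped fixtures the HAT and
cPCET verdicts are stable for θ_H anywhere in [0.15, 0.35].

## Synthetic scenarios

`fixtures.make_synthetic` generates per-orbital charge trajectories that
realize each decision-table pattern exactly at zero noise: sigmoid
interpolation (logistic steepness 8, rescaled to hit the endpoints
exactly) between hand-set endpoint distributions over six atoms (donor,
transferred H, acceptor site, metal centre, two spectators), four
orbitals per spin (X–H bond, acceptor lone pair, metal lone pair,
spectator).  Endpoint weights follow typical IAO bond polarizations
(X 0.55 / H 0.42 for a C–H-like bond, 0.97 for a lone pair, 0.90 for a
metal-gained electron).  Gaussian noise (σ < 0.05 e⁻) is applied
per entry, clipped to non-negative and renormalized.  Everything is
reproducible from a single seed (default 20180829).

What these fixtures do show: the tracking, metric and classification
stages recover the generating mechanism exactly at zero noise and ≥ 95%
at σ = 0.01 over 100 seeds.  What they do not show: anything about real
electronic structure — no avoided crossings, no orbital mixing, no
delocalized substrate radicals.  Those aspects are exercised by the toy
SCF paths, and only at minimal-basis Hartree–Fock quality.

## Toy reaction paths

`fixtures.run_toy_reaction` builds three desk-scale prototypes with an
in-package unrestricted Hartree–Fock engine (McMurchie–Davidson
integrals over contracted Gaussians, DIIS-accelerated SCF, s/p/d shells;
shipped bases: STO-3G, 3-21G, 6-31G for H, He, C, N, O):

* `methane_plus_oh` — •OH + CH₄ → H₂O + •CH₃ (doublet), the HAT
  prototype;
* `methyl_exchange` — •CH₃ + CH₄, the thermoneutral symmetric HAT;
* `ammonia_pt` — NH₄⁺ + NH₃ proton transfer (closed shell), the PT
  prototype.

Paths are linear synchronous transits between reactant-like and
product-like structures (11 frames by default); the diagnostics depend on
endpoints plus continuity, not on the exact steepest-descent coordinate,
so a transit path serves in place of a true IRC.  Each frame's SCF is
seeded with the previous frame's converged density, and the path is swept
from *both* ends with the lower-energy solution kept per frame: a
one-directional chain can ride an excited charge-transfer branch past the
avoided crossing (observed for the hydroxyl abstraction, where the
forward chain stays on a CH₃⁻/H₂O⁺-like state), and the two-sided sweep
restores the variational ground-state sequence.  ⟨S²⟩ is recorded per
frame and a deviation > 0.8 from nominal is flagged in metadata.

Default problem sizes (11 frames, 15–17 AOs) keep a full toy run with
analysis under a minute; test runs use 7–9 frames, which the verdicts are
insensitive to.

These prototypes are stand-ins: they reproduce the *spin-resolved flow
patterns* (one channel's bond orbital following the proton vs. staying
behind) at hydrogen-abstraction scale, not the metalloenzyme systems the
method targets.  A genuine metal-centred cPCET requires transition-metal
wavefunctions that the built-in engine does not produce; cPCET coverage
therefore comes from the synthetic scenarios, and cluster-scale
trajectories computed elsewhere enter unchanged through the frame-bundle
format (demonstrated in the acceptance suite with a synthetic high-spin
iron-bookkeeping bundle).

## File formats

* **Molden** (read): `[Atoms]` in Å or bohr, `[GTO]` with s/p/d/f shells
  (sp contractions supported), unrestricted `[MO]` blocks with `Spin=`
  labels.  Spherical d (`[5D]`) and Cartesian conventions are both
  accepted and the detected dialect is recorded in frame metadata;
  spherical f (`[7F]`) is rejected with a clear error (Cartesian f is
  fine).  Files whose occupied orbitals deviate from orthonormality by
  more than 1e−4 are rejected; smaller deviations (print truncation) are
  repaired by Löwdin re-orthonormalization within the occupied span and
  noted in metadata.  Explicit `Spin=` labels mark a file as
  unrestricted even if only α orbitals are present; restricted
  open-shell exports are rejected with a spin-mismatch error.
* **Frame bundle** (read/write): HDF5, schema tag `ibotrace-frame-1`,
  every matrix at full precision; reading is the exact inverse of
  writing, schema mismatches and truncated archives raise integrity
  errors, and trajectories are validated on both ends (monotone
  arc coordinate, constant atoms/basis/electron counts, orthonormal
  occupieds per frame).
* **CSV tables**: long-format per-orbital charges
  (frame, spin, orbital_id, atom, q), track tables and change profiles;
  all CLI-written CSVs carry a provenance comment line (version,
  configuration hash).

## Numerical choices

* Orthonormality acceptance for frames: 1e−8 (∞-norm of CᵀS₁C − I).
* Löwdin eigenvalue floor 1e−10, condition limit 1e10, occupied-span
  residual tolerance for charge partitioning 1e−6.
* Localization: tol 1e−8 on the pair gradient, 60 sweeps maximum,
  angle refinement to ~1e−12.
* Occupation threshold 0.5 e⁻ separates occupied from virtual on Molden
  read; only integral occupations are accepted.
* Assignment ambiguity tolerance 1e−9 (total-cost degeneracy via 2-swap
  bound); coarse-grid warning at 0.5 e⁻ per step.
* Seeds: every stochastic element (synthetic noise, randomized sweep
  order) takes an explicit seed; nothing draws from global state.

## Known limitations

* The built-in SCF engine covers H–O with s/p/d shells and no effective
  core potentials; transition-metal fixtures are out of its reach by
  design (unsupported elements raise immediately).
* Restricted open-shell inputs are not converted; supply unrestricted
  orbitals.
* One elementary step per analysis; no multi-step networks, no kinetics,
  no tunneling, no energy decomposition.
* Tracking assumes constant electron counts; ionization events along a
  path are not handled.
* The classifier's verdicts are threshold-based operationalizations of
  qualitative criteria; the thresholds are surfaced in every report
  precisely because borderline systems (strongly delocalized substrate
  radicals, very asynchronous transfers) can and should come out
  `ambiguous` for a human to inspect via the narrative and the charge
  tables.
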