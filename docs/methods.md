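# Methods

`dysonspec` simulates single-photon photoelectron spectra — static and
time-resolved — from configuration-interaction (CI) wavefunctions and
surface-hopping trajectory ensembles, using Dyson norms as the ionization
probability proxy. This note records the model, its assumptions, the
numerical choices, and what the synthetic fixtures do and do not emulate.

## Ionization model

An ionization channel i → α connects an n-electron source state Ψᵢ to an
(n−1)-electron ionic state Ψ_α. In the sudden approximation, with the
transition dipole to the continuum treated as a constant and the continuum
electron decoupled from the ion, the channel strength is governed by the
Dyson orbital

    φᴰ_{i,α}(r) = √n ⟨Ψ_α | Ψᵢ⟩_{n−1},

the one-electron overlap left after integrating out n−1 coordinates. Its
squared norm ‖φᴰ‖² (the *Dyson norm*) approximates the relative
single-photon ionization probability; in analogy with the oscillator
strength we use the amplitude

    W_{i,α} = ΔE_{i,α} · ‖φᴰ_{i,α}‖²,   ΔE_{i,α} = V_α − Vᵢ,

as the per-channel yield, where ΔE is the binding energy. With a complete
set of final states this construction satisfies an f-sum-rule analogue:
summing ‖φᴰ‖² over a complete orthonormal basis of the (n−1)-electron space
gives exactly n, which the test suite verifies on small systems.

This model does **not** describe multiphoton or strong-field ionization,
photoelectron angular distributions, or kinetic-energy-dependent continuum
structure; those are outside its validity by construction.

## Determinant algebra

CI states are expansions over Slater determinants. Spin-adapted CSFs with
genealogical (Yamanouchi–Kotani) coupling are expanded into determinants
with products of Clebsch–Gordan coefficients; there is no analytic overlap
between two CSFs built from non-orthogonal orbital sets, so all overlap
work happens in the determinant basis.

Phase convention (fixed, shared by every module): a determinant's phase
refers to the antisymmetrised product in *spatial-major* order — spatial
orbitals ascending, alpha before beta within one orbital — while the stored
representation is the sorted index tuple (alpha block, then beta block).
With this choice a closed-shell determinant has coefficient +1 and the
two-electron singlet expands to (|aα bβ| − |aβ bα|)/√2 in spatial-major
notation. Correctness of relative signs is pinned by a property test that
applies the S² operator (built from explicit fermionic ladder operators in
the same convention) to every expansion and checks the S(S+1) eigenvalue —
a check that no self-consistent sign error can pass.

Because neutral and ionic states come from separate orbital optimisations,
their MO sets are non-orthogonal. The spatial inter-set overlap
C_srcᵀ S_AO C_ion is the only coupling; opposite spins never overlap, so
every (n−1)×(n−1) determinant-pair minor factorises into an alpha and a
beta sub-determinant (evaluated by LU decomposition). The brute-force
reference path deliberately avoids both factorisation and LU — explicit
annihilation-operator algebra plus Leibniz permutation sums — and is
restricted to ≤ 12 spin orbitals.

Screening follows common CI practice: CSF coefficients and
determinant-pair coefficient products are kept only when strictly above
1e-4 in magnitude (configurable, and interpretable as |c| or c²; |c| is the
default). Screened expansions are **not** renormalised, so truncation
shows up honestly as a small norm deficit; tightening the pair threshold
to 1e-7 changes toy-system Dyson norms by well under 1 % (the acceptance
script prints the measured value, typically 0.2–0.6 %).

## Static spectra

Open channels (ΔE ≥ 0) contribute sticks at ΔE with height W; closed
channels are dropped, never clipped. Sticks are convolved with unit-area
Gaussians (default FWHM 0.2 eV) on a uniform binding-energy grid (default
0–14 eV, 0.01 eV step); broadening is linear and conserves the summed
stick weight to the trapezoid accuracy of the grid. Tautomer mixtures are
weighted sums with normalised weights (defaults follow gas-phase cytosine
populations: keto:syn-enol:anti-enol:imino = 29:17:37:17 for the static
spectrum, keto:enol = 35:65 for the time-resolved signal). A global
binding-energy shift is exposed as a config scalar (default 0); lowering
the probe energy by the same amount is the equivalent mechanism on the
kinetic-energy axis, and both are supported. Bright/dark (ππ*/nπ*)
classification assigns the larger transition-dipole norm to ππ*, breaking
near-ties (relative tolerance 0.05) toward the lower state index with a
`mixed` flag.

## Wigner sampling

Initial-condition ensembles come from the vibrational ground-state Wigner
function of a harmonic model: per normal mode the dimensionless coordinate
and momentum are independent zero-mean Gaussians with variance ½, mapped
to Cartesian displacements through the mass-weighted modes with the
characteristic length √(ħ/ω). Only 0 K sampling is implemented;
translations/rotations are excluded by a 10 cm⁻¹ wavenumber threshold.
Momenta are emitted optionally (amu·Å/fs) — static spectra do not use
them, but downstream dynamics codes do.

## Time-resolved assembly

Trajectory records carry spin-mixed state weights w_j(t) (squared
amplitudes of the states contributing to the active surface, summing to
one), state potentials, and per-channel ion potentials and Dyson norms on
a uniform stride (5 fs by default, matching how often Dyson norms are
typically evaluated along trajectories). At each step, each open channel
(0 ≤ ΔE ≤ ħω_probe) emits a stick at E_kin = ħω − ΔE with intensity
w_j · W (default) or w_j · ‖φᴰ‖² (`mode="norm"`); whether the ΔE factor
belongs in the time-resolved signal is genuinely ambiguous in the source
formulation, so both are implemented and the choice is recorded in the
grid metadata.

Pooling: each trajectory of tautomer T gets per-bin weight
frac(T)/n(T, bin), where n counts the tautomer's trajectories covering
that bin — so ensembles with unequal trajectory lengths stay correctly
normalised (normalisation by the total count is the config alternative).
Energy broadening uses the same 0.2 eV Gaussian as the static spectra.
The instrument response is a Gaussian convolution along time (default
FWHM 160 fs, an experimental pump-probe cross-correlation width); the
signal is taken as zero before t = 0 — trajectories start at the pump,
there is no pre-pump signal — and continued by its edge value beyond the
last frame. Both boundary policies are documented behaviour, and fits
exclude the final two FWHM of the convolved traces for this reason.

Decomposition slices keyed (tautomer, source state, pathway) are
accumulated during assembly; the total grid is their exact sum, so any
decomposition is additive to round-off. State attribution is fractional
(proportional to w_j); pathway and tautomer attribution are exclusive
per-trajectory labels. Energy-window integration (default 0–4 eV kinetic
energy) is trapezoidal with linear interpolation at window edges.

## Lifetime fitting

Pathway yields are fitted to independent monoexponentials A·exp(−t/τ),
treating mechanistically distinct relaxation routes as independent. For
convolved traces the Gaussian⊗exponential model (exponentially modified
Gaussian) with the known instrument σ is available; it is evaluated in the
erfcx-stabilised form f(t) = (A/2)·erfcx((σ/τ − t/σ)/√2)·exp(−t²/2σ²),
which is overflow-safe even for τ ≪ σ. Global fits share a set of τ_k
across traces with free per-trace amplitudes; negative amplitudes express
rise terms, so both parallel and sequential (cascade) kinetics are
representable — which functional form underlies any given published global
fit is usually not identifiable from the yield alone, and the package
deliberately does not privilege one. All fits are deterministic:
8 log-spaced τ initialisations per constant, least squares (lmfit),
lowest χ² wins; standard errors come from the local covariance. A best τ
exceeding 100× the trace span sets a `non_decaying` flag instead of
raising. An identifiability warning with a numeric Jacobian condition
number is attached when shared constants are not outnumbered by
informative traces.

## Synthetic fixtures

The generators exist so every pipeline stage is testable with no external
data.

*Toy CI systems*: random normalised CI vectors over determinant sectors of
2–6 spatial orbitals and 2–4 electrons, with three inter-set overlap
regimes (identical orbitals; a random orthogonal rotation; independently
Löwdin-orthonormalised MO sets under a random symmetric-positive-definite
AO metric). The full-CI ionic family option enumerates every
(n−1)-electron determinant, enabling the sum-rule check.

*Trajectory ensembles*: each trajectory starts in the bright ππ* state
(4.6 eV), hops to the dark nπ* state (4.3 eV) after an Exp(τ_hop = 40 fs)
delay, and leaves the excited manifold at a terminal time drawn from
Exp(τ_pathway) measured from t = 0, after which only a closed
ground-state channel remains (binding 8.6 eV > 5.4 eV probe). The
excited-state survival of each pathway — hence its ionization yield —
therefore decays with exactly the specified lifetime, while the
ππ*→nπ* hand-off changes the instantaneous channel amplitudes
(W = 3.2 vs 3.0), imitating a mildly time-dependent ionization
probability. Event times use stratified inverse-CDF sampling by default
(plain i.i.d. via `stratified=False`): marginals remain exponential, but
ensemble-level fluctuations shrink, keeping 100-trajectory demo ensembles
statistically stable. The shipped demo spec uses three equally populated
pathways with lifetimes 60 / 300 / 1300 fs — spanning tens of
femtoseconds to ~1.3 ps, the spread typical of competing internal
conversion and intersystem crossing routes.

What the synthetic ensemble does *not* emulate: real potential-energy
surfaces (energies and norms are constant templates, not
geometry-dependent), nuclear coherence effects, quartet channels, and the
pre-time-zero cross-correlation artefacts of a real pump-probe
experiment. Passing tests therefore demonstrate the correctness of the
assembly/convolution/fitting machinery and the *structural* claim below,
not quantitative agreement with any molecule.

## The headline demonstration

The end-to-end test generates three pathways with well-separated
lifetimes, assembles and convolves the total TRPES, and fits the
energy-integrated yield two ways. Per-pathway monoexponential fits (using
the pathway decomposition, available only in simulation) recover each
generating lifetime within a few percent — well inside the 15 % bound
asserted in the tests. A two-exponential fit of the *total* yield — the
only quantity an experiment provides — converges to composite constants
(≈ 90 fs and ≈ 870 fs for the demo spec) that differ from *every*
generating lifetime by many times their standard error. Multi-pathway
decays on overlapping time scales are thus demonstrably not recoverable
from the total photoionization signal alone, which is the scientific point
the toolkit renders testable.

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: toy systems up
to 6 spatial orbitals / 4 electrons (the brute-force oracle caps at 12
spin orbitals); 200+ random systems for the oracle sweep; 2000 Wigner
samples for variance checks (5 % tolerance); 300 trajectories (100 per
pathway), 1400 fs at 5 fs stride, 0.02 eV kinetic-energy bins for the
pipeline demonstration. Oracle agreement is asserted at 1e-10, sum rules
at 1e-8, CSF expansion norms at 1e-12, spectral conservation at 1e-6
relative, decomposition additivity at 1e-8, and the discrete-vs-analytic
convolution comparison at 1e-6 in the grid interior (≥ 3 FWHM from either
time edge, where neither boundary policy reaches).
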