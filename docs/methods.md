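# Methods

This note records the model, the numerical choices and their rationale, at
the level of detail a maintainer needs to modify the package safely.

## Physical model

A `ModelSystem` is a site-basis effective Hamiltonian: n sites with
energies ε_μ (hartree), positions r_μ (Å), Hermitian inter-site couplings
t_μν, nuclear charges Z_μ and an optional symmetric positive-definite
overlap S (identity by default — the site basis then doubles as the
orthonormal basis; all analysis accepts general S so non-orthogonal
external data work unchanged). The electronic state is the closed-shell
one-electron density matrix; occupations live in [0, 2] and
Tr(P S) = N_e. The effective one-electron operator is

    F(P) = H0 + diag(U_μ (P S)_μμ),

an on-site Hubbard-like mean field: the minimal density dependence that
makes the equation of motion genuinely nonlinear while retaining an
exactly solvable linear limit (U ≡ 0) against which the integrator is
validated. The consistent energy functional is

    E = Tr(P H0) + 1/2 Σ_μ U_μ (P S)_μμ² + E_emb,

whose time derivative vanishes along exact trajectories; E_emb is the
constant interaction of the site nuclear charges with any embedding
charges.

Electrostatic embedding adds the one-electron potential
v_μ = −Σ_c q_c/|r_μ − R_c| (atomic units; electrons are attracted by
positive charges) to the diagonal of H0. Embedding charges closer than
1e-6 Å to a site are rejected rather than regularized.

Units: hartree, bohr and ħ = 1 internally; Å, fs/as and cm⁻¹ at every
user-facing surface. All conversion constants live in `constants.py`
(1 fs = 41.341374575751 a.u., 1 bohr = 0.529177210903 Å,
1 hartree = 219474.6313632 cm⁻¹); nothing else hard-codes a conversion.

## Ground state and excitation

The ground state is the self-consistent aufbau density of F(P): repeated
generalized diagonalization F C = S C ε with linear mixing (0.5) until
max|ΔP| < 1e-10, capped at 500 iterations. The returned density is the
pure aufbau density of the final Fock matrix, hence idempotent
(P S P = 2P). A HOMO–LUMO gap below 1e-8 hartree is an error naming the
degenerate pair — a silent tie-break would make downstream results depend
on eigensolver details.

Koopman excitations move occupation from an occupied reference MO to a
virtual one with no relaxation: `swap` exchanges the pair occupations
(2→0, 0→2), preserving idempotency; `single` moves one electron (2→1,
0→1). Both modes are provided because a restricted one-electron promotion
and a full pair swap are equally defensible readings of
occupation-adjusted state preparation; `swap` is the default since it
keeps the density a pure configuration. Note that under a *linear* F a
Koopman-excited density is diagonal in the eigenbasis and therefore
stationary; nontrivial Koopman dynamics requires U > 0. The analytic
two-level validations instead use a site-localized density
P = 2|site⟩⟨site| (a coherent superposition of the two eigenstates),
which beats with period 2πħ/ΔE under linear dynamics.

## Integrator

MMUT leapfrog: P(t_{k+1}) = U P(t_{k−1}) U†, U = exp(−2iΔt F(t_k)), with
F evaluated from the most recent density (no predictor-corrector). U is
built from the exact eigendecomposition of F — never a truncated series —
so each step is exactly unitary: electron count and the whole occupation
spectrum of P are invariants to round-off, which the Mulliken and
occupation analyses rely on. For a time-independent F the step is the
exact propagator; the scheme's Δt² error enters only through the midpoint
sampling of a density-dependent F.

Two stabilization details:

* **Bootstrap.** The two-point recursion needs a prior density; step 0→1
  uses a single half-window unitary exp(−iΔt F(t_{1/2})), where F at the
  half-window midpoint is estimated from an internal Δt/2 sub-step. The
  cheaper left-edge choice exp(−iΔt F(t_0)) works but leaves a one-time
  O(Δt²) energy offset roughly 3× larger on the reference fixture.
* **Periodic restart.** The bare leapfrog is unstable against odd-even
  parity separation when F depends on P: on the chain fixture at 1 as the
  energy error grows exponentially from ≈5000 steps and reaches 0.3
  hartree by 25 fs. Re-applying the bootstrap step every `restart_every`
  steps (default 10) suppresses the parity mode; restarts are exact (and
  thus inert) in the linear limit. With restarts the 25 fs / 1 as
  reference runs conserve energy to ≈4×10⁻⁸ hartree; the measured global
  error against a tight `solve_ivp` integration of the same equation
  drops 4.0× when Δt halves, confirming second order.

Propagation aborts (rather than warns) on electron-count drift above 1e-6
or non-finite densities. dt is accepted in as or fs with an explicit unit
tag and stored in fs; negative dt propagates backward (used by the
time-reversal test).

## Observables and conventions

Declared sign/geometry conventions, chosen once:

* Dipole: electrons negative, μ = −Tr(P d) + Σ Z_A r_A; nuclear term on by
  default so neutral symmetric systems give exactly zero. The origin is
  the coordinate origin; nothing recenters implicitly. Debye export
  multiplies by 2.541746473.
* Mulliken charge deviation Δq_F > 0 means electron depletion (hole-like),
  the chemical charge convention.
* Barycenters: r_hole is the Δq-weighted mean position over sites with
  Δq > 0, r_electron the |Δq|-weighted mean over Δq < 0. These weighted
  means are not given by any external convention; they are this package's
  declared definition — the simplest scale-invariant reading of a "charge
  depletion barycenter". Frames whose side weight falls below a threshold
  (default 1e-3 e) are marked invalid, never interpolated.
* RMS metrics: d_he = sqrt(⟨|r_hole − r_electron|²⟩) over jointly valid
  frames; speeds are RMS magnitudes of central-difference velocities
  (one-sided at the edges of each contiguous valid run), matching the
  integrator's second order. Whether "RMS velocity" should instead mean
  displacement-based speed is genuinely open; the central-difference
  definition is declared and tested against analytic sinusoid tracks
  (v_rms = Aω/√2 to within 1% at 1 as sampling).

## Correlation estimators

Input series are mean-subtracted over the full record once. Two
estimators serve two purposes:

* **Per-lag normalized** (maps, lag analysis):
  R(k) = Σ_overlap x̃ ỹ / sqrt(Σ_overlap x̃² · Σ_overlap ỹ²). The
  Cauchy-Schwarz inequality makes |R| ≤ 1 a theorem at every lag, which a
  fixed-denominator estimate with per-lag numerators does not guarantee.
  Lags are capped at half the record (default) to bound variance. The
  numerator uses an FFT correlation; equality with the direct O(N²)
  summation to 1e-10 is part of the acceptance suite.
* **Biased fixed-denominator** (spectra):
  R_b(k) = Σ x̃ ỹ / (n σ_x σ_y) over the *full* lag range |k| ≤ n−1. Its
  transform obeys S_xx(ν) = |X(ν)|²/(n²σ²) ≥ 0 at every frequency;
  truncated or per-lag-normalized autocorrelations do not (their
  truncation sidelobes go negative), which is why the spectrum path does
  not reuse the map estimator.

Cross-correlation maps store, for each unique pair, the signed R at the
lag maximizing |R|; ties break toward the smallest |lag|, then toward
negative lag. The zero-lag slice is kept alongside because in-phase /
antiphase structure is often read at τ = 0. The rendered heatmap is a
red-blue diverging scale on [−1, 1], upper triangle only.

Spectra are DFTs of the biased correlation with optional Hann window
(default none — raw peaks are the quantity of interest; Hann is for noisy
external data) and zero padding (default 4×, interpolating the grid). The
frequency axis is cm⁻¹; the physically attainable resolution is
ν_res = 1/(cT) — 1334 cm⁻¹ for a 25 fs record — and peak positions are
only trusted to one such bin regardless of padding. The unpadded,
unwindowed transform inverts back to the correlation exactly (1e-10).
Peak extraction takes local maxima of |S| ordered by magnitude, merging
peaks closer than a separation floor (default one resolution bin).

## Synthetic fixtures

The two fixtures encode the study scenarios the package is meant to
emulate, with the reference run conditions 25 fs at 1 as and a swap
excitation:

* `chain_dba` — 7 sites (donor 3 | bridge 1 | acceptor 3), spacing 2.5 Å.
  Donor block at 0, acceptor at 0.03, bridge at 0.10 hartree; intra-block
  couplings −0.08, donor-bridge −0.05, bridge-acceptor −0.04; U = 0.10 on
  the blocks and 0.02 on the bridge (a small moiety has a softer charging
  energy); 6 electrons. The photo-target orbital (LUMO+1) is
  bridge-centered, so the excited electron exchanges with both ends while
  the two channels — with different couplings and detunings — beat at
  distinct frequencies. This produces the signature pattern: donor/bridge
  and bridge/acceptor strongly anticorrelated (extremal R ≈ −0.91 / −0.55),
  donor/acceptor comparatively weak (≈ −0.40) — two carriers oscillating
  toward and away from the central bridge, unsynchronized with each other.
  U = 0.10 hartree, comparable to the couplings and frontier splittings,
  is stiff enough to be honestly nonlinear while a 1 as MMUT step holds
  energy to ≈4×10⁻⁸ hartree over the full 25 fs.
* `star_hub4` — a hub at −0.30 hartree with four 2-site arms at radius
  2.0 Å: two near-degenerate acceptor arms at 0.05 and 0.06 hartree (a
  deliberate 0.01 symmetry breaking) and two high-lying arms at 0.20;
  hub-arm couplings −0.06/−0.05; U = 0.10; 2 electrons. A HOMO→LUMO swap
  puts the electron ≈74% on arm1, which then migrates coherently to arm2
  (beat period 2π/0.01 a.u. ≈ 15 fs): the interligand-transfer scenario,
  with the arm1/arm2 map entry at ≈ −1.0.

Embedding variants: `point_charges` places a ring of alternating ±0.4 e
charges 4 Å outside the system (positions jittered by the seed at 0.01 Å);
`explicit_shell` appends weakly coupled (−0.02) high-lying (0.5 hartree)
quantum sites beyond each terminus as a coarse explicit environment
shell. Fixture generation is deterministic given (spec, seed); the
physics pipeline itself is seed-free.

What the fixtures do *not* emulate: real electronic structure (no
two-electron integrals, no exchange-correlation), nuclear motion (fixed
sites), decoherence or dissipation (closed-system unitary dynamics), and
the basis-set richness of molecular calculations (one orbital per site).
Passing tests therefore validate the *protocol* — integrator fidelity,
conservation laws, estimator correctness, end-to-end plumbing — not the
quantitative dynamics of any real molecule; molecule-specific numbers
require coupling the analysis side to an electronic-structure engine via
the trajectory container.

## Numerical details and edge cases

* Hermiticity tolerances: 1e-12 for model operators and Fock matrices,
  1e-10 for densities; a Fock asymmetry above 1e-10 aborts the step
  (fail, not symmetrize).
* Overlap square roots by eigendecomposition; non-positive-definite S is
  an error.
* Constant (zero-variance) series are rejected by the correlation
  estimators; per-lag windows with zero energy return R = 0.
* Round-off excursions of |R| past 1 are clipped to exactly 1.
* A flat spectrum yields an empty peak list, not an error.
* Barycenter metrics require ≥ 3 jointly valid frames.
* Trajectory grids must be strictly increasing and uniform to 1e-12 fs;
  the HDF5 reader re-checks this and reports the first missing dataset by
  name.

## Problem sizes

The reference simulations used throughout the tests and the acceptance
script are 25 000 steps on 7- and 9-site models (seconds on one CPU);
oracle comparisons (solve_ivp, direct O(N²) correlation) use 3-site
models, 2 fs horizons and series up to n = 2048, sizes at which the
oracles are themselves fast and trustworthy.
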