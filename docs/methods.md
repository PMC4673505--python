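# Methods

`overtone_sim` simulates direct excitation, spin echoes and PRESTO-II
polarization transfer on the ¹⁴N overtone (Δm = 2) transition of small
¹⁴N–¹H spin systems under magic-angle spinning (MAS).  This note records
the model, the conventions, the numerical design and its limits.

## The physical model

A spin system is a list of spins (one spin-1 ¹⁴N, observed; spin-1/2
neighbours) with

* Zeeman interaction of the ¹⁴N kept **in the laboratory frame** — there
  is no rotating frame that removes the time dependence of an overtone
  experiment, because the RF irradiation oscillates at twice the Larmor
  frequency while the internal Hamiltonian is diagonal-dominated by
  ω_Z S_z itself;
* full quadrupolar coupling `H_Q = Σ_k a_k T_{2,k}` with PAS components
  `a_0 = √6·2πC_Q/4`, `a_±2 = η·2πC_Q/4` for S = 1 (all five spherical
  components retained — the non-secular ones supply the Zeeman-state
  mixing that makes the overtone transition weakly allowed);
* secular chemical shielding of the ¹⁴N (isotropic shift plus the k = 0
  lab component of the Haeberlen anisotropy; non-secular shielding terms
  are ppm-scale against a 43 MHz Zeeman splitting and are dropped);
* heteronuclear dipolar coupling with the proton kept in the proton
  rotating frame: every term containing transverse proton operators
  averages at the proton Larmor frequency and is projected out, leaving
  `I_z ⊗ (any ¹⁴N operator)` — implemented as an exact average over
  proton z rotations;
* radiofrequency terms: the overtone channel is the lab-frame cosine
  `A·cos((2ω_Z+Δ)t+φ)(sinθ S_x + cosθ S_z)` with the coil angle θ
  defaulting to the magic angle (coil wound about the rotor axis), the
  proton channel an ordinary rotating-frame irradiation.

Euler angles are ZYZ, active; spatial tensors transform as
`a'_k = Σ_k' D²_{kk'} a_k'`.  The dipolar and shielding tensors of the
built-in systems are quoted relative to the ¹⁴N quadrupole eigenframe,
which serves as the molecular frame.  The first-order quadrupolar
splitting oracle (static, η = 0, PAS ∥ B₀ → single-quantum splitting
(3/2)·C_Q) pins the tensor normalization; only observable positions and
splittings are contractual, not internal conventions.

### RF amplitude convention

The "nominal RF amplitude" of an experiment is a calibrated *nutation
frequency* ν₁ measured on a single-quantum reference signal.  A linear
(cosine) field produces a resonant rotating component of half its peak
amplitude, so a calibration ν₁ corresponds to a transverse cosine
amplitude `γB₁sinθ = 2·(2πν₁)`; the longitudinal component follows from
the coil geometry (`cotθ` relative to the transverse part).  The proton
recoupling amplitude is derived from rotor synchronization (a π pulse must
fill one R element, ν₁ = N/(2nτ_r) = 89.3 kHz for R18 in two rotor periods
at 19.84 kHz spinning), which reproduces the printed experimental value.

### Sign and axis conventions

With ω_Z > 0 the second-order quadrupolar shift of the overtone transition
is positive, and the isotropic chemical shift enters with the usual sign
(+32.4 ppm appears at +32.4 ppm on the doubled-reference ppm axis).  The
rotor rotation sense relative to these conventions decides on which side
of the centerband the strongly excited overtone sidebands fall; it is
fixed so that the dominant excitation sideband is the one *above* the
centerband — the "+2" spinning sideband on which all experiments sit.
This sense is an observable-anchored convention: the overtone excitation
efficiency is strongly rotor-phase modulated, and its second harmonic
(4× stronger here than the mirror sideband) is what the experiments
exploit.

## Time-independent embeddings of the spinning problem

Spinning makes the Hamiltonian periodically time dependent through the
rotor phase.  Two embeddings remove that time dependence:

* **Floquet**: per crystallite orientation, states are expanded over rotor
  phase Fourier modes; the generator is block-Toeplitz in the Fourier index
  with the ladder `n·ω_MAS` on the diagonal and the rank-2 interaction
  components on the `|Δn| ≤ 2` blocks.  Dimension factor `2l+1` at cut-off
  rank `l`.  A uniform spinner-phase distribution is the `n = 0` block, so
  embedding and detecting there performs the spinner-phase (γ) average
  analytically; the two remaining powder angles run over a spherical
  quadrature grid.
* **Fokker–Planck**: the full sample orientation becomes an explicit
  coordinate expanded over Wigner functions up to rank `l` (dimension
  factor `(1+l)(1+2l)(3+2l)/3`); spinning is the static transport
  generator `ω_MAS(n·L)` about the magic-angle axis and the three-angle
  powder average is implicit.  The single rank here controls *both* the
  sideband space and the angular resolution of the implicit powder
  average, so desk-scale ranks correspond to coarse powder grids; full
  fixture-scale convergence of this picture is what requires the
  very large state spaces handled elsewhere with tensor-network
  machinery, which is out of scope here.  The package uses the
  Fokker–Planck path for free-evolution powder spectra as an independent
  cross-check of the Floquet path at matched angular resolution.

**Detection runs in Liouville space.**  This is essential, not cosmetic:
the first-order quadrupolar modulation (Fourier index of order
C_Q/ω_MAS ≈ 60 for glycine at 19.84 kHz) dresses the individual m = ±1
levels, but cancels structurally in the commutator acting on the overtone
|+1⟩⟨−1| coherence, whose residual modulation is second order
(≈ C_Q²/(ω_Z·ω_MAS) ≈ 1).  A cut-off rank of 5 therefore converges for
the detected overtone signal in the Liouville embedding, while any
expansion over Hilbert-space quasi-energies would need ranks of order
C_Q/ω_MAS.  Spectra are evaluated in the frequency domain through the
resolvent `S(ω) = ⟨⟨P| (r + i(F − ω))⁻¹ |ρ⟩⟩`: each frequency point is an
independent direct linear solve (never a matrix inverse); for the dense
Hermitian per-orientation generators the cached eigendecomposition
evaluates all points at once, and the two routes agree to solver
precision.  The uniform relaxation rate `r = π·lb` regularizes the
denominator and is the frequency-domain equivalent of apodizing the FID
to a Lorentzian of FWHM `lb`.

## Finite overtone pulses: exact lattice propagation

Overtone pulses are hundreds of microseconds long and can never be treated
as ideal.  The engine exploits two periodicities:

1. Over one RF period `T = 2π/(2ω_Z+Δ)` (≈ 11.5 ns) the propagator is a
   time-ordered product of sixteen midpoint slices (second-order product
   integral; sixteen slices reproduce a 256-slice reference to ~1e-5 at
   the overtone timescale).  The matrix-logarithm effective Hamiltonian
   over this period is exposed as `EffectivePulse`; the corresponding
   Magnus expansion does not converge for this problem and is deliberately
   not implemented.  Because the Zeeman eigenphases over one RF period sit
   at ±π *by construction*, the principal logarithm branch is ambiguous on
   exactly resonant overtone problems; the pipeline therefore amplifies
   the one-period propagator by repeated squaring/powering — exact for the
   integer-period durations used (durations are rounded to the nearest RF
   period, error ≤ T/2 ≈ 6 ns against pulses of 10⁵ periods), and
   branch-independent.
2. The spinning rate is snapped so that one rotor period contains an
   integer number Q of RF periods (an adjustment of at most a few Hz,
   orders of magnitude below any linewidth).  The pulse Hamiltonian is
   then exactly periodic on a lattice of Q RF periods.  The one-period
   propagators depend on rotor phase analytically through the rank-2
   components, with geometrically decaying phase harmonics (< 1e-13 by
   order ~10), so the full set of Q propagators is Fourier-interpolated
   from ~32 sampled phases, and a single prefix-product pass yields the
   time-ordered propagator between any two lattice points for any spinner
   phase.  A 700 µs pulse costs a handful of 6×6 multiplications per
   spinner-phase sample.

The result reproduces a brute-force laboratory-frame time-sliced oracle to
~1e-10 (same quadrature, verified in the tests), with *no* Fourier-rank
truncation in the pulse stage at all.  Free-evolution delays and
rotating-frame proton pulses use the same lattice with fewer slices per
period (their Hamiltonians carry no fast cosine).  Because every event
starts on an integer lattice index, the carrier phase at each pulse start
is automatically coherent and only programmed RF phases enter.

The spinner-phase average runs over `n_phase` (default 64) lattice start
indices; the detected γ-averaged observables converge at this count to
~1e-5 (checked against 1024 samples).

## Sequences

* **Direct excitation**: one overtone pulse, then frequency-domain
  acquisition.
* **Nutation**: sweep of the pulse width sharing all per-orientation
  lattice work; the reported amplitude is the peak height of the +2
  sideband (magnitude), matching how nutation data are read off spectra.
* **Spin echo**: 90 – τ₁ – 180 – τ₂ – acquire with both pulses propagated
  exactly; no phase correction is applied.
* **PRESTO-II**: proton R-block (N π pulses per n rotor periods, phases
  alternating ±πν/N, block phase 0) before the overtone 90, reconversion
  block (block phase 90°) after the overtone 180, then τ₂ and acquisition.
  Excitation and reconversion durations are equal and must be whole R
  cycles (enforced; the lattice is built so R elements are integer numbers
  of RF periods, making rotor synchronization exact).  A two-step phase
  cycle of the excitation block with receiver alternation removes the
  directly excited pathway; with the dipolar coupling set to zero the
  cycled signal cancels to machine precision.  `keep_direct=True` retains
  both pathways.
* **Orientation maps**: per-orientation peak heights and positions of any
  sequence, with the γ angle still averaged analytically.

The first-order selection rules of an `RN_n^ν` symmetry (`mn − μν = (N/2)Z`
with Z of the parity of λ) are enumerated exhaustively and checked against
an independent brute force; the R18 family used here — R18₂⁵ and R18₁⁷ —
recouples exactly the space-rank-2 / spin-rank-1 components
{l,m,λ,μ} = {2,±2,1,∓1}, i.e. CSA and heteronuclear dipolar terms, which
is what makes the ¹H→¹⁴N overtone transfer selective.  The digit grouping
of the printed symmetry labels is fixed by this physical contract: the
alternative readings recouple no dipolar term at all.

## Carrier placement

Experiments put the carrier "on resonance with the +2 spinning sideband".
The simulator reproduces the procedure: starting from the sphere-averaged
static overtone shift plus 2·ν_MAS, a coarse powder spectrum is simulated
and the carrier moved to its peak until self-consistent (two to four
passes).  The carrier matters twice — as the RF frequency inside the pulse
propagator and as the centre of the detection window.

## Acquisition decoupling

All reference experiments apply strong heteronuclear decoupling while the
FID is recorded.  The simulator emulates this as ideal decoupling: the N–H
dipolar coupling is removed from the *detection-stage* generator only
(`decouple_acquisition=True`, the default); the pulses always see the full
Hamiltonian.  Without it the glycine +2 sideband shows partially resolved internal
structure and quoted single-line widths are not comparable to experiment.
A pulse-sequence-level simulation of composite decoupling (SPINAL etc.)
is out of scope.  The nutation benchmark is the one place that runs with
the proton fully coupled in detection: it reproduces a reference
*simulation* of the curve that kept the proton coupled throughout (for
glycine the effect of decoupling is minor), and it is the coupled curve
that shows the measured π/2 and π conditions at 260 and 520 µs.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `rank` | 5 | Liouville-Floquet cut-off; glycine spectra change <1% from 5 to 7 |
| `grid_order` | 29 (reduced) | polar quadrature order; fixtures quote 77/131 for production |
| `n_alpha` | order+1 | azimuthal points; the two-spin systems are azimuthally band-limited, 18 points reproduce the NAV powder to <1% |
| `n_phase` | 64 | spinner-phase samples for the γ average |
| `n_slices` | 16 | slices per RF period in the pulse quadrature |
| `lb_hz` | 300 / 2000 | Lorentzian broadening (glycine / NAV) |
| `n_points`, `window_hz` | 256, ν_MAS/2 | detection window ("a few hundred points" in place of millions of time-domain samples) |

## What the model systems do and do not capture

The built-in systems are single ¹⁴N–¹H pairs: glycine's NH₃ rotation is
replaced by one effective coupling along the rotation axis (r = 1.28 Å),
NAV carries the full shielding tensor of a peptide-bond model.  Passing
benchmarks on them shows the spin dynamics of excitation, echo formation
and recoupling transfer is right; it does not probe multi-proton baths,
relaxation, RF inhomogeneity, probe backgrounds or dead-time effects, so
experimental *enhancement factors* (which fold in relaxation times and
calibration) are outside the simulated scope — line shapes, widths,
positions and nutation behaviour are the reproducible observables.

## Known limitations

* One spin-1 nucleus, spin-1/2 neighbours; no homonuclear ¹H–¹H couplings
  (each model system has a single proton).
* Relaxation enters only as the uniform detection-stage broadening.
* The Fokker–Planck path covers free evolution; pulsed sequences run on
  the Floquet path (a matrix logarithm of the ~10⁴-dimensional
  Fokker–Planck pulse propagator is not desk-scale).
* Desk-scale grids trade a few per cent of powder convergence for
  minutes-scale runtimes; production grid orders (77/131) are accepted by
  the same interfaces.
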