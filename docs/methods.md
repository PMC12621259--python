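# Methods

This note records the models, conventions and numerical choices behind
`fqdrop`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where the genuinely open design decisions
landed.

## Fluctuating-charge / fluctuating-dipole solvent response

Each solvent atom carries a charge determined by electronegativity
equalization under per-molecule total-charge constraints; in the FQFμ
variant it also carries an induced isotropic point dipole.  The state
(q, λ, μ) is the stationary point of the quadratic functional

E(q, λ, μ) = ½ q_λᵀ M q_λ + q_λᵀ C_Q + qᵀ V + qᵀ T^{qμ} μ + ½ μᵀ T^{μμ} μ − μᵀ E,

obtained from the symmetric block system

    [ T^{qq}  Λᵀ   T^{qμ} ] [q]   [ −χ − V ]
    [ Λ       0    0      ] [λ] = [    Q    ]
    [ T^{μq}  0    T^{μμ} ] [μ]   [    E    ]

with Λ the molecule-indicator matrix.  C_Q stacks χ on site rows and −Q on
constraint rows, so that λ-stationarity reproduces Λq = Q; the sign layout
follows directly from this stationarity derivation.  With dipoles disabled
the dipole blocks vanish and the classic FQ model is recovered exactly.

**Kernels.**  The diagonal of T^{qq} is the atomic hardness η; diagonal 3×3
blocks of T^{μμ} are (1/α)·I.  Off-diagonal interactions come in two
dialects:

- `bare_coulomb`: 1/r charge–charge, (r_i−r_j)/r³ charge–dipole,
  (I − 3r̂r̂ᵀ)/r³ dipole–dipole.
- `gaussian_smeared` (default): point multipoles are replaced by spherical
  Gaussians.  The charge width derives from η by requiring the isolated
  Gaussian self-energy √(2a/π) to equal η (so a = πη²/2); the dipole width
  uses the polarizability radius, σ = α^{1/3}.  Interactions become
  erf(βr)/r and its damped derivatives (damping factors
  g₁(x) = erf x − (2x/√π)e^{−x²},
  g₂(x) = erf x − (2x/√π)(1 + 2x²/3)e^{−x²}), approaching the bare forms at
  large separation.  Smearing regularizes close contacts in droplets cut
  from condensed-phase frames.

All intramolecular pairs interact through the kernel; only self-terms come
from η and α.  Internal units are atomic (bohr, hartree, e); every public
interface takes Å and converts through a single constants table.

**Stability.**  The functional is bounded below only while the combined
(T^{qq}, T^{qμ}, T^{μμ}) block operator is positive definite on the
constraint manifold.  Bare Coulomb kernels with large α at short contact
distances produce the classical polarization catastrophe — the functional
becomes unbounded and the "solution" of the linear system is a saddle.  The
smeared dialect pushes this boundary out substantially; the synthetic
parameter sets used in the test suite were verified (by direct eigenvalue
scan of the projected block operator over droplet batches) to lie in the
positive-definite regime for both dialects, so variational and
direct-minimization cross-checks are meaningful.

**Solving.**  One dense LU factorization after symmetric scaling of the
constraint rows/columns by 1/√(molecule size); iterative refinement until
the max-norm residual is ≤ 1e-10 (typically one pass reaches ~1e-15).  An
exactly singular or non-finite solve raises a conditioning error carrying a
condition-number estimate.  Molecule order is the order of first appearance
in the site list, everywhere.

**Mutual polarization.**  A polarizable solute stand-in (point charges +
static dipoles + isotropic polarizable sites) is coupled to the solvent by
damped block coordinate descent on the jointly quadratic coupled energy:
solvent solved exactly given the solute induced dipoles, then the induced
dipoles updated by a damped (factor 0.5, user-overridable) step toward
their exact conditional minimizer (a small dense solve that includes the
induced–induced coupling).  Because both half-steps descend the same
functional, the per-iteration energy trace is monotone non-increasing after
the first entry — which the tests assert — and the energy change between
iterations is the convergence criterion (default 1e-10 hartree).
Non-convergence raises an error carrying the full trace.

## Droplet protocol and trajectory descriptors

- **Droplet cutting**: center = solute geometric center (center of mass
  switchable); a water is retained iff its oxygen lies within the radius
  (closed ball: a molecule exactly on the boundary is kept), and molecules
  are always retained whole so hydrogen-bond partners stay intact.  Default
  radius 18 Å, the scale at which solute–solvent electrostatics are
  essentially converged for small solutes.  Snapshot decorrelation is a
  stride parameter (frames every ~10 ps in typical production data), not an
  autocorrelation test.
- **RDF/RCN**: pair histograms under orthorhombic minimum image; g(r)
  normalized by spherical-shell volume and the bulk density N_target/V from
  the box (or user-supplied when boxless).  Finite droplets are not valid
  RDF input — bulk normalization is undefined there.  The running
  coordination number is the cumulative mean neighbor count per reference
  atom.
- **Dihedrals**: four-point torsion with the IUPAC sign convention (verified
  against an independent formulation and against MDAnalysis), range
  (−180°, 180°]; frames with a degenerate central bond are skipped and
  logged per tuple.
- **Clustering**: GROMOS neighbor counting on mass-free optimally superposed
  RMSD (Kabsch via quaternion alignment), default threshold 0.11 nm.  Ties
  in neighbor count resolve to the earliest frame index, making memberships
  deterministic and order-stable.

GRO/PDB dialects are read through MDAnalysis with residues defining
molecules; the XYZ dialect is parsed in-package so molecule sidecar maps
and line-numbered parse errors are available, and plain O,H,H repetitions
are auto-grouped into waters.

## Stick spectra, broadening, convergence

Stick spectra (position, signed intensity) are broadened with unit-area
Gaussian or Lorentzian kernels of declared FWHM; defaults follow common
practice for aqueous spectra: Gaussian 0.5 eV for UV/ECD, Lorentzian
10 cm⁻¹ for IR/Raman/ROA.  Default grids: 150–350 nm at 0.5 nm (UV/ECD),
400–2000 cm⁻¹ at 1 cm⁻¹ (vibrational), 0–12 ppm at 0.001 ppm (NMR); all
overridable.  Both broadening and averaging are linear, so their order is
immaterial (tested to 1e-10).

A practical note on intensity conservation: the broadened integral equals
the summed stick intensity only over the kernel's effective support.  Eight
FWHM of padding suffices for Gaussians at 1e-6 relative, but Lorentzian
wings decay as 1/x² and a grid must reach ~10⁶ FWHM (the tests use a dense
core plus geometrically spaced tails) before truncation error falls below
1e-6.

**Convergence diagnostic.**  For snapshot counts n = inc, 2·inc, …, the
distance ‖S̄_n − S̄_{n−inc}‖₁ / ‖S̄_n‖₁ between successive running averages
is computed on the grid; the reported converged count is the first n whose
distance and the following one are both within tolerance.  The normalized
L1 metric is deliberately robust for sign-alternating spectra (ECD, ROA),
where positive and negative lines nearly cancel: the denominator shrinks
with the signal, so cancellation-dominated ensembles need more snapshots —
the signed-vs-unsigned comparison in the acceptance battery reproduces this
ordering on paired draws.

**Per-frame scalars** (e.g. optical rotation at the sodium D line, 589.3 nm,
in degree/(dm·g/cm³)) get exact running means, the standard error, a seeded
bootstrap percentile confidence interval, and the sign-consensus fraction —
the share of frames agreeing with the sign of the mean, a useful summary
when frame-to-frame values fluctuate across zero far beyond the ensemble
mean.

## NMR

Shieldings convert to shifts as δ = σ_ref − σ (TMS references: 31.7 ppm for
¹H, 182.852 ppm for ¹³C).  Coupled spectra come from the isotropic spin
Hamiltonian H = Σ ν_i I_{z,i} + Σ_{i<j} J_ij **I**_i·**I**_j with
ν_i = δ_i × spectrometer frequency (600 MHz default), built in the 2^N
product basis, block-diagonalized by total magnetization, and read out as
single-quantum transitions with intensities |⟨f|Σ I_{x,i}|s⟩|² (raw matrix
elements; the convention is recorded in the spectrum provenance).
Equivalent nuclei are not detected specially — equal shifts make their
mutual coupling invisible automatically.  The exact mode caps at 12 spins
(4096-dimensional space); beyond that a first-order multiplet construction
(successive ±J/2 doublet splitting) is provided, valid for Δν ≫ J.
Exchangeable protons (N–H) are excluded from coupled simulation via a
caller-supplied label list, mirroring how such spectra are compared with
aqueous experiments; nothing is hardcoded.

One dissonance is worth recording: a "0.002 eV" NMR linewidth, taken
literally through E = hν at 600 MHz, is ~8×10⁸ ppm.  The faithful
eV→Hz→ppm converter is provided (`fwhm_ev_to_ppm`), but the CLI default
linewidth is 0.01 ppm, a realistic solution linewidth.

Inter-model deviation statistics (per-nucleus |Δ|, max with argmax, mean)
operate on label-aligned tables; argmax ties resolve to the first label.
The bundled tryptophan dataset (ensemble-averaged shifts/shieldings from
two polarizable embedding models) yields max deviations of 0.3953 ppm (¹H,
at the pyrrole N–H), 7.0153 ppm (¹⁷O) and 2.1466 ppm (¹⁵N, pyrrolic N) —
these are properties of the bundled input table, recomputed, not asserted
constants.

## Partial Hessian vibrational analysis

Only active-region second derivatives enter: the 3N×3N block is extracted,
symmetrized as (H+Hᵀ)/2 (asymmetry beyond 1e-6 is a data-quality error),
mass-weighted, and diagonalized.  Projection removes the active region's
own rigid-body space (3 translations, plus up to 3 rotations built from the
geometry; 2 for linear fragments); because a frozen environment breaks
exact rotational invariance, residual near-zero modes among the remaining
spectrum are *labeled* (|ν̃| < 5 cm⁻¹) rather than deleted.  Negative
eigenvalues are reported as negative wavenumbers.  The conversion constant
√(hartree/(bohr²·amu)) / (2πc) = 5140.484678 cm⁻¹ is centralized to ten
significant digits.

Intensities: IR ∝ |∂μ/∂Q_k|²; Raman activity via the Placzek invariants
45a′² + 7γ′² from ∂α/∂Q_k, scaled by (ν̃₀ − ν̃_k)⁴ at the declared
excitation (634 nm default).  ROA enters only as externally supplied
per-mode sticks — the chiroptical response tensors are out of scope, and
pass-through is the honest boundary.

Partial optimization relaxes active coordinates by L-BFGS-B with frozen
atoms held bit-identical, exiting only when the active-gradient max-norm
meets the tolerance (non-convergence raises with the energy trace of
accepted evaluations).

## Synthetic data

Generators are pure functions of (seed, parameters); each draws from its
own named substream of the master seed so adding one generator never
perturbs another.

- **Water droplets**: rigid three-site geometry (O–H 0.9572 Å, H–O–H
  104.52°, the standard rigid-water values), uniform positions in a ball
  with a minimum O–O separation (default 2.5 Å, just under the liquid-water
  first-peak distance) and uniform random orientations; infeasible packings
  fail fast by volume check and bounded rejection.
- **Stick ensembles**: per-band normal draws of position and intensity per
  snapshot, emulating solvent-induced inhomogeneous broadening; the sign is
  applied after the draw so sign-flipped ensembles share draws exactly,
  enabling paired signed/unsigned comparisons.
- **Ball-and-spring systems**: harmonic bond networks with analytic
  Hessians (rest lengths default to current distances, making the input an
  exact minimum) and small random derivative tables.
- **Spin systems**: shifts uniform on a proton-like window; couplings drawn
  from geminal-like (17–19 Hz) and vicinal-like (4–12 Hz) ranges.

What the generators do *not* emulate: real force-field conformational
statistics, solvent structure (droplets are ideal-gas-like with a contact
exclusion, not hydrogen-bonded networks), anharmonicity, or any electronic
structure.  Green tests therefore certify the machinery — solvers, kernels,
conventions, statistics — on data with known structure; they do not certify
parametrizations against experiment.  The shipped water parameter set is
explicitly a placeholder for demos; every test uses synthetic parameters.

## Problem sizes in the verification batteries

The acceptance script and suite run: 10 droplet systems of 15 sites for the
solver-vs-minimizer check (tolerance 1e-8 hartree), 100 random droplets for
charge conservation (≤1e-12 e) and residuals (≤1e-10), 50 AB spin pairs
(line positions to 1e-9 Hz), 20 diatomics (1e-6 relative), paired
300-snapshot ensembles × 50 replicates for the signed-convergence
comparison, and 20 frames of 500 waters for droplet brute-force
equivalence.  These sizes make every check exhaustive at desk scale while
the full suite stays in the couple-of-minutes range.

## Known limitations

No nuclear gradients of the FQ(Fμ) energy, no periodic electrostatics
(droplets are finite clusters), no QM density coupling (the solute is a
classical stand-in), no relaxation/linewidth physics in NMR, no
anharmonicity or vibronic structure, no triclinic minimum image in the RDF,
and no attempt to reproduce any specific published spectrum — the package
is the protocol's classical machinery, not its quantum chemistry.
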