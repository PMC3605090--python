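# Methods

This note documents the models, conventions and numerical choices behind
landscape-bridge, and what the synthetic-data tests do and do not establish.

## Rigid-core identification

Per-residue rmsf is computed g_rmsf-style: every frame is superposed
(mass-unweighted Kabsch over heavy atoms; proper rotations only) onto the
*time-average* configuration of the alignment group, iterating the
average-and-realign step to a fixed point (tolerance 1e-10 Å, at most 10
rounds); per-atom rmsf is the RMS deviation from the mean position and the
residue value averages its heavy atoms.  A `reference="first"` flag switches
to first-frame alignment for comparison; the two differ negligibly for the
sub-Å cores the algorithm converges to.

Iterative exclusion walks the threshold schedule (default 5, 4, 3, 2, 1.5,
1 Å, strictly decreasing) and, at each threshold ε, repeats
{self-align on the surviving set → rmsf → remove all residues with
rmsf ≥ ε} until a pass removes nothing, then advances.  Choices worth
noting:

* **Batch removal** — all residues at or above ε go in one pass.  This makes
  the result deterministic and order-independent (verified by permutation
  tests); one-at-a-time removal would need a tie-break rule.
* **≥ vs >** — removal triggers at rmsf *equal to* ε, which makes the final
  guarantee strict: every member of the converged core has rmsf < 1 Å.
* **Alignment set** — each pass aligns on the *current* surviving set, so the
  reference frame tightens as mobile residues leave.
* The rmsf is recomputed after the final removal at each threshold before
  advancing, so the audit log always ends a threshold with a clean pass.
* Analysis window: the first 1000 ns at 1 ns sampling by default, clipped to
  what the trajectory provides (the clip is recorded in the result).

The algorithm terminates because every inner pass either removes a residue
(bounded by the candidate count) or advances the schedule.  It errors out if
the set empties or drops below 3 residues (superposition would be
degenerate) — that means no rigid core exists under the schedule.

## Rotation coordinates

Subunit rotation is read from *idealized* coordinates: the reference core is
rigidly least-squares fitted onto the frame's core atoms and the coordinate
is evaluated on the fitted copy.  This discards internal fluctuations, so
individual atomic noise enters the angle only through the 6-DOF fit (error
~ σ/(√N·R_g) radians for N core atoms of gyration radius R_g).  The axis is
defined by exhaustive search over P–P pairs of the moving core, scored by
direction change between the classical and rotated endpoint models after
(1) expressing both models in the fixed core's frame and (2) idealizing each
moving core; ties break toward the longer pair vector, then lexicographic
atom keys.  The plane normal is the unit cross product of the two
orientations of the winning vector; angles are measured by atan2 of the
in-plane projection against the classical orientation, counter-clockwise
positive viewed down the normal.  For the head swivel the fixed core is the
30S-body core (so body rotation and head swivel separate); for body rotation
it is the large-subunit core.

Diagnostic variants (`idealization="none"` and `idealization="group"`) read
the pair vector from raw atom positions or idealize over a wider residue
group; on synthetic data with mobile peripheries the idealized-core variant
has the smallest angle variance, which is the reason it is the default
estimator.

The tRNA-position coordinate ships as a configurable centroid–centroid
landmark distance.  The precise atom selections in the literature are
defined by citation chains rather than explicitly; the shipped preset is a
stand-in and should be overridden with the user's own definition.

## Effective diffusion

MSD(τ) averages over *all* overlapping frame pairs at each lag on the
series' native sampling grid.  D = slope/2 of an unweighted least-squares
line over [τ_min, τ_max] (weighting by pair counts is available behind a
flag but changes little, since errors across lags are strongly correlated).
Default burst cutoffs are 30 ns for rotation angles and 10 ns for the tRNA
coordinate; an automatic elbow detector is deliberately not applied
silently.  A linear correlation coefficient below 0.95 over the window
raises a warning flag (diffusive coordinates fit at ≈0.97–0.99).

The ballistic diagnostic fits MSD = aτ against MSD = aτ + bτ² and flags
non-diffusive behavior when the quadratic term removes > 50% of the residual
variance **and** is material, |b|·τ_max ≥ 0.2·a.  The magnitude condition
matters: MSD sampling noise is smooth in τ, so a free quadratic absorbs much
of the residual even for perfectly Brownian input, and the bare
variance-improvement rule would false-flag clean diffusive data.

Split-half analysis fits each contiguous half independently;
|ln(D₁/D₂)| k_BT is exactly the shift in barrier height that would be
inferred at fixed observed rate, because the rate enters as D·e^{−ΔF‡}.
Units are carried symbolically (degrees²/ns, Å²/ns); nothing assumes a
particular absolute scale of D.

Estimates from basin-confined series are biased low: as the fit window
approaches the basin relaxation time 1/(κD), the MSD saturates toward the
stationary variance.  The harmonic-well tests reproduce this directionally;
users should keep fit windows well below any apparent relaxation time.

## Free-energy profiles and rates

Profiles live on [0, L] with F(0) = F(L) = 0 and a single transition state
at x_ts with height ΔF‡ (all energies in k_BT; kcal/mol conversions use
k_BT = 0.596 kcal/mol at 300 K unless another temperature is given).  Two
families satisfy the constraints:

* `piecewise_parabola` (default): two inverted parabolic branches with
  per-branch widths x_ts and L − x_ts.  Endpoint approach has finite slope.
* `quartic_smooth`: per-branch double-well quartic
  ΔF‡·(1 − ((x − x_ts)/w)²)², stationary and twice differentiable at the
  endpoints — required for curvature-based (Kramers) rates.

**MFPT.**  Reflecting boundary at the starting minimum, absorbing at the
destination.  The double integral is integrated as the ODE system
Φ′ = e^{−F}, T′ = e^{F}Φ/D with an adaptive RK45 at rtol 1e-9, which handles
barriers past 50 k_BT and reduces to L²/2D on flat profiles to machine
precision.  The implementation is cross-validated three ways: a dense
trapezoid double-sum oracle (≤ 0.1% everywhere tested), closed forms, and
direct Euler–Maruyama first-passage ensembles (within statistical error at
barriers 2–4 k_BT).

**Kramers.**  k = (D/π)·sqrt(κ₀·κ‡)·e^{−ΔF‡} with curvatures read from the
profile family (one-sided at the cusp-like piecewise basins; geometric mean
of the branch curvatures at an asymmetric peak).  The prefactor is D/π, not
the textbook D/2π: with the starting minimum *on* the reflecting boundary
only half of the basin's Gaussian well is populated, which doubles the
escape rate.  Without this boundary factor the approximation converges to
half the quadrature rate instead of converging to it.  With it, the
deviation from the quadrature falls monotonically with barrier height
(≈27% → 11% over 5 → 14 k_BT on the quartic family); the residual is the
O(1/ΔF‡) anharmonicity of the quartic well and is irreducible within the
curvature approximation.

**Attempt frequency.**  ln(rate) is fitted with slope constrained to −1 over
a user-chosen barrier range (≥ 5 k_BT enforced), giving
ν = exp(mean(ln k + ΔF‡)).  For these profile families the curvatures scale
with ΔF‡, so ν drifts algebraically (~ΔF‡ on the quartic family, ~ΔF‡^{3/2}
on the piecewise family) rather than being strictly constant; the residual
RMS is reported and flagged above 0.2 ln-units.

**Barrier inversion.**  Bisection (Brent) on the strictly decreasing
barrier → rate map, bracket [0, 50] k_BT auto-expanding, relative tolerance
1e-6.  Observed rates at or above the flat-landscape rate 2D/L² return
barrier 0 with a "no barrier required" flag.  When the observed rate is that
of a full multi-step process, the inverted value is an upper bound for every
substep.

**Peak-position robustness.**  `robustness_scan` reports two numbers, and
they answer different questions.  The max/min ratio of forward rates across
peak positions is large (→ 4 between peaks at 0.2L and 0.8L at high
barrier) because the escape attempt rate from the starting basin scales as
1/x_ts in these families — this is real, Langevin-verified physics, not
quadrature error.  The robustness statement that matters for barrier
inference is the shift relative to the symmetric-peak form used for the
headline rate curves: max |ln(rate/rate_sym)| = ln(0.5L/0.2L) ≈ 0.92 k_BT
< 1 k_BT, i.e. not knowing where the transition state sits perturbs an
inferred barrier by under 1 k_BT.

## Synthetic generators

The assembly generator emulates exactly the features the analysis relies
on: internally rigid domains (per-axis Gaussian jitter about a rigid
reference, sub-Å by default), a prescribed relative rotation path about a
known axis, and untethered Gaussian-random-walk peripheral residues whose
rmsf grows without bound (guaranteeing clean separation from cores).  Each
residue carries a P and a C1′ atom so residue averaging and P-pair searches
are exercised.  It makes **no** attempt to mimic rRNA geometry, sequence,
secondary structure, tethered-loop dynamics, solvent, or force-field
physics; passing tests establish the correctness of the estimators on data
matching their assumptions, not the biological conclusions drawn from any
particular trajectory.

The Langevin generator is plain Euler–Maruyama,
x ← x − D F′(x) dt + sqrt(2D dt)·η, with F in k_BT (mobility = D) and
reflecting walls at the domain edges.  A step guard rejects dt unless the
deterministic drift per step is below 10% of the thermal step,
D·max|F′|·dt < 0.1·sqrt(2D dt); the max is taken over the whole domain, so
steep confining wells force conservative steps.  Higher-order integrators
were deliberately not used — at the enforced step size the Euler bias is far
below the statistical tolerances asserted anywhere, and the scheme is
trivial to oracle.  Generators are deterministic per seed (byte-for-byte for
PDB text) and return ground truth alongside the data.

## Problem sizes

Tests and the acceptance script run at desk scale by design: assemblies of
60–200 residues over 30–200 frames, Brownian series of 1e5 points,
first-passage ensembles of 500 walkers, 20-seed repetition for stochastic
claims.  These sizes were chosen so every statistical tolerance has
comfortable margin under the Monte-Carlo oracles used to calibrate it.  The
candidate-set bookkeeping is nevertheless exercised at full rRNA scale
(complete 2903- and 1542-residue chains) where the computation is exact
counting.

## Known limitations

* Constant D along each coordinate; no coordinate-dependent D(x) in the
  MFPT integral, and no quasi-harmonic diffusion estimator.
* One-dimensional, single-barrier landscapes only; no committor or
  Markov-state validation of the coordinates.
* PDB reading rejects alternate locations beyond the first and does not
  handle insertion codes; no PDB writing of modified experimental
  structures (only synthetic fixtures are written).
* Core identification is tested on rRNA-like (nucleotide-named) synthetic
  residues; nothing restricts it to RNA, but protein use is untested.
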