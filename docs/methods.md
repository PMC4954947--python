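# Methods

## Scope and conventions

`msmbind` estimates binding thermodynamics (ΔG°) and kinetics (kon,
koff, mean first passage times, committors) of a ligand against a
receptor from many short, independent trajectories, using a reversible
Markov state model built on a TICA/k-centers discretization of binary
contact-map features.  Units are fixed throughout: lengths in Å, times
in ns (converted to seconds only in rate outputs), energies in kcal/mol,
concentrations in mol/L, temperature in K.

All matrices use the **row convention**: `K[i, j]` is the transition
rate from state i to state j (rows of K sum to zero), and
`T(Δt) = expm(K Δt)` has `T[i, j] = p(j, Δt | i, 0)`.  Master-equation
literature often writes the transpose (column) convention; one
convention everywhere keeps the linear algebra and the serialized
artifacts unambiguous.

## Featurization

A trajectory bundle declares receptor reference atoms (typically
alpha-carbons), per-ligand atom groups, optional free ions, and the
frame spacing.  Because ligand copies in one box interact with the
receptor essentially independently (direct ligand–ligand contacts are
transient at mM concentrations), each (run, ligand copy) pair is
treated as its own trajectory; a box with five copies yields five
trajectories.  Features are binary contacts: receptor atom *p* is "in
contact" in a frame iff its minimum distance to any ligand atom is
*strictly* below the cutoff (default 8 Å).  A boolean coordination flag
marks frames in which any ligand phosphate atom is strictly within 4 Å
of any declared ion.  Both cutoffs use strict `<`.  Distances are plain
Euclidean by default; an explicit minimum-image mode handles periodic
cubic boxes.  No alignment or superposition is performed — contact maps
are invariant to rigid-body motion by construction.

## TICA

The slow order parameters solve `C(τ) v = λ C(0) v` with mean-free
covariances pooled over all (t, t+τ) pairs of all trajectories and a
**symmetrized** time-lagged covariance
`C(τ) = ½⟨x_t x_{t+τ}ᵀ + x_{t+τ} x_tᵀ⟩`.  Symmetrization guarantees a
real spectrum at finite sampling.  Binary contact columns are often
collinear or constant, so: constant columns are dropped (recorded in
the model so transforms stay consistent) and `C(0)` receives a ridge
`ε = 1e-6 · trace(C(0))/F`.  Components are normalized in the `C(0)`
metric (unit instantaneous variance of each projection); eigenvalue
(kinetic-map) rescaling is available behind a flag but off by default,
as plain eigenvector projection is what the downstream k-centers step
assumes.  The lag must be an integer multiple of the frame spacing —
no interpolation, for bit-reproducibility.  Default lag 2 ns; default
dimension 3 for single-ion analyses and 5 for substrate-pathway
analyses (the projection dimension is a required choice, not inferred).

Observation noise attenuates TICA eigenvalues by the signal-variance
fraction of the slow coordinate; eigenvalues therefore approximate the
underlying λ₂(Δt) only when state separation is large against noise
(see "Synthetic benchmarks").

## Discretization

k-centers uses the Gonzalez (farthest-point) rule: the first center is
a seeded uniform draw from the pooled frames; each next center is the
frame farthest from its nearest existing center.  This covers rare but
kinetically important regions (intermediates, bound pose) with few
centers, at the cost of sensitivity to outliers — acceptable here
because contact/TICA space is bounded.  Assignment is nearest-center by
Euclidean distance with ties to the lowest center index.  The covering
radius is reported; it is non-increasing in k.

After geometric clustering, every cluster observed with both values of
the coordination flag is split in two (`n_final = k + #mixed`); splits
are based on observed flag values only, so empty microstates are never
created.  Splitting happens before transition counting, so the MSM sees
coordination changes as state transitions even when the geometry barely
moves.

## MSM estimation

Transition counts use a sliding window at lag Δt, never across
trajectory boundaries; sliding counting maximizes data use and is the
standard companion of likelihood estimation.  Estimation is restricted
to the largest strongly connected component of the count graph (ties:
larger total counts, then lowest index); frames outside it are excluded
from population sums.

The transition matrix maximizes `Σ C_ij log T_ij` subject to detailed
balance, via the classic fixed-point iteration on symmetric auxiliary
variables `x_ij`:

    x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),   T_ij = x_ij / x_i

iterated until the maximum relative change is below 1e-12 (cap 10⁶
sweeps; in practice convergence takes tens of sweeps).  π is read off
as `x_i / Σx`.  The tests pin this estimator to an independent
penalized-likelihood optimization within 1e-8.

Implied timescales are `τ_s = −Δt / ln λ_s` for eigenvalues in (0, 1);
λ within 1e-12 of 1 reports ∞, non-positive λ reports NaN (no
relaxation-time meaning).  `lag_scan` re-counts and re-estimates per
lag on the common active set and suggests the smallest lag whose
slowest timescale changes by <10% to the next lag — the usual
"timescales stop depending on the lag" criterion.  The appropriate lag
is data-set specific and remains a required configuration value.

## Macrostates and binding kinetics

PCCA+ builds fuzzy memberships from the top-M right eigenvectors by the
inner-simplex construction (M maximally spread microstates as simplex
vertices; coordinates of all microstates expressed in that vertex
basis; small negative round-off clipped and rows renormalized).  Crisp
assignment is maximal membership with ties to the lower macrostate
index.  Bulk is the macrostate with the smallest stationary-weighted
mean contact count, bound the largest; equality is reported as a
degenerate system rather than silently labelled.

Macro-MFPTs solve `m = Δt·1 + T_restricted m` with m = 0 on the target
microstates; the source value is averaged with the stationary
distribution restricted to (and renormalized over) the source — the
equilibrium-weighted entry point, with uniform weighting available by
flag.  Committors solve the harmonic boundary-value problem in `T`.

Rates: the on-MFPT is a single-ligand quantity, so the pseudo-first-
order rate 1/MFPT_on divides by the single-copy box concentration
(`n/(N_A V)`) to give the bimolecular kon; koff = 1/MFPT_off; and
ΔG° = RT ln(koff/(kon·C°)) at C° = 1 M, R = 1.9872×10⁻³ kcal/(mol·K),
default T = 298 K.  A population route
(`Kd = (π_unbound/π_bound)·C_sim`) is computed alongside as an internal
consistency check; for a two-state model the two routes agree exactly
by detailed balance, and on the synthetic benchmark they agree to
better than 0.1 kcal/mol.  Helper conversions cover frequency-based
on-rates (events/μs ÷ concentration), Kd-based free energies and
turnover times (1/rate).  The reciprocal relation is applied as stated;
a pseudo-first-order inverse of an on-rate of 1.85×10⁵ M⁻¹s⁻¹ at 1 mM
is 5.4 ms, whatever a back-of-envelope round-off may suggest.

## Bootstrap errors

Each of 7 independent runs drops ⌊0.2·N⌋ trajectories (seeded draw
without replacement, independent across runs), then re-runs clustering
(k-centers with a run-specific seed), MSM estimation and kinetics with
the same hyper-parameters.  The reported uncertainty is the sample
standard deviation over runs — labelled sd, not SEM.  Runs that lose
ergodicity are skipped with a warning and reported in
`n_effective_runs`.  Fixed seeds reproduce partitions and errors
bit-identically.

## Synthetic benchmarks

`sample_ctmc_trajectories` draws exact Gillespie jump sequences of a
rate matrix and records them on the frame grid; this is the exact law
of the discretized process, with no integrator error.  Initial states
are stationary draws by default (so occupancy estimates are unbiased);
binding-time experiments can start all trajectories in bulk, analogous
to placing free ligands away from the protein.  `embed_states` maps
states to centroids plus isotropic Gaussian noise.  Shipped presets:

- **twostate** — symmetric slow exchange (rates 0.05/ns, frame 0.1 ns);
  the sign of TICA component 1 must separate the states.
- **binding5** — five states: a dominant bulk state (π ≈ 0.50, dwell
  10 ns), an off-pathway interface state exchanging only with bulk, two
  short-lived on-pathway intermediates, and a long-lived bound state
  (π ≈ 0.41, dwell 33 ns).  The topology is a tree, so detailed balance
  holds by construction.  Analytic values at these rates: MFPT
  bulk→bound 114 ns, bound→bulk 86.8 ns, τ₂ ≈ 47.8 ns at a 2 ns lag.
  The box volume encodes a 12 mM single-ligand concentration, matching
  substrate-scale conditions.  Centroids are contact-map-like (bulk at
  the origin, bound largest in total magnitude) so the bulk/bound
  labelling rule applies unchanged.
- **metastable-blocks** — two weakly connected 3-state blocks for
  lumping tests; PCCA+ must recover the blocks exactly.

Embedding separation is a design rule, not an accident: centroid
pairs sit ≈9σ apart (minimum distance 4.74 at noise 0.5).  Per-frame
misassignment probability p enters the estimated slow eigenvalue
roughly as λ₂(1−2p), and because τ = −Δt/ln λ, even p ≈ 1% halves an
estimated 48 ns timescale at a 1 ns lag.  At ~9σ separation p is
negligible (<1e-5) and the end-to-end pipeline recovers kon and koff
within a few percent at 200 × 5000-frame sampling (tolerances in the
tests are 25% for rates, 0.3 kcal/mol for ΔG°, 15% for τ₂).

The Brownian generator integrates overdamped dynamics
`x ← x + √(2DΔt)·ξ + (DΔt/k_BT)·F(x)` in a reflecting box with a
flat-bottom spherical well whose wall is a cosine ramp over the outer
20% of the radius (continuous forces).  Construction rejects time steps
whose RMS displacement exceeds a quarter of the well radius.

What the synthetic data does *not* emulate: conformational plasticity
of the receptor, ligand–ligand interactions and ion bridging, adaptive
(non-equilibrium) seeding of trajectories, force-field error, and
genuinely high-dimensional feature spaces with correlated noise.
Passing the synthetic suite therefore demonstrates correctness of the
estimators and the pipeline plumbing — not that any specific MD data
set is Markovian at the chosen lag, which must still be checked with
the implied-timescale scan on the data itself.

## Problem sizes used in the shipped checks

The recovery benchmark runs 200 trajectories × 5000 frames (0.1 ns
spacing; 100 μs aggregate), clustered at k = 50, MSM lag 2 ns, 5
macrostates — large enough that statistical error sits well inside the
stated tolerances, small enough to run in seconds.  The bootstrap
scaling check compares 40 against 160 trajectories at 20 bootstrap
runs.  Monte-Carlo cross-checks use 1e4 Gillespie first-passage runs
(continuous time) and 1e5 chain runs (discrete time) against 99%
confidence intervals.

## Known limitations

- PCCA+ memberships use the inner-simplex construction without the
  subsequent constrained optimization step; for well-separated
  metastable systems (the intended regime) crisp assignments are
  identical, but memberships for heavily overlapping spectra may be
  cruder than optimized PCCA+.
- k-centers is outlier-seeking by design; with heavy-tailed noise the
  covering structure can waste centers on stray frames.
- The MFPT-based kon assumes the bulk macrostate is a well-mixed
  reservoir; strongly diffusion-limited systems with spatial structure
  in bulk violate this.
- `lag_scan`'s 10% flatness rule is a heuristic; at lags far beyond
  the slowest timescale the eigenvalue estimate degenerates (reported
  as NaN) and no suggestion is made.
- Uncertainty is trajectory-bootstrap only; no Bayesian posterior over
  transition matrices.
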