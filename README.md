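# msmbind

Markov state model (MSM) reconstruction of ligand-binding thermodynamics
and kinetics from ensembles of short molecular-dynamics trajectories.

## The problem

Modern binding studies of systems such as myo-inositol monophosphatase
(IMPase) and its Mg²⁺ cofactors do not run one long simulation; they run
thousands of short, independent trajectories in which free ligands
diffuse, form encounter complexes and eventually reach the bound pose.
No single trajectory samples the full binding/unbinding equilibrium.
An MSM stitches the swarm together: conformational space is discretized
into microstates, transitions are counted at a lag time Δt, and the
equilibrium populations and slow kinetics of the whole process are
obtained from the resulting transition matrix.  `msmbind` packages that
entire analysis chain for practitioners who have (a) trajectory bundles
with a receptor and one or more ligand copies per box, or (b) no data at
all and want a fully verifiable synthetic benchmark.

## The model

The continuous-time dynamics are a master equation dP/dt = P K (row
convention: `K[i, j]` is the rate i→j, rows sum to zero), with
transition matrix `T(Δt) = expm(K Δt)` so that `T[i, j]` is the
probability of state j at lag Δt given state i.  The estimation chain:

1. **Featurization** — each (run, ligand copy) pair is an independent
   trajectory; frames become binary receptor–ligand contact maps (atom
   in contact iff distance < 8 Å), optionally refined by an
   ion-coordination flag (phosphate–ion distance < 4 Å).
2. **TICA** — generalized eigenproblem `C(τ) v = λ C(0) v` with
   symmetrized time-lagged covariance pools all trajectories and
   projects onto the slowest linear order parameters.
3. **k-centers** — Gonzalez farthest-point discretization of the
   projected data; clusters observed with both coordination-flag values
   are split in two.
4. **Reversible MSM** — sliding-window counts on the largest strongly
   connected state set; maximum-likelihood transition matrix under
   detailed balance π_i T_ij = π_j T_ji; validation by implied
   timescales τ_s = −Δt/ln λ_s across a ladder of lags.
5. **Macrostates and rates** — PCCA+ lumps microstates into a few
   metastable macrostates; the bulk (fewest contacts) and bound (most
   contacts) macrostates anchor mean first passage times, which convert
   to rate constants and a standard free energy:

       kon  = 1 / (MFPT_on · C_sim)          [1/(M·s)]
       koff = 1 / MFPT_off                    [1/s]
       ΔG°  = RT ln( koff / (kon · C°) ),     C° = 1 M

6. **Bootstrap** — errors come from 7 independent re-analyses, each
   dropping 20% of the trajectories and re-clustering.

The synthetic module generates exact Gillespie trajectories of known
rate matrices embedded in feature space (plus Brownian ligand-in-a-box
simulations), with analytic stationary vectors, transition matrices and
MFPTs, so every stage above is testable against ground truth.

## Worked example

```python
import numpy as np
from msmbind import PipelineConfig, analyze_trajectories
from msmbind.synthetic import preset, sample_ctmc_trajectories, embed_states

system = preset("binding5")         # bulk / interface / 2 intermediates / bound
dtrajs = sample_ctmc_trajectories(system, n_traj=100, n_frames=2000, seed=1)
seeds = np.random.SeedSequence(2).spawn(len(dtrajs))
ftrajs = [embed_states(d, system.embedding,
                       seed=int(np.random.default_rng(s).integers(2**31 - 1)),
                       frame_dt=system.frame_dt)
          for d, s in zip(dtrajs, seeds)]

config = PipelineConfig(tica_lag=2.0, tica_dim=3, n_clusters=50, msm_lag=2.0,
                        n_macrostates=5, concentration=system.concentration, seed=1)
obs = analyze_trajectories(ftrajs, config)["observables"]
print(f"kon  = {obs['kon_M_s']:.2e} /M/s")
print(f"koff = {obs['koff_s']:.2e} /s")
print(f"dG0  = {obs['dG0_kcal_mol']:.2f} kcal/mol")
print(f"tau2 = {obs['tau2_ns']:.1f} ns")
```

prints

```
kon  = 7.25e+08 /M/s
koff = 1.20e+07 /s
dG0  = -2.43 kcal/mol
tau2 = 47.3 ns
```

against the analytic ground truth of the generating rate matrix
(kon 7.31e8, koff 1.15e7, ΔG° −2.46 kcal/mol, τ₂ 47.8 ns): the pipeline
recovers the bimolecular on-rate at the 12 mM single-ligand box
concentration, the dissociation rate of the long-lived bound state, the
standard free energy from the rate ratio, and the slowest relaxation
time, all within a few percent at this sampling size.

The same chain runs from the shell:

```
msmbind run --preset binding5 --seed 1 --out report/
msmbind run --bundle my_bundle/ --n-clusters 925 --msm-lag-ns 20 --out report/
```

producing `features/`, `tica/`, `clusters/`, `msm/`, `kinetics/` and
`bootstrap/` artifacts plus a human-readable summary, every file stamped
with the config hash and seed.

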