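# unbind

Tools for deciding which step of an enzymatic cycle is rate-limiting from
simulation data, built around the m6A RNA methyltransferase problem: a
catalytic heterodimer binds a methyl donor (SAM) and an adenosine
substrate, transfers a methyl group, and must then release the products.
`unbind` quantifies the two candidate bottlenecks independently:

* **ligand residence times** from ensembles of independent MD runs —
  heavy-atom contact maps, a percentile-based binding-pocket definition,
  first-passage dissociation times, survival-curve exponential fits with
  combinatorial block averaging, and conversions to `koff`, `Kd`, mean
  lifetime and the Eyring activation free energy;
* **the chemical barrier** from well-tempered multiple-walker
  metadynamics — HILLS parsing, walker merging, final-bias PMF
  reconstruction `F(ξ) = −γ/(γ−1)·V(ξ)` along the antisymmetric
  methyl-transfer stretch `ξ = r(CE−SD) − r(CE−N6)`, convergence traces
  and replica averaging with SEM;

plus **near-attack-conformation geometry** of static structures (Kabsch
superposition, N6–Cε distance, 5'S–Cε–N6 angle, SN2-compatibility flags)
and a **synthetic-data module** that generates every input with known
ground truth, so the whole chain is testable without cluster resources.

## The model

Dissociation of a ligand from an ensemble of `n` independent runs of
length `T` is treated as a single-exponential first-passage process. The
fraction of still-bound trajectories is fitted with

    S(t) = exp(−t/τ)        (model A)
    S(t) = A·exp(−t/τ)      (model B; A ≈ 1 indicates a good fit)

with never-dissociating runs counted as bound through the horizon. The
uncertainty comes from enumerating all C(n, n/2) half-ensembles (12 870
for n = 16), fitting each, and reporting the mean ± SD of the block
estimates. Rates follow as `koff = 1/τ`, `Kd = koff/kon` with a
diffusion-limited `kon = 1e9 /M/s` by default, and
`ΔG‡ = RT·ln(kB·T/(h·koff))`.

## Worked example

Sixteen synthetic 500 ns trajectories with a true mean lifetime of
150 ns, analysed end to end:

```python
import unbind as ub

params = ub.TwoStateParams(koff_true_per_ns=1/150, seed=0)
real = ub.simulate_two_state(params)
bound = [ub.classify_bound(d, threshold_A=10.0, frame_interval_ns=params.dt_ns)
         for d in real.distances_A]
res = ub.DissociationKinetics.from_bound_series(bound).fit(model="A")
print(res.summary())
```

```
Dissociation kinetics (single-exponential survival fit)
==========================================================
trajectories                    16   (censored: 1)
horizon                      500.0 ns
model                            A
tau (all runs)                 195 ns
pre-exponential A                1
block size                       8   (12870 subsets, 0 skipped)
tau (block mean)             201.9 ns
tau SD                       63.26 ns
----------------------------------------------------------
koff                     4.954e+06 1/s
Kd (kon=1e+09/M/s)       4.954 mM
mean lifetime            2.019e-07 s
Eyring dG' (T=300 K)     8.375 kcal/mol
```

The block-averaged lifetime (201.9 ± 63.3 ns) covers the 150 ns truth;
the conversions show what such a lifetime implies at a diffusion-limited
on-rate. The same objects convert measured rates directly, e.g.
`ub.lifetime_from_koff(2e-4)/60 → 83.3 min`, and
`ub.eyring_barrier(0.6/60, 300) → 20.3 kcal/mol` for a slow enzymatic
turnover — an order of magnitude above a typical computed methyl-transfer
barrier, which is what makes product release, not chemistry, the
bottleneck candidate.

The metadynamics side mirrors a production protocol (bias factor 35,
0.3 kJ/mol hills of width 0.05 every 0.2 ps, 24 walkers sharing history
every 1 ps):

```python
import numpy as np
from unbind import metad

run = ub.simulate_wtmetad(ub.WTMetadParams(barrier_kcal=4.0, seed=1))
prof = metad.pmf(run.merged_hills(), np.linspace(-1.6, 1.6, 601), gamma=35.0)
barrier, dg = metad.barrier_and_dg(prof, (-1.4, -0.6), (0.6, 1.4))
# barrier ≈ 4.19 kcal/mol, dg ≈ 0.23 kcal/mol on the 4 kcal/mol double well
```

A `unbind` command-line tool wraps the same functions
(`unbind simulate ...`, `unbind kinetics fit/convert`,
`unbind fes reconstruct`, `unbind geometry`, `unbind run-all`).

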