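# Methods

## Scope and model

`unbind` analyses ligand dissociation kinetics from ensembles of
independent, equal-length MD trajectories and reconstructs 1-D free-energy
profiles from well-tempered multiple-walker metadynamics. The underlying
kinetic model is a two-state first-passage picture: a ligand is bound
until it first leaves the binding pocket, dissociation times are
exponentially distributed with rate `koff = 1/τ`, and re-entries after the
first crossing are not credited (they are observable separately through
the contact time series). This matches how residence times are usually
extracted from swarms of unbiased trajectories: the quantity of interest
is the first dissociation per run, with runs that never dissociate
right-censored at the common horizon.

## Contacts and pocket definition

Contacts are intermolecular heavy-atom (element ≠ H) pairs at distance
strictly below a cutoff (default 5 Å). Per-residue contact counts are
averaged over all frames of all runs of a condition; the binding pocket is
the set of residues whose mean contact count reaches the 90th percentile
(linear interpolation) of the mean counts. Two conventions needed fixing:

* the percentile is computed over residues with a *nonzero* mean contact,
  and membership uses `≥` rather than `>` — a strict inequality on a
  single contacting residue would yield an empty pocket;
* the ligand-to-pocket distance is, per pocket residue, the minimum
  heavy-atom distance from that residue to any ligand heavy atom, averaged
  over pocket residues. Minimum-atom distance is the standard contact
  metric; centre-of-mass and Cα variants would be straightforward but are
  not implemented.

A frame is unbound when this mean pocket distance surpasses 10 Å
(bound ⇔ d ≤ 10). The alternative bound criterion — adenosine N6 to
D395-Cγ below 6 Å, strict — is available through the same classifier.
Inputs must be pre-imaged (ligand and residues whole); `check_imaged`
rejects trajectories in which any heavy atom of a multi-atom residue has
no neighbour within 3 Å, the signature of a residue split across the
periodic box. Salt-bridge/H-bond monitoring uses a 4.0 Å heavy-atom
formation cutoff by default (configurable per pair); these cutoffs are
conventions of the field rather than measured quantities.

## Survival fitting and block averaging

The fit target is the empirical fraction-bound curve, evaluated on a
**uniform** time grid over the common horizon (256 points by default).
This matters: evaluating the step function only at event times
concentrates fit weight in the event-dense early decay and biases τ low
by ~10% under censoring at ~3τ, while the uniform grid — the natural
sampling of a per-frame bound fraction — is unbiased to within sampling
error (verified on 300 synthetic ensembles). Model A is `exp(−t/τ)`;
model B adds a free pre-exponential as a fit-quality diagnostic. The
nonlinear least squares is a bounded 1-D minimisation in τ (model B:
2-parameter trust-region), initialised from the time at which the curve
first drops below 1/e, falling back to half the horizon — a deterministic
start with no random restarts.

Uncertainty uses combinatorial block averaging: all C(n, n/2)
half-ensembles (12 870 for n = 16) are enumerated, each block's survival
curve fitted, and the mean ± SD of the block estimates reported. Blocks
with no dissociation events cannot be fitted; they are skipped and
counted. Complementary subsets are kept as distinct draws, preserving the
full 12 870 count. The interpretation "fit each enumerated half-ensemble,
then average" was chosen over a paired two-block statistic; the subset
enumeration is exposed so other poolings can be built on top.

Censored runs count as bound through the horizon with no Kaplan–Meier
re-weighting — with a fixed common horizon the naive estimator is exact.
If every trajectory is censored, fitting raises a dedicated error rather
than returning a number; the lifetime is then only bounded from below.

## Conversions

`koff = 1/τ`, `Kd = koff/kon` with `kon = 1e9 /M/s` by default
(diffusion-limited association), mean lifetime `1/koff`, and the Eyring
relation `ΔG‡ = RT·ln(kB·T/(h·k))` with transmission coefficient 1.
Constants: R = 1.98720425e−3 kcal/(mol·K), kB = 1.380649e−23 J/K,
h = 6.62607015e−34 J·s; the default temperature is 300 K ("ambient").
The barrier→rate→barrier round trip is exact to 1e−10 relative.

## Metadynamics reconstruction

HILLS files are PLUMED-style text with a `#! FIELDS` header; `time` and
`height` are required by name, any `sigma*` column supplies the width, and
the remaining (second) field is the CV centre. Deposited heights are
assumed already tempered — the common convention for written HILLS — and
heights stay in kJ/mol until the final profile (kcal = kJ/4.184).
Walkers merge by a stable time sort with ties broken by walker index.

The estimator is the final-bias formula `F = −(γ/(γ−1))·V` on a grid,
min-shifted to zero; `γ = ∞` gives the untempered `F = −V` for runs that
were not well tempered. No time-dependent (Tiwary–Parrinello) reweighting
is applied: convergence is assessed exactly as the protocol states, by
recomputing the profile as a function of the number of Gaussians added
and tracking the maximum deviation from the final profile. Replica
averaging re-anchors each profile's reactant-basin minimum at zero before
taking the pointwise mean and SEM (`sd/√n`); anchoring at the reactant
minimum is the least-assumption alignment when the original analysis does
not state one. Barrier extraction takes the highest grid point between
the two window minima; halving the grid spacing moves the barrier by
< 0.05 kcal/mol on smooth profiles. Everything is 1-D, matching the
antisymmetric-stretch CV `ξ = r(CE−SD) − r(CE−N6)`.

## Synthetic generators

*Two-state trajectories.* Jump times are drawn i.i.d. from
Exp(`koff_true`); frames record the state at the end of each interval
(`dt`, `2dt`, …), so an arbitrarily fast rate leaves every recorded frame
unbound. Bound-state distances are Gaussian about 4 Å (sd 0.8, clipped at
0), unbound about 20 Å (sd 1.5) — a stationary fluctuation model with the
bound band more than 3 sd clear of the 10 Å threshold, so threshold
crossings are driven by the jump, not the noise. The unbound state is
absorbing by default (first-passage analysis); an optional rebinding rate
adds re-entries for testing the no-rebinding-credit rule. Defaults are
the study design: 16 runs × 500 ns, frames every 0.5 ns.

*Coordinate ensembles.* A rigid three-residue pocket cradles a two-atom
ligand within contact range; at the jump time the ligand is displaced by
15 Å. Pocket atoms jitter with sd 0.1 Å, ligand atoms 0.3 Å. There is no
force-field realism, no solvent, and no internal protein motion — these
fixtures exercise the contacts→kinetics chain, not MD physics, so passing
tests demonstrate correct bookkeeping and estimation, not that real
trajectories are two-state.

*Metadynamics.* Overdamped Langevin (Euler–Maruyama) on the quartic
double well `V(x) = B((x/a)² − 1)²` (default B = 4 kcal/mol, a = 1), with
kBT at 300 K, diffusion coefficient 0.1 CV²/ps and a 0.004 ps step —
small enough that the deterministic drift stays below the hill width
everywhere on the deposition grid (a warning fires otherwise). The
deposition protocol matches production settings: hills every 0.2 ps,
initial height 0.3 kJ/mol tempered by `exp(−V_bias/(kB·T(γ−1)))` with
γ = 35, width 0.05, 24 walkers × 250 ps sharing hill history every 1 ps
(each walker always sees its own hills immediately). The bias and its
gradient are accumulated on a 1601-point grid over ±1.8·a and
interpolated linearly, which keeps per-step cost constant. At the
default length (30 000 hills) the reconstructed barrier lands within
±15% of the analytic 4 kcal/mol and the reaction free energy within
±0.5 kcal/mol across seeds.

*Toy structures.* Written as minimal PDB with coordinates rounded to the
format's 3-decimal precision, so a write→read round trip is exact; the
reader re-rounds the parser's float32 output to 3 decimals for the same
reason.

## Geometry

PDB reading uses Biopython's parser; alternate locations resolve to the
highest occupancy (alphabetic altloc on ties), waters and hydrogens are
retained (hydrogens flagged). Superposition is Kabsch via rotation
alignment with the RMSD computed from the actually-applied transform;
collinear or <3-pair selections are rejected as underdetermined. The NAC
table reports the N6–Cε distance and the 5'S–Cε–N6 angle per complex and
flags SN2-compatible geometry at distance ≤ 3.5 Å and angle ≥ 150°
(configurable); in bisubstrate analogues the donor "sulphur" position is
a nitrogen, so atom specs accept either name. Fetching structures by
accession is network-gated and off by default; analyses of deposited
structures run only on locally supplied files.

## Problem sizes and determinism

Synthetic checks use the study-design sizes where those are the point
(16 × 500 ns ensembles; 24 walkers × 250 ps) and small fixtures
elsewhere. The acceptance script's parameter-recovery block runs 20
replicates of the full design; every random draw in the package goes
through `numpy` Generators seeded from explicit parameters, and
identical seeds give byte-identical outputs.

## Known limitations

* Single-exponential kinetics only; multi-exponential or stretched decays,
  Kaplan–Meier estimation and Bayesian rate inference are out of scope.
* The block-averaged SD measures within-ensemble spread of half-ensemble
  fits, not the full across-ensemble sampling error; coverage of the true
  lifetime at ±2 SD is ~90% in the tested design, not guaranteed.
* The final-bias PMF estimator ignores the time-dependent offset of
  well-tempered metadynamics; for the deposition protocol used the
  residual non-uniformity is well inside the reported tolerance, but very
  short runs are better served by reweighting estimators.
* 1-D CVs only; no periodic CVs.
* No periodic-boundary handling in the contact module beyond the
  broken-residue check; trajectories must be imaged beforehand.
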