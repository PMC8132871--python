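# Methods

## The method in brief

A conformation of a molecule with D dihedral angles is represented as the
2D-vector x = (cos θ₁, sin θ₁, …, cos θ_D, sin θ_D); the doubled encoding
removes the 2π seam that raw angles would put through any smooth model.
An encoder network maps x to the mean μ and log-variance ln σ² of a
k-dimensional diagonal Gaussian; a mirrored decoder reconstructs x from a
reparameterized sample z = μ + σ ⊙ ε.  After training, each conformation
owns a latent distribution, and the closed-form KL divergence between
diagonal Gaussians measures how novel the current conformation is relative
to the archive of saved frames.  The biasing potential
V_bias = (V_KL_upper / V_KL)² is added to the physical energy: essentially
zero while V_KL ≫ V_KL_upper, steeply repulsive as the system re-approaches
a visited state.  Biased trajectories are reweighted to the canonical
ensemble with per-frame weights ∝ exp(+V_bias/k_BT).

## Architecture and training

* Encoder: N fully connected hidden layers (PReLU activations, one learned
  slope per layer, initialized at 0.25); layer n has ⌊2D/n⌋ nodes.  Two
  linear heads of size k = ⌊2D/(N+1)⌋ emit μ and ln σ².  The decoder
  mirrors the encoder (layers m = N…1 of ⌊2D/m⌋ nodes) and ends in a
  linear output of size 2D.  N defaults to 7; for very low-dimensional toy
  systems N must shrink so that no width floors to zero (the config
  validator enforces this), and the 1-D double-well experiments use N = 1.
  Both encoder and decoder widths use the 2D numerator: with a D/n encoder
  the deepest hidden layer would be *narrower* than the latent layer,
  contradicting the mirror-image construction, so the self-consistent 2D/n
  form is used throughout.
* Loss: loss_model = (1−w)·loss_mse + w·loss_kl with w = 0.1.  Both terms
  are per-sample sums averaged over the batch: loss_mse sums squared
  reconstruction errors over the 2D features, loss_kl = ½ Σᵢ (σᵢ² + μᵢ² −
  ln σᵢ² − 1) sums over the k latent dimensions.  The sum convention is
  load-bearing, not cosmetic: it keeps the reconstruction term O(2D) so
  that with w = 0.1 reconstruction dominates.  Averaging the
  reconstruction error per element instead makes posterior collapse
  (μ → 0, σ² → 1, decoder ignores z) the *optimum* on well-separated
  two-basin data — we verified this directly — and no training schedule
  rescues it.
* Optimizer: Adam with decoupled weight decay (lr 1e-4, betas 0.9/0.999,
  weight decay 0.01 on weight matrices only), batch size 512, up to 5000
  epochs with 50 equally spaced milestones each multiplying the learning
  rate by 0.99, early stopping after 250 non-improving epochs with the
  best parameters restored.  The recorded per-epoch loss is the running
  training loss (mean of batch losses); an optional validation split
  (`validation_fraction`) switches early stopping to a held-out metric.
  All stochasticity (initialization, shuffling, reparameterization noise)
  flows from explicitly seeded generators.
* Everything is numpy with hand-written backpropagation.  The same
  backward pass, applied to the encoder with respect to its *inputs*,
  yields the exact bias force (below); finite-difference checks at
  h = 1e-5 agree to better than 1e-5 relative error.

## Biasing

V_KL is computed between the current frame's latent Gaussian and each of
K = 32 representatives drawn uniformly without replacement from the frame
pool at every bias update, then reduced:

* `min` (default): the bias reacts to the *nearest* visited region — the
  behavior that actively steers away from re-sampling.  The gradient
  follows the argmin branch (first index on ties).
* `mean`: a smooth, bounded alternative (see Reweighting).

A frame that was appended to the pool at the current step is excluded
from the draw: the KL of a conformation from itself is identically zero
and carries no novelty information, but under min-aggregation it would
floor V_KL and spuriously cap the bias.

Numerical guards: V_KL is floored at 1e-12 and V_bias capped at 1e6; in
either regime the potential is treated as locally constant and the force
is zero.  V_KL_upper defaults to 1e-5 and is the aggressiveness dial —
larger values mean the bias engages at larger divergences.  Setting it to
0 disables biasing entirely; a disabled run is bit-identical to plain
unbiased dynamics under the same seed (this is a regression test).  In
the toy backend energies are in units of k_BT (k_BT = 1); adapters for
real engines must declare their energy unit.

The force on the dihedral coordinates is the exact gradient of the chain
angles → (cos, sin) → encoder → V_KL → V_bias.  The toy backend's
coordinates are the dihedrals themselves, so this force enters the
integrator directly; how a real engine maps generalized dihedral forces
onto Cartesian atomic forces is deliberately left on the engine side of
the adapter contract.

## Sampling loop

Counters obey n_biasing ≪ n_saving ≪ n_short ≪ n_needed, "≪" meaning a
factor ≥ 10, with the divisibility needed to align block, saving and
retraining boundaries.  Documented production-scale defaults are
1e9 / 1e7 / 1e4 / 50 with retraining every n_saving·100 steps; desk-scale
runs in the tests use 50 000 / 5 000 / 500 / 50.  The loop: (1) n_short
unbiased steps, saving every n_saving into the pool; (2) initial training
on the pool; (3) while n_completed < n_needed: encode the current frame,
aggregate V_KL over fresh representatives, hold the resulting force fixed
for an n_biasing block, record (step, V_KL, V_bias), append frames at the
saving cadence, and every retrain_every steps continue training the
existing model (200-epoch budget per round) on a uniformly drawn pool
subset (≤ 50 000 frames), refreshing every cached latent afterwards.
Checkpoints written at retraining boundaries allow bit-identical resume;
all random streams (dynamics noise, model init, training shuffles,
representative draws, subset draws) are spawned from one run seed.

## Toy dynamics

Overdamped (first-order) Euler–Maruyama Langevin dynamics on the flat
torus: θ ← wrap(θ + (−∇U + F_extra)·dt/γ + √(2·k_BT·dt/γ)·ξ), defaults
dt = 0.01, γ = 1, k_BT = 1.  First-order dynamics was chosen over a
thermostatted second-order integrator because the enhanced-sampling logic
is integrator-agnostic and the overdamped form gives the cleanest
stationary-distribution test: a 1e6-step run on the 2 k_BT double well
U = (h/2)(1 − cos 2(θ−c)) reproduces the quadrature Boltzmann histogram
to L1 ≈ 0.02–0.03 (36 bins).  A guard dt·max|∇U|/γ < 0.5 rejects
configurations where the discrete step could hop across the torus.

## Reweighting and its limits

Weights w_i ∝ exp(+V_bias,i/k_BT) (max-subtracted before exponentiation),
with each saved frame inheriting the V_bias of the block active at its
step — half-open [start, start+n_biasing) blocks, bootstrap frames get 0,
and the final frame of a run, which lands on the closing edge of the last
block, inherits that block's value.  PMFs are weighted histograms with
F = −k_BT ln p shifted to min 0; unvisited bins are reported as unvisited
(NaN free energy), never as 0 or ∞.  The printed form of the reweighting
relation in the source literature carries a negative β and a stray
exponent index; the standard canonical-ensemble convention implemented
here is the only one under which a run biased by an exactly known static
potential recovers its Boltzmann distribution, which is the test we use.

Two approximations matter.  First, the instantaneous-bias estimator is
exact only for a static bias; during the loop the bias evolves, so the
estimator carries the usual adiabatic assumption.  Second — and specific
to this bias form — V_bias is *unbounded* as V_KL → 0, so under
min-aggregation single frames that closely re-approach a visited state
can acquire weights exp(V/k_BT) that dominate the entire histogram, and
the importance-sampling estimator does not converge.  This is a genuine
limitation of inverse-square KL biasing (contrast metadynamics, whose
Gaussians are bounded by construction).  Consequently the quantitative
reweighting validation uses (a) an exactly known static flattening bias
and (b) a desk-scale loop run with `aggregation="mean"`, whose bias is
bounded; both recover the reference PMF within 0.2 k_BT on occupied bins.
Min-aggregated runs are for exploration; their reweighted histograms
should be treated as qualitative.

## Synthetic data

The two-basin generator emulates the statistical structure the method
assumes: a hidden Markov chain over B Ramachandran-like basins
(stay-probability 0.995) with, per dihedral, von Mises noise (κ = 20,
≈13° spread) around the basin center — helix-like (−60°, −45°) and
sheet-like (−120°, +130°) values alternating across dimensions.  von
Mises noise was chosen over wrapped normal for its exact circular support
and standard concentration parameter.  Dimensions are independent given
the basin; real dihedral couplings, kinetic correlations within basins,
and gradual (non-Markov) transitions are *not* modeled, so passing tests
demonstrate correct mechanics and learnability of metastable structure,
not performance on real molecular data.

## Analysis conventions

Dihedral PCA operates on mean-centered, unscaled cos/sin features (they
are already bounded); component signs are fixed by making each
component's largest-magnitude entry positive.  Radius of gyration is
mass-weighted; RMSD superposition is mass-unweighted Kabsch over all
supplied atoms (callers select subsets upstream).  χ₁ is taken for every
residue that has one (heavy-atom fourth-neighbor table; Gly/Ala have
none); missing atoms skip the affected dihedral with a logged warning
rather than failing, since experimental structures routinely have gaps.
Dihedral signs follow the IUPAC convention (verified against mdtraj),
under which reversing the atom quadruple *preserves* the signed angle.

## Problem sizes used in the shipped experiments

Desk-scale counters (50 000 total steps, 8 k_BT barrier, 5 seeds) for the
enhanced-sampling comparison; 1e6 integrator steps for stationary-
distribution and reweighting checks; D = 10, T = 5000 for the
representation-learning fixture.  These sizes give comfortably resolved
statistics for every asserted tolerance while keeping the full suite in
the minutes range on one CPU.

## Known limitations

* Reweighting of min-aggregated runs is qualitative (see above).
* The VAE retrains from the current parameters with a fresh optimizer
  state each round; no replay balancing between old and new pool regions.
* The toy backend is 1–2 dimensional in practice; nothing prevents higher
  D, but the shipped potentials are separable cosine wells.
* No multi-walker variant; no second-order/thermostatted integrator.
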