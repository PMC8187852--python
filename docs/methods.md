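# Methods

This note documents the models implemented in `mmkit`, the choices behind
their default parameters, the problem sizes used by the test suite and the
acceptance script, and what the toy setting does and does not establish.

## Toy systems and integrator

All potentials are analytic, with energies in kT (kT = 1 internally; a
physical-units mode expresses hill heights in kJ/mol at 340 K for parity
with typical biomolecular settings).  The multi-well form is a
log-sum-exp Gaussian mixture

    U(x) = -log Σ_k exp( D_k - |x - c_k|² / (2 w_k²) ),

chosen because the Boltzmann factor is then exactly a sum of Gaussian
bumps: well k carries mass e^{D_k}(2πw_k²)^{dim/2}, so target state
populations convert to depths in closed form
(D_k = log p_k - (dim/2) log 2πw_k²) and depth perturbations shift
population ratios exactly (the toy analogue of switching force fields).
State populations, marginal free-energy profiles and ensemble averages are
computed by midpoint-rule quadrature on a rectangle covering all wells
± 6 widths (neglected tail mass < e^{-18} per well; default 4000 nodes per
axis in 1D, 500 in 2D — node spacing well below well widths, and tests that
compare against binned profiles align nodes with bin edges to avoid
histogram aliasing).

Dynamics are overdamped (Brownian) Langevin,
x' = x - (Δt/γ)∇U + sqrt(2kTΔt/γ)ξ — the simplest ergodic sampler for these
landscapes.  The default scheme is first-order, so its stationary density
carries an O(k·Δt) bias where k is the local curvature.  This constrains
the toy geometry: the log-sum-exp barrier top has curvature ≈ 2·(barrier)/w²,
so wells are made wide and well-separated (double well at ±2, w ≈ 0.48;
two-state system at ±1.2, w = 0.45; three-well system with widths
0.45–0.62), keeping k·Δt ≲ 0.15 everywhere at the default Δt of
0.002–0.004.  A predictor-corrector (Heun) variant of the same update —
drift averaged between the current and predicted point, same noise — is
available (``IntegratorConfig(scheme="heun")``); its density bias is second
order, which permits much larger time steps when total simulated time, not
step count, limits accuracy (free-energy recovery uses it; see below).

The default three-state system mirrors a small fast-folding peptide near
its melting temperature: folded (55%), misfolded (15%) and unfolded (30%)
basins, an RMSD-like distance from the folded minimum partitioning the
states (thresholds 1.5 and 3.6, half-open intervals with boundary frames
assigned to the lower state), and a size CV s(x) rising from ≈1.0 (folded)
to ≈1.8 (unfolded) — roughly the compaction contrast between native and
expanded ensembles.  Synthetic scattering targets are Guinier-like
intensities f_q = exp(-q²s²/3) on 24 equally spaced angles between 0.01 and
1.39 (inverse length), a deliberately wide range so high-angle points carry
state contrast.  The Guinier stand-in preserves the size sensitivity of
small-angle scattering but none of its atomistic structure (no form
factors, no solvent layer); conclusions about forward-model quality do not
transfer.

## Metadynamics

Well-tempered heights h = h₀ exp(-V(s)/((γ-1)kT)) with γ = 10 and pace
200–250 steps; defaults in configs mirror common biomolecular practice
(γ = 10, h₀ = 0.5 kJ/mol in physical mode, 10 walkers).  Gaussian widths
are fixed per CV (roughly a third of a well width; configs take PLUMED-like
per-CV minima) rather than dynamically adapted — fixed widths keep the bias
transparent and reproducible on analytic landscapes.  Parallel-bias
deposition multiplies the well-tempered height by the softmax share
exp(-V_i/kT)/Σ_j exp(-V_j/kT), which sums to one across CVs.

The bias lives on regular grids (~8 nodes per Gaussian width): values and
analytic gradients are accumulated at the nodes per hill (hills truncated
beyond 7σ, < e^{-24.5}), and evaluation interpolates both linearly.  Grids
are exact at the nodes; between nodes the error is quadratic in the node
spacing — about 0.2% of a hill height for values, and up to a few percent
of the peak gradient for forces, which perturbs the sampled distribution
far less than the hill deposition noise itself.  Walkers advance
synchronously; at a deposition step all walkers deposit in ascending index
order on one shared clock.

Reweighting uses the final bias only, w_i ∝ exp(V_final(s_i)/kT), with no
time-dependent offset correction; analyses discard an initial 20–25% of
each walker's frames, during which the growing bias makes the
constant-bias assumption worst.

## CV combination

ψ(a) is minimized on the unit sphere (Σa_i² = 1, first nonzero weight
positive) via multi-start Nelder–Mead — the objective is smooth except at
the max/min width-ratio switch, which a simplex method crosses without
trouble; starts are the uniform vector plus seeded random directions.
0·ln 0 := 0 in the entropy term.  Per-state CV variance uses the full
covariance aᵀCa, so correlated inputs are handled.  For more than two
states the discrimination and width-ratio terms are summed over unordered
state pairs with a single entropy term — the simplest symmetric extension.

## Metainference

The Gaussian-noise restraint is implemented exactly as written above
(`mmkit.metainference.mi_energy`), with:

* λ = 1 fixed by default (sampling it is supported in the energy but not
  exercised: it is an optional scaling and the reference workflow does not
  use it);
* E_σ = (kT/2)Σ log 2π(σ_B²+σ_SEM²) + kT Σ log σ_B — Gaussian-likelihood
  normalization plus a Jeffreys prior p(σ_B) ∝ 1/σ_B (switchable);
* σ_B sampled per (replica, datum) by symmetric-proposal Metropolis within
  (σ_min, σ_SEM√NR], σ_min = 10⁻⁶|d_i|; one vectorized site sweep per
  restraint step (sites are conditionally independent given ⟨f⟩);
* the cap σ_SEM·√NR: read as converting a standard error of the mean back
  to a single-replica error scale;
* replica weights from a moving average of the bias over the AVERAGING
  window (default = deposition pace), held constant when differentiating
  the restraint (on-the-fly approximation); σ_SEM reported as its maximum
  over the same window;
* restraints applied every 2 MD steps (the stride between force refreshes).

NR_eff - 1 in the σ_SEM denominator is floored at 10⁻³ as a run-time guard:
with very few effective replicas σ_SEM then blows up (a huge, honest error
bar) instead of dividing by zero; a run aborts only if NR_eff ≤ 1 persists
over a full window.  The mean relative error reported for a run averages
σ_SEM/d over data points and over the final quarter of the diagnostics
history, so single-window spikes do not dominate.

## Error analysis

Weighted block errors use contiguous equal-frame blocks (remainder merged
into the last block), raw weight sums per block, and the effective block
number NB_eff = (ΣW_b)²/ΣW_b² in place of NB — with unbalanced block
weights NB would underestimate the error, which the tests demonstrate.
Per-bin FES errors propagate the block error of the bin indicator as
kT·err_p/p_b.  Replicate (triplicate) averages work on the probability
scale: F̄_b = -kT log p̄_b and err = kT σ_p/(p̄_b √n).  Transition counting
uses the extreme states of the partition with an intermediate buffer:
excursions into the middle state neither count nor reset; uncertainties are
Poisson (√count), a pragmatic choice since the counts are small.
R-factors average |I-I_ref|/I_ref uniformly over data points.

## Problem sizes

The default study sizes (used by tests and `scripts/acceptance.py`) are
chosen so each experiment resolves its target effect comfortably on a
single core: free-energy recovery uses one walker for 2·10⁶ steps
(Δt = 0.012 under the Heun scheme — the error of the reweighted profile is
governed by the number of independent traversals of the flattened
landscape, so simulated time is maximized at fixed step count; several
thousand barrier crossings result); triplicate population runs use
3 × 4 walkers × 1.5·10⁵ steps (Δt = 0.003); metainference correction runs
use 10–16 replicas × 2·10⁵ steps (Δt = 0.004); the parallel-bias vs joint
comparison uses 8 seed pairs of 4 walkers × 5·10⁴ steps.

## Limitations

* The toy landscape has no solvent, no inertia and no rough intra-state
  structure, so NF_eff fractions are far higher than atomistic practice;
  only orderings and formula behavior transfer, not magnitudes.
* First-order Langevin stepping leaves a small O(Δt) density bias; the
  geometries above keep it ≪ statistical errors, but very sharp custom
  potentials would need a smaller Δt.
* The σ_B Metropolis step size is fixed (a tenth of the allowed range);
  acceptance rates are logged but not auto-tuned.
* Parallel-bias deposition assumes the biased CVs are weakly coupled
  one-dimensional coordinates; no joint adaptivity, bias exchange or
  transition-tempered variants are provided.
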