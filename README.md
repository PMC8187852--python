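# mmkit

Toy-model toolkit for **metadynamics–metainference (M&M)** methodology:
enhanced sampling with well-tempered and parallel-bias metadynamics,
Bayesian integration of (synthetic) experimental data over weighted
replicas, and the statistics needed to judge both — weighted block-average
errors, effective sample sizes and replica-number diagnostics.

## Who this is for

Simulators who combine metadynamics with ensemble restraints face two
coupled questions: *how precise* are populations and free energies estimated
from a reweighted biased trajectory, and *how many replicas* does a
replica-averaged restraint need before it stops distorting the ensemble?
Answering them on an atomistic system is expensive and confounded.  `mmkit`
reproduces the full methodology on analytic multi-well "folders" (Brownian
dynamics on 1D/2D landscapes with folded/misfolded/unfolded analogues and a
Guinier-like intensity standing in for SAXS), where exact quadrature answers
exist for every quantity, so every formula and every diagnostic can be
validated end to end.

## The models

**Sampling.** Overdamped Langevin dynamics on
U(x) = −log Σ_k exp(D_k − |x−c_k|²/2w_k²) (energies in kT).  Well-tempered
metadynamics deposits Gaussians of height h = h₀ exp(−V(s)/((γ−1)kT));
parallel-bias metadynamics keeps one 1D bias per CV, combined as
V_PB(s) = −kT log Σ_i exp(−V_i(s_i)/kT) with softmax-partitioned hill
heights.  Multiple walkers share one bias.  Frames are reweighted with the
final bias, w_i ∝ exp(V_final(s_i)/kT).

**CV combination.** A discriminating collective variable
CV(a, φ) = Σ a_i φ_i (Σ a_i² = 1) is fit to labeled states by minimizing

ψ(a) = −(⟨CV₁⟩−⟨CV₂⟩)²/(σ²₁+σ²₂) + max(σ₁,σ₂)/min(σ₁,σ₂) + Σ a_i² ln(a_i²N)

(discrimination + comparable widths + weight uniformity).

**Metainference.** Gaussian-noise ensemble restraint over NR replicas,

E_MI = E_FF + (kT/2) Σ_i Σ_r (d_i − λ⟨f_i(X)⟩)² / ((σ^B_{r,i})² + (σ^SEM_i)²) + E_σ,

with replica weights w_r ∝ exp(V̄_G/kT) (moving-average bias), weighted
replica averages ⟨f_i⟩, σ^SEM the weighted standard error of the mean
(window-maximized), Monte-Carlo-sampled σ^B capped at σ^SEM·√NR, and the
diagnostics NR_eff = (Σw)²/Σw² and the relative error 100·σ^SEM/d_i.

**Statistics.** Weighted block averages with the effective block number
NB_eff = (ΣW_b)²/ΣW_b², free-energy profiles F_b = −kT log p_b with block
errors, NF_eff, transition counts, triplicate averaging with
err(F̄_b) = kT σ_p/(p̄_b √n), and the R-factor = mean |I−I_ref|/I_ref × 100.

## Worked example

```python
import numpy as np
import mmkit
from mmkit.metad import MetaDConfig, run_metad, default_grid_range
from mmkit.dynamics import IntegratorConfig
from mmkit.potentials import analytic_marginal_fes
from mmkit.stats import weighted_fes

dw = mmkit.double_well_1d()               # symmetric, 8 kT barrier
x = dw.cv("x")
lo, hi = default_grid_range(dw.spec, x)
cfg = MetaDConfig(cvs=(x,), sigma=(0.2,), grid_min=(lo,), grid_max=(hi,),
                  mode="joint", height=0.2, pace=30, biasfactor=10.0)
integ = IntegratorConfig(dt=0.012, n_steps=500_000, seed=1, save_stride=20,
                         scheme="heun")
run = run_metad(dw.spec, cfg, integ, n_walkers=1)

w = run.frame_weights(discard_frac=0.25)
fes = weighted_fes(run.cv_series()[:, 0][w > 0], w[w > 0],
                   np.linspace(-3.2, 3.2, 49), n_blocks=10)
truth = analytic_marginal_fes(dw.spec, x, fes.edges)
mask = truth.free_energy < 5.0
print(f"NF_eff fraction: {run.nf_eff_fraction(0.25):.2f}")
print(f"max |F - F_exact| on bins below 5 kT: "
      f"{np.nanmax(np.abs(fes.free_energy - truth.free_energy)[mask]):.2f} kT")
```

prints (seed 1):

```
NF_eff fraction: 0.48
max |F - F_exact| on bins below 5 kT: 0.37 kT
```

i.e. the well-tempered bias lets a single walker cross the 8 kT barrier
repeatedly, final-bias reweighting recovers the exact profile to a fraction
of kT, and the reweighting costs roughly half of the frames' statistical
power (NF_eff < NF) — the trade-off at the heart of coupling metadynamics
with replica-averaged restraints.

A command-line surface wraps the same pipeline:

```bash
mmkit simulate -c config.yaml -o out/          # (PB)MetaD walkers
mmkit optimize-cv --state f=STATE_F.dat --state u=STATE_U.dat -o out/
mmkit mm-run -c config.yaml -o out/            # restrained M&M
mmkit analyze out/colvar.*.dat --cv dist --bias-col metad.bias ... -o out/
mmkit report --diagnostics out/diagnostics.tsv --targets out/targets.tsv -o out/
```

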