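# idpscore

Bayesian maximum-log-likelihood scoring and Monte Carlo sub-ensemble
selection for disordered-protein conformer pools.

Intrinsically disordered proteins (IDPs) and unfolded protein states cannot
be described by a single structure; they are characterized by conformational
ensembles judged against solution experiments that only report time- and
ensemble-averaged observables. `idpscore` scores a candidate ensemble
against eight heterogeneous data types — NMR chemical shifts, three-bond
J-couplings, homonuclear NOE and PRE distance restraints, residual dipolar
couplings, hydrodynamic radius, mean smFRET transfer efficiency, and SAXS
intensity curves — while treating experimental noise and back-calculation
error as Gaussian nuisance parameters that are optimized in closed form.
A conformer-swap Monte Carlo optimizer then refines size-N sub-ensembles
drawn with replacement from a larger pool, under single, dual, or joint
data-type objectives.

## Model

For an ensemble X = {x_i} of N conformers and M experimental data points
D = {d_j}, the score is the maximum log-likelihood

    log p(X, ξ | D, I) = log p(X | I) + Σ_j log[ p(d_j | X, ξ_j, I) p(ξ_j | I) ]

with an uninformative structural prior. Two nuisance models cover all data
types:

* **Offset model** (CS, NOE, PRE, RDC, R_h, ⟨E⟩, SAXS points): a
  back-calculation offset q ~ N(0, σ_q) and an experimental residual
  ε = d − q − ⟨m(X)⟩ ~ N(0, σ_ex). The maximizing offset is
  q\* = σ_q²(d − ⟨m⟩)/(σ_q² + σ_ex²), and the restraint's log-likelihood
  collapses to nc − (d − ⟨m⟩)²/(2(σ_q² + σ_ex²)), normalization constants
  included.
* **Karplus model** (J-couplings): J = A⟨cos²(φ−φ₀)⟩ + B⟨cos(φ−φ₀)⟩ + C with
  independent Gaussian priors on (A, B, C) (Vuister–Bax means and spreads)
  and a Gaussian experimental residual; the four-Gaussian objective is
  maximized in closed form.

Ensemble averages are arithmetic means, except NOE/PRE distances which use
the r⁻⁶ convention ⟨d⟩ = (mean dᵢ⁻⁶)⁻¹ᐟ⁶, and smFRET, where per-conformer
Cα–Cα distances are linker-scaled, converted to efficiencies, and averaged
on the efficiency scale. SAXS points are scored independently and the
per-point sum is multiplied by min(1, N_s/N_q), where
N_s = D_max(q_max − q_min)/π is the number of Shannon channels in the
curve, correcting for the oversampling of a continuous scattering profile.

The optimizer replaces one ensemble member with a uniformly drawn pool
conformer per step, accepting exchanges greedily (strict score increase) or
by a Metropolis rule acc = min[1, exp(β·Δscore)] with β = 0.1. Running
per-restraint sums make the cost of a swap independent of N.

## Worked example

Score and refine a synthetic two-population study (compact vs extended
conformers; pseudo-experimental data generated for a 75/25 mixture at
realistic noise levels), jointly optimizing a local data type (J-couplings)
with a long-range one (PREs):

```python
import numpy as np
import idpscore as ip
from idpscore import DataType

truth = ip.default_truth(n_pool=1000, seed=3)
pool = ip.make_pool(truth)
restraints = ip.make_experimental(truth, pool, {"compact": 0.75, "extended": 0.25},
                                  rng=np.random.default_rng(17))

cfg = ip.OptimizerConfig(n_steps=10_000, ensemble_size=100, n_replicates=50,
                         seed=11, active=(DataType.JC, DataType.PRE))
summary = ip.run_replicates(pool.tables, restraints, cfg)
report = ip.replicate_report(summary, pool.tables, restraints,
                             labels=pool.labels, rg_per_conformer=pool.rg)

print(f"objective: {summary.initial_objective_mean:.1f} -> "
      f"{report.objective_mean:.1f} (sd {report.objective_sd:.1f})")
for name in ("JC", "PRE", "NOE", "FRET"):
    row = report.per_type[name]
    print(f"{name:4s} score {row['score_mean']:8.1f} ({row['score_sd']:.1f})   "
          f"RMSD {row['rmsd_mean']:.3f} ({row['rmsd_sd']:.3f})")
print("composition:", {k: round(v, 3) for k, v in report.composition.items()})
```

Output:

```
objective: 516.5 -> 620.0 (sd 0.2)
JC   score    234.6 (0.1)   RMSD 0.112 (0.007)
PRE  score    385.4 (0.2)   RMSD 3.195 (0.014)
NOE  score    488.8 (0.7)   RMSD 5.023 (0.031)
FRET score      6.9 (0.2)   RMSD 0.009 (0.006)
composition: {'compact': 0.729, 'extended': 0.271}
```

The JC+PRE objective rises by ~100 log-units over random sampling; the
optimized ensembles recover the generating 75/25 mixture (72.9% compact),
and data types that never entered the objective (NOE, smFRET) improve as a
by-product — the cross-validation signature of pairing local with
long-range restraints. RMSD is in each type's own units (Hz, Å, efficiency);
scores are absolute log-likelihoods, so only differences are meaningful.

A command-line interface mirrors the library
(`idpscore simulate|score|optimize|report`); see `idpscore --help`.

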