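# Methods

## Scoring model

The package scores a sub-ensemble X of N conformers against M restraints as
a sum of per-restraint maximum log-likelihoods. Each restraint carries two
Gaussian uncertainty sources: an experimental residual with known σ_ex, and
a back-calculation nuisance with prior N(0, σ_q) (or, for J-couplings,
Gaussian priors on the three Karplus coefficients). The nuisances are
*optimized*, not marginalized: the reported score is the joint log-density
at the maximizing nuisance values, normalization constants included.

Both nuisance models have exact closed forms. For the offset model the
stationarity condition q·σ_ex² = ε·σ_q² splits the discrepancy
δ = d − ⟨m(X)⟩ between the two error channels, and the maximal
log-likelihood is nc − δ²/(2(σ_q² + σ_ex²)) with
nc = −log(σ_q√2π) − log(σ_ex√2π). For the Karplus model with ensemble
averages a₁ = ⟨cos(φ−φ₀)⟩ and a₂ = ⟨cos²(φ−φ₀)⟩, writing
ε₀ = J − (μ_A a₂ + μ_B a₁ + μ_C) and S = σ_A²a₂² + σ_B²a₁² + σ_C², the
optimum shifts each coefficient proportionally to its prior variance
(A* = μ_A + σ_A² a₂ ε₀/(σ_ex² + S), and analogously for B*, C*) and the
maximal log-likelihood is nc − ε₀²/(2(σ_ex² + S)). Both collapses are the
exact summed optima, verified in the test suite against brute-force
numerical maximization to 1e−6 and against the per-component Gaussian form.
The A-coefficient multiplies ⟨cos²⟩, the ensemble average of the squared
cosine (not the square of the average): that is what the per-conformer
Karplus relation averages to under fast exchange, and it keeps the inputs
on the Jensen-consistent domain a₂ ≥ a₁².

σ_q = 0 is accepted in the offset model: the offset is pinned at zero and
the degenerate prior contributes nothing to the score. In practice NOE and
PRE use the small sentinel σ_q = 0.0001 Å instead, taken literally; its
normalization constant contributes a large positive constant (~+8.3) per
restraint, which is why NOE/PRE absolute scores dominate all other types.
Only score *differences* matter for ranking and optimization, so this is a
presentation issue, not a statistical one.

## Ensemble averaging conventions

* CS, RDC, R_h, SAXS intensities: arithmetic mean over ensemble members
  (with multiplicity — ensembles are multisets).
* NOE/PRE: the r⁻⁶ mean (mean dᵢ⁻⁶)⁻¹ᐟ⁶, a single averaging pass over the
  sub-ensemble. The value lies between the minimum and the mean, weighted
  toward the shortest distances, as the NOE/PRE physics requires.
* J-couplings: averages of the cos and cos² terms, then one Karplus
  evaluation (never per-conformer J averaging with per-conformer
  coefficients).
* smFRET: per-conformer Cα–Cα distance → linker-scaled inter-dye distance
  r_DA = r_CαCα·((N+N_linker)/N)^υ → per-conformer efficiency
  E = (1+(r_DA/r₀)⁶)⁻¹ → arithmetic mean. Averaging on the efficiency
  scale is the fast-exchange ⟨E⟩ regime of single-molecule measurements;
  distance-averaging followed by one efficiency evaluation would be wrong
  for broad distance distributions and is deliberately not offered.

## SAXS information weighting

Scoring each intensity point as an independent restraint overweights SAXS
relative to single-restraint types, because neighbouring Q points are
strongly correlated. The per-point log-likelihood sum is therefore
multiplied by min(1, N_s/N_q) with N_s = D_max(q_max−q_min)/π Shannon
channels. The default applies the factor to the entire sum, normalization
constants included — the simplest reading of a likelihood raised to the
power N_s/N_q. A config switch (`saxs.weight_residual_only`) instead scales
only the quadratic residual part, for users who want the normalization
constants intact. q_min/q_max default to the experimental grid bounds;
D_max defaults to 60 Å and should be set per system (an explicit
`ns_override` is also accepted). For a drkN-SH3-like configuration
(N_s ≈ 3, N_q = 37) the weight is ≈ 3/37.

## Default uncertainty constants

All defaults are the drkN SH3 unfolded-state study values: Karplus priors
μ_A = 6.51, σ_A = 0.14; μ_B = −1.76, σ_B = 0.03; μ_C = 1.60, σ_C = 0.08
(Vuister–Bax), σ_Jex = 0.5 Hz; chemical shifts σ_ex = 0.3 ppm for
carbon-like nuclei and 0.03 ppm for hydrogens, with back-calculator bands
0.3–0.5 ppm (H) and 1.2–1.4 ppm (C) — the published band midpoints (0.4 and
1.3) are the defaults since the exact per-atom split is not specified, and
both are configurable; σ_qNOE = σ_qPRE = 0.0001 Å with σ_ex from the
restraint-range rules (mid-range target, range/2 for NOE giving 4 or 5 Å
for the <8/<10 Å classes, range/4 for PRE); σ_qRDC = 0.9 Hz,
σ_RDCex = 1.0 Hz; σ_Rhex = 0.30 Å, σ_qRh = 0.8 Å; σ_qFRET = 0.007 and
σ_FRETex = 0.02 — these two are used on the dimensionless efficiency scale
even though they are sometimes printed with length units, since ⟨E⟩ itself
is dimensionless; σ_qSAXS = 0.006 with σ_ex interpolated from 0.002 near
Q = 0 down to 0.0008 at q_max.

φ₀ defaults to 60°, the standard ³J(HN–Hα) convention for the Vuister–Bax
parameterization, and is configurable. FRET geometry defaults
(r₀ = 54 Å, N_linker = 9, υ = 0.55) are field-typical values for common dye
pairs on disordered chains; they enter only the geometry table builder and
the synthetic generator, never the scoring of an existing efficiency table.

## Optimization

Sub-ensembles are size-N multisets sampled uniformly with replacement
(duplicates are meaningful: they carry population weighting). One exchange
attempt evicts a uniformly chosen member and inserts a uniformly chosen
pool conformer. Greedy acceptance requires a strict score increase (ties
rejected); the Metropolis variant accepts downhill moves with probability
exp(β·Δ), β = 0.1 by default. Defaults are N = 100, 10,000 exchange
attempts, and 1000 replicates per study, each replicate re-drawing its
initial ensemble from the pool under an independent stream spawned from the
master seed, so an entire study is a pure function of (inputs, seed).

The state caches per-restraint running sums (values; cos and cos² for JC;
d⁻⁶ for NOE/PRE), so a swap costs two row updates plus a closed-form
re-score per restraint — independent of N. Floating-point drift in the
sums is bounded by a full recomputation every 1000 accepted swaps, and an
`audit()` method exposes the cached-vs-fresh deviation. Note the sums can
be numerically large (e.g. carbonyl shifts ~176 ppm × 100 members), so the
audit tolerance of 1e−10 absolute is meaningful only under this refresh
cadence; the objective itself agrees with full recomputation to better
than 1e−8 after 10,000 unrefreshed swaps.

## Synthetic study design

The generator emulates the structure of the drkN SH3 unfolded-state
analysis without any structural downloads. A pool of 1000 conformers is
drawn from two labelled populations ("compact": helix-like φ ≈ −65°, short
log-normal contact distances, R_g ≈ 16 Å; "extended": coil-like φ ≈ −120°,
longer distances, R_g ≈ 24 Å; 50/50 pool weights). Per-restraint population
means are themselves drawn once per truth (so restraints differ), and
conformer-level scatter keeps members heterogeneous. Restraint counts
default to the reference set sizes (267 CS, 47 JC, 93 NOE, 68 PRE, 28 RDC,
37 SAXS points, one R_h, one ⟨E⟩). Pseudo-experimental targets are mixture
averages of the population means under chosen weights (r⁻⁶ and
efficiency-averaging conventions respected) plus Gaussian noise at the
per-type σ_ex. Physical coherence is maintained by construction: φ angles
are drawn and Karplus terms derived, distances are log-normal (positive),
efficiencies are induced from distances, and SAXS curves are Guinier-like
functions exp(−(Q·R_g)²/3) of the per-conformer R_g.

What this does and does not show: passing the recovery tests demonstrates
that the likelihood and optimizer correctly identify mixture composition
when the pool contains the generating populations and the back-calculations
are unbiased. Real applications add back-calculator bias, restraint
mis-assignment, pool non-representativeness, and inter-restraint
correlations that the generator does not emulate; absolute scores on real
data are therefore not comparable to synthetic ones.

## Numerical and design choices

* Normalization constants are kept in all log-likelihoods; scores across
  types have mixed signs and magnitudes, and per-type RMSDs (absolute
  deviation for single-restraint types) are reported alongside as the
  intuitive metric.
* The additive constant of the Bayesian objective is fixed at 0
  (uninformative structural prior).
* Restraint tables are tab-separated with a header and `#` comments;
  JC back-calculation tables store φ in degrees so the per-cell
  cos² = (cos)² identity is structural and round trips are bit-exact
  (`repr` on write, round-trip float parsing on read). Experimental SAXS
  curves are also accepted as 3-column `.dat` files.
* Degenerate inputs fail loudly: non-positive σ_ex, empty distance lists,
  Jensen-violating (a₁, a₂) pairs, misaligned or NaN-bearing tables,
  out-of-range member indices.
* Replicate aggregation uses the sample (N−1) standard deviation; a single
  replicate reports sd = 0. R_g histograms use a fixed 0.5 Å bin width so
  figures are comparable across runs. The report object leaves a hook for
  externally computed per-residue secondary-structure propensity tables
  rather than computing DSSP itself.
* Problem sizes in the validation scripts (1000-conformer pool, 100
  replicates for recovery studies, 10,000 exchange attempts) were chosen as
  the smallest study at which replicate statistics are stable; the
  defaults for production use remain 1000 replicates.

## Known limitations

* NOEs are treated as static r⁻⁶ distance restraints; no relaxation-matrix
  or dynamical treatment.
* Chemical shifts, RDCs, R_h and SAXS intensities must be back-calculated
  by external predictors and supplied as tables; the package computes only
  what follows from coordinates directly (φ, distances, FRET efficiencies,
  R_g).
* PRE distances from coordinates use a proxy atom (e.g. tag-site Cβ) when
  no explicit spin-label atom is present; no label conformer modelling.
* No Boltzmann-weighted structural priors; no per-measurement σ estimation
  from raw spectra; no folded/unfolded deconvolution of raw SAXS or smFRET
  data (inputs are assumed to describe the disordered state already).
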