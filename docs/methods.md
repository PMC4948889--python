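# Methods

This note records the model as implemented, the assumptions behind it, the
choices made where the design was genuinely open, and what the synthetic
inputs do and do not establish.

## Reaction scheme and rate-law conventions

The network is encoded as 26 processes over 24 state variables: 20
molecular concentrations (nM) and the four adhesivity factors σ
(dimensionless).  Rate laws follow three conventions: reversible binding
as *kᵢ·X·Y − k₋ᵢ·(X/Y)*, protein synthesis at constant rates *νᵢ*, and
conversion/transport/degradation as first-order *kᵢ·X*.  Transcription of
*DPAGT1* is a Hill activation by the β-catenin/TCF complex with no basal
term — basal expression is carried by the Wnt OFF equilibrium itself,
which has a nonzero β-catenin/TCF level at total Wnt3a = 1 nM.

Block structure:

* **1–10, Wnt/β-catenin.**  Wnt3a binds mature LRP5/6 (process 1, rapid,
  *K₁*); the Wnt3a·LRP complex engages the destruction complex directly
  (2, rapid, *K₂*) and disassembles it (4, *k₄*).  The destruction
  complex assembles from APC and axin/GSK-3β (3, *k₃*/*k₋₃*), carries an
  activation equilibrium (8, *K₈*), binds β-catenin (6, rapid, *K₆*),
  phosphorylates it (7, *k₇*); phospho-β-catenin is degraded (5, *k₅*).
  β-catenin is synthesized (9, *ν₉*) and has a slow axin-independent
  degradation route (10, *k₁₀*).
* **11–19, DPAGT1/N-glycosylation.**  β-catenin/TCF binding (11, rapid,
  *K₁₁*); Hill transcription (12: *T*max, *K*TmRNA, *n*); mRNA decay (13);
  translation (14, first-order in transcript, rate constant *P*max); LRP5/6
  synthesis (15, *ν₁₅*), GPT-dependent maturation (16, bimolecular *k₁₆·G·L*,
  realizing the requirement that LRP5/6 reaches the membrane only when
  N-glycosylated — the route by which N-glycosylation feeds back on Wnt3a
  binding), immature- and mature-LRP turnover (17, 18); GPT decay (19).
* **20–26, E-cadherin.**  Co-synthesis of the E-cadherin/β-catenin complex
  in the ER (20: *ν₂₀* plus the glycosylation parameters λ = *V*max·t/*G*max
  and *K*M), ER exit (21, *K₂₁*), membrane internalization into the
  recycling compartment (22), recycling back (23), adhesivity-coupled AJ
  assembly (24, *k₂₄* = κ₂₄σ_M) whose disassembly (*k₋₂₄* = κ₂₄(1 − σ_AJ))
  internalizes the complex into the ERC, lysosomal degradation (25) and
  E-cadherin degradation with β-catenin release to the cytoplasm (26).

A single coupling slope κ₂₄ serves both arms of process 24.  The linear
form *k₋₂₄* = κ₂₄(1 − σ_AJ) is the only monotone-decreasing linear
dependence on σ_AJ that stays nonnegative on [0, 1]: maximally adhesive
junctions do not disassemble.

Adhesivity mixes with transport: each pool's σ relaxes toward the σ of its
source at the fractional-influx rate *f*gain = influx/(pool + ε),
ε = 10⁻⁹ nM guarding empty pools.  The ER pool, fed by synthesis rather
than transport, relaxes toward 1 − λ·G/(*K*M + G) (Michaelis–Menten
glycosylation by GPT); λ ≤ 1 keeps the target in [0, 1], and values above
1 (reached only in sensitivity sweeps) clamp the target at 0.

## Reduction to a DAE and its numerics

Processes 1, 2, 6, 8, 11 are rapid equilibria, and Wnt3a, APC, TCF and
axin/GSK-3β are conserved; the nine dependent species (free Wnt3a, its
two complexes, the activated and β-catenin-bound destruction complexes,
free TCF, β-catenin/TCF, free APC, free axin/GSK-3β) then follow in
closed form from the fifteen independent variables.  The reduced system
is integrated in the coordinates that the rapid reactions leave invariant
(total cytosolic unphosphorylated β-catenin, total assembled destruction
complex, total mature LRP), mapped back through the analytic Jacobian of
the invariant map — the exact singular-perturbation limit, not the common
approximation of writing ODEs for free species directly.  A Wnt3a step
re-partitions the rapid complexes instantaneously; the invariants are the
continuous quantities across the step.

Integration uses the stiff BDF method at rtol 10⁻⁸ / atol 10⁻¹⁰ nM.
Steady states are found by chunked integration followed by a hybrid-Powell
polish; the sweep warm-starts each solve from the neighboring factor's
solution.  Steady-state detection on time courses: the earliest sampled
time from which every state variable keeps |dx/dt|/(|x| + 10⁻⁶) below
10⁻⁴ per hour for the rest of the horizon (the source analysis reports a
settling time without stating a criterion; this one is the package's).
The unreduced ODE system, used as a cross-check, gives the rapid steps
explicit mass-action rates with off-rate 2×10⁵ min⁻¹ (~10³ times the
fastest slow process); reduced trajectories agree with it to ~10⁻³
relative.

## Reference condition

The 35 parameters: kinetic constants of the 26 processes plus the four
conserved totals.  Values for the Wnt core follow the Lee model where
transferable (ν₉ = 0.423 nM/min, k₁₀ = 2.57×10⁻⁴ min⁻¹, k₇ = 206 min⁻¹,
k₅ = 0.417 min⁻¹, K₆ = 120 nM, K₁₁ = 30 nM, k₋₃/k₃ = 50 nM, APC⁰ = 100 nM,
TCF⁰ = 15 nM, axin/GSK-3β total 0.02 nM scale).  The remaining values were
selected once by constraint-based calibration against the behavioral
targets the analysis is anchored to — the Wnt OFF cytoplasmic β-catenin of
the Lee core (≈ 25 nM, maintained within 3%), a ~3-fold active-β-catenin
response to Wnt3a, E-cadherin pool residence of a few hours (tagged-chase
scale), modest (~1.5-fold) DPAGT1 induction, and settling of the activated
system near 35 h — and then frozen.  Total Wnt3a is 1 nM in the OFF state
and 28.062 nM in the ON state; the ICG-001 (dysregulated) condition
doubles K₁₁.

## Sensitivity analysis

33 parameters (all but total Wnt3a, which defines the fold-change metric,
and the Hill coefficient) are scaled over [0.1, 10] on a log-uniform grid,
9 points per decade (18 factors; F = 1 excluded since the measure is
undefined there).  For each cell the Wnt OFF equilibrium of the scaled
condition is solved and the Wnt ON response is read out at the 72 h cap of
the activation protocol — the settling time varies across the sweep and is
deliberately not tracked per cell; `lsa(cap_hours=None)` substitutes true
ON steady states.  S = |(fold/fold_ref − 1)/(F − 1)| is averaged over the
factor grid, then over all 24 variables for the global ranking.  Cells
whose OFF state leaves a variable at zero (λ-sweep values that saturate
glycosylation) or that fail to converge are excluded and counted.  The
high/low impact classification flags a parameter for a variable when its
averaged sensitivity is at least twice (at most half) the variable's mean
over all parameters; the rule is scale-invariant.

Structural consequences worth knowing: the ER-exit rate K₂₁ and the
recycling rate k₂₃ have exactly zero steady-state fold-change sensitivity
(ER throughput equals the synthesis flux regardless of K₂₁; recycling
rescales pools identically in both Wnt states), and the phospho-β-catenin
pool scales as 1/k₅ in both states so k₅ cancels from every fold change.
β-catenin synthesis ranks first; the signaling block dominates the
glycosylation block, which dominates the adhesion block (block influence
summarized as the mean of each block's three highest sensitivities, since
a pathway's leverage is carried by its strongest processes).  The
absolute scale of the averages depends on the variable list and factor
grid; rankings and zeros are the robust outputs.

## Calibration module

Constraints are declarative: a steady-state level at a given total Wnt3a,
or an ON/OFF fold change, each with target, relative tolerance and weight.
Fitting minimizes Σ w·((value − target)/(tol·target))² in log-parameter
space (rates are positive and span decades) with box bounds of two decades
around the start, by Nelder–Mead from five seeded starts; a locally flat
objective triggers a non-identifiability warning.  With two to three free
parameters and model-generated targets, fits recover generating values
within a few percent from 3-fold perturbed starts.

## Motility metrics

Velocity fields are regular 2-D grids of PIV vectors; wound closure is +x,
lateral is y.  The correlation function is computed on lateral
fluctuations (lateral component minus its field mean), binned by pair
separation at the grid spacing, normalized by the root-mean-square
fluctuation of the pair members so C(0) = 1.  The correlation length is
the interpolated distance at which C(r) first falls below 1/e — exact for
an exponential profile; first-zero-crossing and absolute-threshold modes
are available for the convention used in experimental work, where the
length is the distance at which correlation becomes negligible.  Frames in
the first hour are excluded and the remainder (27 frames of a 15 h, 30-min
cadence protocol) averaged.  Movement angles are binned in 72 bins of 5°
centered on multiples of 5°, zero vectors excluded with a reported count.
Leading-edge speed is the field-of-view traversal time of the average
foremost fluorescent column; when the front never spans the field of view
a least-squares slope is returned with a flag (the traversal estimate is
biased when per-row jitter clips at the image edge, so synthetic recovery
checks use a wide field).

## Synthetic inputs: what they establish

The generators emulate the *structure* of the real inputs — spatially
correlated lateral flows (Gaussian field with exponential covariance,
imposed by spectral filtering with the 2-D Matérn-½ density on a padded
grid), directional jitter around wound closure, advancing jittered fronts,
and model-generated fold-change observations with lognormal noise.  They
are reproducible bit-for-bit from (spec, seed).  Passing the round-trip
tests shows the estimators are unbiased at realistic grid sizes and noise
levels; it does not validate cell-biological assumptions (PIV artifacts,
non-stationary flows, uneven illumination are not modeled).  Likewise the
kinetic tests verify internal consistency (conservation, reduction
accuracy, Lee-core agreement) and reproduction of the anchored behaviors,
not the literature provenance of individual rate constants, several of
which are calibrated rather than measured.

## Known limitations

* The supplementary equation list of the source analysis was unavailable;
  the scheme is a reconstruction from the stated conventions, the process
  numbering, and the parameter table.  Structural zeros (K₂₁, k₂₃, k₅)
  and the sensitivity ranking's absolute scale are where a different
  reconstruction would differ most.
* Junction count and junctional adhesivity share the relaxation clock of
  the assembly/disassembly exchange, so the AJ fold settles only slightly
  before the adhesivity fold (via its fast membrane-pool component and
  convex amplification), not hours before.
* No spatial or stochastic simulation; single-compartment deterministic
  kinetics only.  The CBP/p300 distinction behind partial ICG-001
  responses is outside the model.
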