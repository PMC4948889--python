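# rcn — the Wnt/β-catenin · N-glycosylation · E-cadherin regulatory cell network

`rcn` is a kinetic model of the regulatory cell network (RCN) that couples
three conserved pathways of epithelial homeostasis: Wnt/β-catenin
signaling, protein N-glycosylation through the Wnt target gene *DPAGT1*
(whose product, the glycosyltransferase GPT, initiates the lipid-linked
oligosaccharide pathway), and E-cadherin–mediated cell–cell adhesion.
β-catenin sits at the hub — it is both the co-transcriptional activator of
*DPAGT1* and a structural component of adherens junctions (AJ) — so the
three pathways form feedback loops whose behavior is hard to anticipate
from diagrams alone.  The package is for systems biologists who want to
simulate this network quantitatively: compute fold-change responses to
Wnt3a, rank the processes that control them, fit parameters to behavioral
constraints, and quantify collective migration from PIV velocity fields.

## The model

The network comprises 26 processes over 24 state variables:

* **Wnt/β-catenin signaling (processes 1–10).**  In the basal state the
  destruction complex (BDC: APC + axin/GSK-3β) binds cytoplasmic
  β-catenin (equilibrium constant *K₆*), phosphorylates it (*k₇*), and
  routes it to degradation (*k₅*); synthesis (*ν₉*) balances the loss.
  Wnt3a binds mature LRP5/6 receptors (*K₁*), the Wnt3a·LRP complex
  engages the BDC directly (*K₂*), sequesters it and drives its
  disassembly (*k₄*), so β-catenin accumulates.
* **DPAGT1 / N-glycosylation (11–19).**  β-catenin/TCF complex formation
  (*K₁₁*) drives Hill-type *DPAGT1* transcription
  (rate = *T*max·*c*ⁿ/(*K*ᴛ·mRNAⁿ + *c*ⁿ)), translation yields GPT, and GPT
  in turn N-glycosylates LRP5/6, which must be glycosylated to reach the
  membrane — closing a positive feedback on Wnt reception.
* **E-cadherin recycling and adhesion (20–26).**  E-cadherin/β-catenin
  complexes are co-synthesized in the ER, trafficked to the membrane,
  internalized into a recycling compartment, and assembled into AJs.
  Each pool carries an *adhesivity factor* σ ∈ [0, 1] — the inverse of its
  E-cadherin N-glycosylation extent — that mixes with transport
  (dσ/dt = *f*gain·(σ_source − σ_dest)) and is set at synthesis by GPT
  through Michaelis–Menten kinetics.  AJ assembly and disassembly rates
  couple to adhesivity: *k₂₄* ∝ σ_M, *k₋₂₄* ∝ (1 − σ_AJ).

Five binding steps (1, 2, 6, 8, 11) are treated as rapid equilibria and
the four constitutive molecules (Wnt3a, APC, TCF, axin/GSK-3β) are
conserved, reducing the ODE system to a DAE with 15 ODEs and 9 algebraic
equations (35 parameters).  The Wnt "OFF" state is the equilibrium at
total Wnt3a = 1 nM; activation steps it to 28.062 nM.  Fold change of a
molecule is its Wnt ON value over its Wnt OFF equilibrium value, the
quantity that determines downstream Wnt responses.

Local sensitivity analysis scales each of 33 parameters over two decades
(log-uniform, the total Wnt3a and the Hill coefficient excluded) and
measures S = |(fold_perturbed/fold_reference − 1)/(F − 1)|, averaged over
the factor grid and all variables to rank the processes.

The motility module is independent of the kinetics: it computes the
lateral velocity correlation function
C(r) = ⟨u(r′)u(r′+r)⟩/[⟨u(r′)²⟩⟨u(r′+r)²⟩]^½ and its decay length,
movement-angle occupancy maps, and leading-edge speed from binary front
masks — the metrics used to quantify collective migration in scratch-wound
assays.

## Worked example

```python
from rcn.simulate import run_preset

for condition in ("reference", "dysregulated"):
    for wnt in ("wnt_off", "wnt_on"):
        r = run_preset(condition, wnt)
        print(condition, wnt, round(r.bcat, 2), round(r.aj, 2), round(r.sigma, 3))
```

prints

```
reference    wnt_off  25.91  12.67  0.635
reference    wnt_on   77.70   9.52  0.549
dysregulated wnt_off  25.44  20.05  0.750
dysregulated wnt_on   72.94  11.15  0.597
```

Reading the numbers: at the reference condition, stepping Wnt3a from 1 to
28.062 nM triggers a 3.0-fold rise of free cytoplasmic β-catenin
(25.9 → 77.7 nM, matching the ~3-fold increase of active β-catenin seen on
immunoblots) while adherens junctions and adhesivity drop — activation
boosts *DPAGT1*, E-cadherin becomes more N-glycosylated, adhesion weakens.
The *dysregulated* condition models ICG-001 treatment as a doubling of the
β-catenin/TCF equilibrium constant *K₁₁*: with transcription weakened, AJ
abundance and adhesivity are **higher** than reference in both Wnt states,
the direction observed for α-catenin/E-cadherin co-precipitation under the
inhibitor.  The activated reference system reaches steady state at ≈ 35 h.

The `examples/` directory holds one short narrative script per capability
(activation time course, presets, sensitivity ranking, calibration,
motility metrics); each prints the numbers it computes and what they mean.
A thin CLI exposes the same operations from a shell:

```bash
rcn simulate --preset dysregulated:wnt_on --out state.csv
rcn lsa --grid 9 --out ranking.csv
rcn motility --fields piv_frames/ --out metrics.csv
```

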