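"""The four experimental condition presets.

Reference = physiological beta-catenin/TCF binding; dysregulated = ICG-001
treatment, modeled as doubling the binding equilibrium constant K11 (less
transcription-promoting complex).  Each preset is a steady state; the
dysregulated condition shows MORE adherens junctions and HIGHER adhesivity
in both Wnt states: blocking beta-catenin/TCF transcription lowers DPAGT1
expression, E-cadherin is less N-glycosylated, and junctions stabilize.
"""

from rcn.simulate import run_preset

print(f"{'condition':14s}{'Wnt state':10s}{'beta-cat (nM)':>14s}"
      f"{'GPT (nM)':>10s}{'AJ (nM)':>9s}{'adhesivity':>12s}")
for condition in ("reference", "dysregulated"):
    for wnt in ("wnt_off", "wnt_on"):
        r = run_preset(condition, wnt)
        print(f"{condition:14s}{wnt:10s}{r.bcat:14.2f}{r.gpt:10.2f}"
              f"{r.aj:9.2f}{r.sigma:12.3f}")

ref = run_preset("reference", "wnt_on")
dys = run_preset("dysregulated", "wnt_on")
print(f"\nWith Wnt ON, ICG-001 raises AJ abundance {dys.aj / ref.aj:.2f}-fold"
      f" and adhesivity {dys.sigma / ref.sigma:.2f}-fold over the reference,"
      "\nmatching the measured increase in alpha-catenin/E-cadherin "
      "co-precipitation under the inhibitor.")
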