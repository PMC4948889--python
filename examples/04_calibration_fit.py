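"""Constraint checking and parameter fitting.

Scores the reference condition against the shipped behavioral targets
(Lee-core beta-catenin agreement, ~3-fold active-beta-catenin response,
DPAGT1 induction), then demonstrates recovery: targets are generated from
the model itself, two parameters are perturbed 3-fold, and the fitter
(log-space Nelder-Mead multi-start) pulls them back.
"""

from rcn.calibration import (Constraint, constraint_report,
                             default_constraints, evaluate_observable,
                             fit_parameters)
from rcn.parameters import reference_parameters

params = reference_parameters()
report = constraint_report(params, default_constraints())
print("Reference condition vs shipped constraints:")
print(report.round(4).to_string())

truth = params
targets = tuple(
    Constraint(c.name, c.kind, c.variable,
               target=evaluate_observable(truth, c), tol=0.02)
    for c in (Constraint("mrna_off", "steady_state", "dpagt1_mrna", 1.0),
              Constraint("gpt_off", "steady_state", "gpt", 1.0)))
start = truth.with_overrides(Tmax=truth.Tmax * 3, k19=truth.k19 / 3)
fitted = fit_parameters(["Tmax", "k19"], targets, seed=2, params=start,
                        n_starts=3, maxiter=150)
for name in ("Tmax", "k19"):
    print(f"{name}: truth {truth[name]:.4g}, start {start[name]:.4g}, "
          f"fitted {fitted[name]:.4g} "
          f"({100 * abs(fitted[name] / truth[name] - 1):.1f}% off)")
print("Both parameters return to within a few percent of their generating "
      "values: the targets identify them.")
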