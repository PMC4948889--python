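"""Local sensitivity analysis around the reference condition.

Each of 33 parameters (all but the total Wnt3a, which defines the fold-change
metric, and the Hill coefficient) is varied one at a time over two orders of
magnitude on a uniform logarithmic grid, one decade above and one below the
physiological value.  For parameter i scaled by factor F (the j-th grid
value), the sensitivity of variable X at time t is

    S_ij(t) = | ( (X_on/X_off)_ij / (X_on/X_off)_ip - 1 ) / (F - 1) |

where (X_on/X_off)_ip is the fold change at the physiological value (F = 1).
S_ij is averaged over the grid j to give one sensitivity per (parameter,
variable), and over all variables to give the global robustness ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FULL_ORDER, INDEPENDENT, pack_independent
from .parameters import ParameterSet, reference_parameters
from .simulate import (WNT_OFF, WNT_ON, find_steady_state,
                       steady_state_newton)

__all__ = ["sweep_factors", "relative_sensitivity", "SensitivityTable",
           "lsa", "classify_impact"]


def sweep_factors(points_per_decade: int = 9) -> np.ndarray:
    """Log-uniform scaling factors spanning [0.1, 10], excluding F = 1."""
    if points_per_decade < 2:
        raise ValueError("points_per_decade must be >= 2")
    k = np.arange(-points_per_decade, points_per_decade + 1)
    k = k[k != 0]
    return 10.0 ** (k / points_per_decade)


def relative_sensitivity(fold_ij: float, fold_ip: float, factor: float):
    """|(fold_ij/fold_ip - 1) / (F - 1)|; undefined at F = 1."""
    factor = np.asarray(factor, dtype=float)
    if np.any(factor == 1.0):
        raise ValueError("sensitivity is undefined at factor F = 1")
    if np.any(np.asarray(fold_ip) <= 0.0):
        raise ValueError("reference fold change must be positive")
    out = np.abs((np.asarray(fold_ij) / fold_ip - 1.0) / (factor - 1.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class SensitivityTable:
    """Results of the local sensitivity analysis.

    ``long``: one row per (parameter, factor, variable) with S_ij.
    ``by_variable``: parameters x variables, S averaged over the factor grid.
    ``average``: per-parameter average over all variables (ranking metric).
    ``ranking``: rank / process / parameter / average sensitivity.
    """

    long: pd.DataFrame
    by_variable: pd.DataFrame
    average: pd.Series
    ranking: pd.DataFrame
    failed_cells: list = field(default_factory=list)

    def block_summary(self, top: int = 3) -> pd.Series:
        """Pathway influence: mean of each block's ``top`` highest-ranked
        parameter sensitivities (signaling / glycosylation / adhesion)."""
        blocks = {}
        for name, s in self.average.items():
            blocks.setdefault(ParameterSet.info(name).block, []).append(s)
        return pd.Series({b: float(np.mean(sorted(v, reverse=True)[:top]))
                          for b, v in blocks.items()})


def _condition_folds(params: ParameterSet,
                     warm_off: np.ndarray | None,
                     variables: list[str],
                     cap_min: float | None):
    """Fold changes ON/OFF for one parameter condition.

    The Wnt OFF equilibrium is solved by Newton (warm started, integration
    fallback).  The Wnt ON value follows the activation protocol: the system
    is restarted from the perturbed OFF equilibrium with total Wnt3a stepped
    to 28.062 nM and read out at the 72 h cap (``cap_min``); with
    ``cap_min=None`` the true ON steady state is solved instead.  Returns
    (folds, x_off) or None when the condition cannot be evaluated.
    """
    from scipy.integrate import solve_ivp

    from .model import (INDEPENDENT, dae_rhs, fast_invariants,
                        free_from_invariants, full_state_from_independent)

    p_off = params.with_overrides(WNT0=WNT_OFF)
    p_on = params.with_overrides(WNT0=WNT_ON)
    x_off = steady_state_newton(p_off, warm_off) if warm_off is not None else None
    if x_off is None:
        try:
            x_off = pack_independent(find_steady_state(p_off))
        except RuntimeError:
            return None
    s_off = full_state_from_independent(x_off, p_off)
    # Wnt3a step: repartition the rapid complexes, then run the ON system
    y = fast_invariants(s_off["bcat"], s_off["bdc"], s_off["lrp_m"], p_off)
    b, d, lm = free_from_invariants(*y, p_on)
    x0 = x_off.copy()
    x0[INDEPENDENT.index("bcat")] = b
    x0[INDEPENDENT.index("bdc")] = d
    x0[INDEPENDENT.index("lrp_m")] = lm
    if cap_min is None:
        x_on = steady_state_newton(p_on, x0)
        if x_on is None:
            try:
                x_on = pack_independent(find_steady_state(p_on, x0=x0))
            except RuntimeError:
                return None
    else:
        sol = solve_ivp(dae_rhs, (0.0, cap_min), x0, args=(p_on,),
                        method="BDF", rtol=1e-7, atol=1e-10,
                        t_eval=[cap_min])
        if not sol.success:
            return None
        x_on = np.clip(sol.y[:, -1], 0.0, None)
    s_on = full_state_from_independent(x_on, p_on)
    off = np.array([s_off[v] for v in variables])
    on = np.array([s_on[v] for v in variables])
    if np.any(off <= 0.0):
        return None
    return on / off, x_off


def lsa(params: ParameterSet | None = None,
        points_per_decade: int = 9,
        variables: list[str] | None = None,
        parameters: list[str] | None = None,
        cap_hours: float | None = 72.0) -> SensitivityTable:
    """Full local sensitivity analysis of the fold-change response.

    For every parameter and factor, the Wnt OFF equilibrium of the scaled
    condition is solved (Newton continuation along the factor grid,
    integration fallback) and the Wnt ON response is read out at the 72 h
    cap of the activation protocol (the settling time varies across the
    sweep and is not tracked per cell; ``cap_hours=None`` solves the true ON
    steady state instead).  Fold changes are converted to sensitivities and
    assembled into a :class:`SensitivityTable`.  Non-convergent cells are
    excluded from the averages and reported in ``failed_cells`` with a
    warning.  Deterministic: no randomness enters the sweep.
    """
    if params is None:
        params = reference_parameters()
    if variables is None:
        variables = list(FULL_ORDER)
    if parameters is None:
        parameters = list(ParameterSet.lsa_names())
    factors = sweep_factors(points_per_decade)
    cap_min = None if cap_hours is None else 60.0 * cap_hours

    base = _condition_folds(params, None, variables, cap_min)
    if base is None:
        raise RuntimeError("reference steady states could not be computed")
    fold_ref, x_off_ref = base

    records = []
    failed = []
    for name in parameters:
        # continuation outward from F = 1, separately for each half-decade
        for half in (factors[factors < 1.0][::-1], factors[factors > 1.0]):
            warm_off = x_off_ref
            for f in half:
                res = _condition_folds(params.scaled(name, f),
                                       warm_off, variables, cap_min)
                if res is None:
                    failed.append((name, float(f)))
                    continue
                folds, warm_off = res
                s = relative_sensitivity(folds, fold_ref, f)
                for v, sv in zip(variables, s):
                    records.append((name, float(f), v, float(sv)))
    if failed:
        warnings.warn(f"{len(failed)} LSA cells did not converge and were "
                      f"excluded: {failed[:5]}...")
    long = pd.DataFrame(records, columns=["parameter", "factor", "variable", "S"])
    by_variable = (long.groupby(["parameter", "variable"])["S"].mean()
                   .unstack("variable").reindex(parameters))
    average = by_variable.mean(axis=1).rename("avg_sensitivity")
    order = average.sort_values(ascending=False)
    ranking = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "process": [ParameterSet.info(n).reaction for n in order.index],
        "parameter": order.index,
        "avg_sensitivity": order.values,
    }).set_index("rank")
    return SensitivityTable(long, by_variable, average, ranking, failed)


def classify_impact(table: SensitivityTable) -> pd.DataFrame:
    """High/low impact flags per (parameter, variable).

    A parameter is "high" for a variable when its averaged sensitivity is at
    least twice the variable's mean over all parameters, "low" when at most
    half of it, else "neutral".  Scale-invariant by construction.
    """
    bv = table.by_variable
    mean = bv.mean(axis=0)
    nonzero = mean > 0
    flags = pd.DataFrame("neutral", index=bv.index, columns=bv.columns)
    flags = flags.mask(bv.ge(2.0 * mean, axis=1) & nonzero, "high")
    flags = flags.mask(bv.le(0.5 * mean, axis=1) & nonzero, "low")
    return flags
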