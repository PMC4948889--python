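"""Steady states, Wnt-activation time courses, fold changes and presets.

The Wnt "OFF" state is the equilibrium at total Wnt3a WNT0 = 1 nM; activation
is an instantaneous step of WNT0 to 28.062 nM at t = 0 from that equilibrium.
Fold change of a variable is its Wnt "ON" value divided by its Wnt "OFF"
equilibrium value.  The *dysregulated* condition (ICG-001 treatment) doubles
the beta-catenin/TCF equilibrium constant K11, shifting the equilibrium away
from the transcription-promoting complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (FULL_ORDER, INDEPENDENT, StateVector, dae_rhs,
                    fast_invariants, free_from_invariants,
                    full_state_from_independent, pack_independent)
from .parameters import ParameterSet, reference_parameters

__all__ = [
    "WNT_OFF", "WNT_ON", "DEFAULT_TIME_GRID_MIN",
    "Trajectory", "PresetResult",
    "find_steady_state", "steady_state_newton", "time_course",
    "fold_change", "steady_state_time", "run_preset", "PRESET_NAMES",
]

WNT_OFF = 1.0     # nM, total Wnt3a in the Wnt "OFF" state
WNT_ON = 28.062   # nM, total Wnt3a in the Wnt "ON" state

#: reporting grid: every 100 min from 1-900 min, then every 12 h from 24-72 h.
DEFAULT_TIME_GRID_MIN: tuple[float, ...] = tuple(
    [1.0] + [float(t) for t in range(100, 1000, 100)]
    + [float(h * 60) for h in (24, 36, 48, 60, 72)]
)

_RTOL = 1e-8
_ATOL = 1e-10
_RATE_EPS = 1e-6          # nM floor in the relative-rate criterion
_SS_RATE_TOL_PER_H = 1e-4  # steady state: every |dx/dt|/(|x|+eps) below this


def _default_initial_guess(params: ParameterSet) -> np.ndarray:
    guess = {
        "bcat": 10.0, "bcat_p": 1.0, "bdc": 0.5 * params.AXG0,
        "lrp_i": 1.0, "lrp_m": 1.0, "dpagt1_mrna": 0.5, "gpt": 10.0,
        "ecad_er": 1.0, "ecad_m": 5.0, "ecad_erc": 2.0, "ecad_aj": 5.0,
        "sigma_er": 0.5, "sigma_m": 0.5, "sigma_erc": 0.5, "sigma_aj": 0.5,
    }
    return np.array([guess[n] for n in INDEPENDENT])


def _relative_rates_per_hour(x: np.ndarray, params: ParameterSet) -> np.ndarray:
    dx = dae_rhs(0.0, x, params)
    return 60.0 * np.abs(dx) / (np.abs(x) + _RATE_EPS)


def steady_state_newton(params: ParameterSet,
                        x0: np.ndarray) -> np.ndarray | None:
    """Newton (hybrid Powell) solve of the reduced system from a warm start.

    Returns the 15-vector of independent variables, or None if the solver
    fails, converges to a negative/invalid state, or leaves a large residual.
    """
    sol = root(lambda x: dae_rhs(0.0, x, params), x0, method="hybr",
               options={"xtol": 1e-12, "maxfev": 4000})
    x = sol.x
    if not sol.success:
        return None
    if np.any(x < -1e-8):
        return None
    sig = [x[INDEPENDENT.index(n)] for n in
           ("sigma_er", "sigma_m", "sigma_erc", "sigma_aj")]
    if min(sig) < -1e-8 or max(sig) > 1 + 1e-8:
        return None
    x = np.clip(x, 0.0, None)
    resid = np.abs(dae_rhs(0.0, x, params))
    if np.any(resid > 1e-8 * (np.abs(x) + 1.0)):
        return None
    return x


def find_steady_state(params: ParameterSet,
                      wnt0: float | None = None,
                      x0: np.ndarray | None = None) -> StateVector:
    """Deterministic steady state of the reduced system.

    Integrates from a fixed initial condition until the relative rates are
    small, then polishes with a Newton solve.  ``wnt0`` overrides the total
    Wnt3a of ``params`` (1 nM = Wnt OFF, 28.062 nM = Wnt ON).

    Raises
    ------
    RuntimeError
        If no converged nonnegative equilibrium is found; the message carries
        the residual norm.
    """
    if wnt0 is not None:
        params = params.with_overrides(WNT0=wnt0)
    x = _default_initial_guess(params) if x0 is None else np.asarray(x0, float)
    chunk = 3000.0  # min
    for _ in range(60):
        sol = solve_ivp(dae_rhs, (0.0, chunk), x, args=(params,),
                        method="BDF", rtol=_RTOL, atol=_ATOL)
        if not sol.success:
            raise RuntimeError(f"steady-state integration failed: {sol.message}")
        x = np.clip(sol.y[:, -1], 0.0, None)
        polished = steady_state_newton(params, x)
        if polished is not None:
            return full_state_from_independent(polished, params)
        if np.max(_relative_rates_per_hour(x, params)) < 1e-7:
            return full_state_from_independent(x, params)
    resid = float(np.linalg.norm(dae_rhs(0.0, x, params)))
    raise RuntimeError(
        f"no steady state found after long integration; residual norm {resid:.3e}"
    )


@dataclass
class Trajectory:
    """Time course of the full 24-variable state on a fixed output grid."""

    times_min: np.ndarray
    states: np.ndarray  # (n_times, 24) in FULL_ORDER
    params: ParameterSet
    wnt0_off: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def times_h(self) -> np.ndarray:
        return self.times_min / 60.0

    def state_at(self, t_min: float) -> StateVector:
        i = int(np.argmin(np.abs(self.times_min - t_min)))
        if abs(self.times_min[i] - t_min) > 1e-6:
            raise KeyError(f"time {t_min} min not on the output grid")
        return StateVector(self.states[i])

    def final_state(self) -> StateVector:
        return StateVector(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: time_min, variable, value."""
        wide = pd.DataFrame(self.states, columns=list(FULL_ORDER))
        wide.insert(0, "time_min", self.times_min)
        return wide.melt(id_vars="time_min", var_name="variable",
                         value_name="value")


def time_course(params: ParameterSet,
                initial: StateVector | None = None,
                wnt0_on: float = WNT_ON,
                t_grid_min: Sequence[float] | None = None,
                dense_dt_min: float | None = None) -> Trajectory:
    """Integrate the Wnt3a activation protocol.

    ``initial`` defaults to the Wnt OFF equilibrium of ``params``.  At t = 0
    the total Wnt3a steps to ``wnt0_on``; the rapid equilibria re-partition
    instantaneously (the rapid-reaction invariants are the continuous
    quantities), then the reduced system is integrated over the output grid.
    """
    wnt0_off = params.WNT0
    if initial is None:
        initial = find_steady_state(params)
    params_on = params.with_overrides(WNT0=wnt0_on)

    # re-partition the fast complexes under the new total Wnt3a
    y_b, y_d, y_l = fast_invariants(initial["bcat"], initial["bdc"],
                                    initial["lrp_m"], params)
    b, d, lm = free_from_invariants(y_b, y_d, y_l, params_on)
    x0 = pack_independent(initial)
    x0[INDEPENDENT.index("bcat")] = b
    x0[INDEPENDENT.index("bdc")] = d
    x0[INDEPENDENT.index("lrp_m")] = lm

    if t_grid_min is None:
        t_grid_min = DEFAULT_TIME_GRID_MIN
    t_grid = np.asarray(sorted(set([0.0] + [float(t) for t in t_grid_min])))
    if dense_dt_min is not None:
        t_grid = np.unique(np.concatenate(
            [t_grid, np.arange(0.0, t_grid[-1] + dense_dt_min / 2, dense_dt_min)]))

    sol = solve_ivp(dae_rhs, (0.0, float(t_grid[-1])), x0, args=(params_on,),
                    method="BDF", rtol=_RTOL, atol=_ATOL, t_eval=t_grid)
    if not sol.success:
        raise RuntimeError(
            f"activation time course failed at t={sol.t[-1] if len(sol.t) else 0} "
            f"min: {sol.message}")
    states = np.empty((len(t_grid), len(FULL_ORDER)))
    for i in range(len(t_grid)):
        states[i] = full_state_from_independent(
            np.clip(sol.y[:, i], 0.0, None), params_on).as_array()
    return Trajectory(t_grid, states, params_on, wnt0_off=wnt0_off,
                      meta={"wnt0_on": wnt0_on})


def fold_change(on_traj: Trajectory,
                off_state: StateVector | Mapping[str, float],
                times_min: Sequence[float] | None = None,
                variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-variable ratio of the Wnt ON trajectory to the Wnt OFF equilibrium.

    Returns a frame indexed by time (min) with one column per variable.

    Raises
    ------
    ValueError
        If the OFF value of a requested variable is zero (undefined ratio).
    """
    if variables is None:
        variables = list(FULL_ORDER)
    off = np.array([float(off_state[v]) for v in variables])
    zero = [v for v, o in zip(variables, off) if o <= 0.0]
    if zero:
        raise ValueError(f"fold change undefined: zero Wnt OFF value for {zero}")
    if times_min is None:
        times = on_traj.times_min[on_traj.times_min > 0]
    else:
        times = np.asarray([float(t) for t in times_min])
    rows = np.empty((len(times), len(variables)))
    cols = [list(FULL_ORDER).index(v) for v in variables]
    for i, t in enumerate(times):
        j = int(np.argmin(np.abs(on_traj.times_min - t)))
        if abs(on_traj.times_min[j] - t) > 1e-6:
            raise KeyError(f"time {t} min not on the trajectory grid")
        rows[i] = on_traj.states[j, cols] / off
    return pd.DataFrame(rows, index=pd.Index(times, name="time_min"),
                        columns=list(variables))


def steady_state_time(params: ParameterSet | None = None,
                      wnt0_on: float = WNT_ON,
                      horizon_min: float = 72 * 60.0,
                      dt_min: float = 10.0,
                      rate_tol_per_h: float = _SS_RATE_TOL_PER_H) -> float:
    """Hours until the activated system reaches steady state.

    Detection rule: the earliest sampled time from which every state variable
    keeps a relative rate |dx/dt| / (|x| + eps) below ``rate_tol_per_h``
    (per hour) for the rest of the horizon.
    """
    if params is None:
        params = reference_parameters()
    traj = time_course(params, wnt0_on=wnt0_on,
                       t_grid_min=np.arange(0.0, horizon_min + dt_min, dt_min))
    idx = [list(FULL_ORDER).index(n) for n in INDEPENDENT]
    ok = np.empty(len(traj.times_min), dtype=bool)
    for i in range(len(traj.times_min)):
        x = traj.states[i, idx]
        ok[i] = np.max(_relative_rates_per_hour(x, traj.params)) < rate_tol_per_h
    # earliest time from which the criterion holds for good
    holds_from = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        holds_from = i
    if holds_from >= len(ok):
        raise RuntimeError(
            f"system not at steady state within {horizon_min / 60:.0f} h")
    return float(traj.times_min[holds_from] / 60.0)


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

PRESET_NAMES: tuple[str, ...] = (
    "reference:wnt_off", "reference:wnt_on",
    "dysregulated:wnt_off", "dysregulated:wnt_on",
)


@dataclass(frozen=True)
class PresetResult:
    """Steady-state readout of one experimental condition."""

    condition: str
    wnt_state: str
    params: ParameterSet
    state: StateVector

    @property
    def aj(self) -> float:
        """Adherens-junction E-cadherin/beta-catenin concentration (nM)."""
        return self.state["ecad_aj"]

    @property
    def sigma(self) -> float:
        """Adhesivity of junctional E-cadherin (sigma_AJ)."""
        return self.state["sigma_aj"]

    @property
    def bcat(self) -> float:
        """Free cytoplasmic beta-catenin (nM)."""
        return self.state["bcat"]

    @property
    def gpt(self) -> float:
        """GPT enzyme concentration (nM)."""
        return self.state["gpt"]


def run_preset(condition: str, wnt_state: str | None = None,
               params: ParameterSet | None = None) -> PresetResult:
    """Steady state of one of the four experimental condition presets.

    ``condition``: "reference" (physiological K11) or "dysregulated"
    (ICG-001 treatment, modeled as 2 x K11).  ``wnt_state``: "wnt_off"
    (WNT0 = 1 nM) or "wnt_on" (WNT0 = 28.062 nM).  A combined
    "condition:wnt_state" string is also accepted.
    """
    if wnt_state is None:
        if ":" not in condition:
            raise ValueError(f"unknown preset {condition!r}; "
                             f"expected one of {PRESET_NAMES}")
        condition, wnt_state = condition.split(":", 1)
    if params is None:
        params = reference_parameters()
    if condition == "reference":
        pass
    elif condition == "dysregulated":
        params = params.scaled("K11", 2.0)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if wnt_state not in ("wnt_off", "wnt_on"):
        raise ValueError(f"unknown Wnt state {wnt_state!r}")
    off = find_steady_state(params, wnt0=WNT_OFF)
    if wnt_state == "wnt_off":
        state, wnt0 = off, WNT_OFF
    else:
        # activation protocol: continue from the OFF equilibrium after the
        # Wnt3a step (repartitioning the rapid complexes), to land on the
        # attractor the stimulated system actually reaches
        wnt0 = WNT_ON
        params_on = params.with_overrides(WNT0=wnt0)
        y_b, y_d, y_l = fast_invariants(off["bcat"], off["bdc"], off["lrp_m"],
                                        params.with_overrides(WNT0=WNT_OFF))
        b, d, lm = free_from_invariants(y_b, y_d, y_l, params_on)
        x0 = pack_independent(off)
        x0[INDEPENDENT.index("bcat")] = b
        x0[INDEPENDENT.index("bdc")] = d
        x0[INDEPENDENT.index("lrp_m")] = lm
        state = find_steady_state(params_on, x0=x0)
    return PresetResult(condition, wnt_state, params.with_overrides(WNT0=wnt0),
                        state)
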