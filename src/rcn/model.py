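"""Rate laws, rapid-equilibrium algebra, and the reduced dynamical system.

The 26-process scheme is integrated in two equivalent forms:

* the **full ODE system** (:func:`ode_rhs`): mass-action kinetics for all 24
  state variables, with the five rapid binding equilibria (processes 1, 2, 6,
  8, 11) given explicit on/off rates scaled far above every slow process.
  This form serves as the reference for the reduction and for conservation
  checks.

* the **reduced system** (:func:`dae_rhs`): 15 ODEs (11 concentrations + the
  4 adhesivity factors) with the 9 dependent concentrations eliminated
  through 5 equilibrium relations and 4 conservation laws.  Internally the
  integrator advances the rapid-reaction invariants (total cytosolic
  beta-catenin, total assembled destruction complex, total mature LRP) and
  maps back to free concentrations through the closed-form algebra, so the
  reduction is the exact singular-perturbation limit of the full system.

Adhesivity factors sigma in [0, 1] track the (inverse) N-glycosylation
extent of E-cadherin per pool; each relaxes toward the adhesivity of its
source pool at the fractional influx rate f_gain = influx / (pool + eps).
"""

from __future__ import annotations

from typing import Iterator, Mapping

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet
from .scheme import (CONSERVED_FAMILIES, DEPENDENT, INDEPENDENT, REACTIONS,
                     SIGMA, SPECIES)

__all__ = [
    "StateVector",
    "FULL_ORDER",
    "EPS_POOL",
    "FAST_SCALE",
    "transcription_rate",
    "adhesivity_rate",
    "er_adhesivity_rate",
    "aj_rates",
    "resolve_dependent",
    "reaction_rates",
    "ode_rhs",
    "dae_rhs",
    "pack_independent",
    "unpack_independent",
    "full_state_from_independent",
    "fast_invariants",
    "free_from_invariants",
    "algebraic_residuals",
]

#: state ordering used by every array interface: 15 independent then 9 dependent.
FULL_ORDER: tuple[str, ...] = INDEPENDENT + DEPENDENT
_IDX = {name: i for i, name in enumerate(FULL_ORDER)}
_SIGMA_IDX = [_IDX[s] for s in SIGMA]

#: regularizer (nM) for the fractional-influx rate of empty E-cadherin pools.
EPS_POOL = 1e-9

#: nominal on/off rate scale (1/min) of the rapid equilibria in the full ODE
#: system; ~1000x the fastest slow process (k7 ~ 206/min).
FAST_SCALE = 2.0e5

_CONC = tuple(s.name for s in SPECIES if not s.is_sigma)

# stoichiometry matrix over concentration species (rows) x reactions (cols)
_S = np.zeros((len(FULL_ORDER), len(REACTIONS)))
for _j, _r in enumerate(REACTIONS):
    for _sp in _r.reactants:
        _S[_IDX[_sp], _j] -= 1.0
    for _sp in _r.products:
        _S[_IDX[_sp], _j] += 1.0
_RAPID_COLS = np.array([j for j, r in enumerate(REACTIONS) if r.rapid])

# process 24 is bidirectional with asymmetric routing: assembly moves
# membrane complexes into junctions, while disassembled junction complexes
# are internalized into the ERC.  The extended matrix carries the
# disassembly arm in an extra column (same process id).
_AJ_COL = next(j for j, r in enumerate(REACTIONS) if r.rid == 24)
_S_EXT = np.hstack([_S, np.zeros((len(FULL_ORDER), 1))])
_S_EXT[_IDX["ecad_aj"], -1] = -1.0
_S_EXT[_IDX["ecad_erc"], -1] = 1.0


class StateVector(Mapping[str, float]):
    """Mapping of the 24 state variables (20 concentrations, nM; 4 sigma).

    Fifteen entries are independent (ODE variables), nine are dependent
    (fixed by the rapid equilibria and conservation laws).
    """

    __slots__ = ("_arr",)

    def __init__(self, values: Mapping[str, float] | np.ndarray):
        if isinstance(values, np.ndarray):
            if values.shape != (len(FULL_ORDER),):
                raise ValueError(f"expected array of length {len(FULL_ORDER)}")
            self._arr = np.asarray(values, dtype=float).copy()
        else:
            missing = [n for n in FULL_ORDER if n not in values]
            if missing:
                raise ValueError(f"missing state variables: {missing}")
            self._arr = np.array([float(values[n]) for n in FULL_ORDER])

    def __getitem__(self, key: str) -> float:
        return float(self._arr[_IDX[key]])

    def __iter__(self) -> Iterator[str]:
        return iter(FULL_ORDER)

    def __len__(self) -> int:
        return len(FULL_ORDER)

    def as_array(self) -> np.ndarray:
        """Full state as an array in :data:`FULL_ORDER`."""
        return self._arr.copy()

    def independent_array(self) -> np.ndarray:
        return self._arr[: len(INDEPENDENT)].copy()

    def validate(self) -> None:
        if not np.all(np.isfinite(self._arr)):
            raise ValueError("state contains non-finite values")
        if np.any(self._arr < -1e-9):
            bad = [n for n in FULL_ORDER if self[n] < -1e-9]
            raise ValueError(f"negative concentrations: {bad}")
        sig = self._arr[_SIGMA_IDX]
        if np.any(sig < -1e-9) or np.any(sig > 1 + 1e-9):
            raise ValueError("adhesivity factors must lie in [0, 1]")

    def conserved_totals(self, params: ParameterSet | None = None) -> dict[str, float]:
        """Summed concentration of each constitutive-molecule family."""
        return {tot: sum(self[m] for m in members)
                for tot, members in CONSERVED_FAMILIES.items()}

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{n}={self[n]:.4g}" for n in FULL_ORDER)
        return f"StateVector({body})"


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def transcription_rate(complex_conc: float, params: ParameterSet) -> float:
    """Hill-type DPAGT1 transcription rate (nM/min) driven by beta-catenin/TCF.

    rate = Tmax * c**n / (KTmRNA**n + c**n); no basal term.
    """
    c = np.asarray(complex_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("complex concentration must be nonnegative")
    cn = c ** params.n
    out = params.Tmax * cn / (params.KTmRNA ** params.n + cn)
    return float(out) if np.isscalar(complex_conc) else out


def adhesivity_rate(sigma_dest: float, sigma_source: float, f_gain: float) -> float:
    """d(sigma_dest)/dt for a pool fed by transport: f_gain*(source - dest)."""
    for s in (sigma_dest, sigma_source):
        if not (-1e-12 <= s <= 1 + 1e-12):
            raise ValueError(f"adhesivity factor {s} outside [0, 1]")
    if f_gain < 0:
        raise ValueError("f_gain must be nonnegative")
    return f_gain * (sigma_source - sigma_dest)


def er_adhesivity_rate(sigma_er: float, gpt: float, f_gain: float,
                       params: ParameterSet) -> float:
    """d(sigma_ER)/dt: nascent E-cadherin glycosylated by GPT (Michaelis-Menten).

    The target adhesivity is 1 - lam*gpt/(KM + gpt) with the lumped
    lam = Vmax*t/Gmax in [0, 1], so the target stays in [0, 1].
    """
    if gpt < 0:
        raise ValueError("GPT concentration must be nonnegative")
    target = 1.0 - params.lam * gpt / (params.KM + gpt)
    if target < 0.0:
        raise ValueError(
            "lam = Vmax*t/Gmax > 1 drives the adhesivity target below 0 at "
            f"GPT = {gpt} nM: rejected parameterization")
    return adhesivity_rate(sigma_er, target, f_gain)


def aj_rates(sigma_m: float, sigma_aj: float,
             params: ParameterSet) -> tuple[float, float]:
    """Adhesivity-coupled AJ assembly and disassembly rates (1/min).

    k24 = kappa24*sigma_M (assembly needs adhesive membrane E-cadherin);
    k-24 = kappa24*(1 - sigma_AJ) (adhesive junctions resist disassembly).
    """
    for s in (sigma_m, sigma_aj):
        if not (-1e-12 <= s <= 1 + 1e-12):
            raise ValueError(f"adhesivity factor {s} outside [0, 1]")
    return params.kappa24 * sigma_m, params.kappa24 * (1.0 - sigma_aj)


# ---------------------------------------------------------------------------
# rapid-equilibrium algebra
# ---------------------------------------------------------------------------

def _dependent_from_free(b: float, d: float, lm: float,
                         params: ParameterSet) -> dict[str, float]:
    """Closed-form dependent concentrations given the free B, D, LRP_m."""
    p = params
    d_act = d / p.K8
    db = b * d_act / p.K6
    t = p.TCF0 * p.K11 / (p.K11 + b)
    bt = b * t / p.K11
    c = (1.0 + d / p.K2) / p.K1
    w = p.WNT0 / (1.0 + c * lm)
    wl = w * lm / p.K1
    wd = wl * d / p.K2
    family = d + d_act + db + wd
    apc = p.APC0 - family
    ag = p.AXG0 - family
    return {"wnt": w, "wnt_lrp": wl, "wnt_bdc": wd, "bdc_act": d_act,
            "bdc_bcat": db, "tcf": t, "bcat_tcf": bt, "apc": apc,
            "axin_gsk": ag}


def resolve_dependent(independent_state: Mapping[str, float] | np.ndarray,
                      params: ParameterSet, check: bool = True) -> StateVector:
    """Solve the 9 algebraic relations for the dependent species.

    Five rapid equilibria (processes 1, 2, 6, 8, 11) and the conservation of
    Wnt3a, APC, TCF and axin/GSK-3beta fix the nine dependent concentrations
    given the fifteen independent variables (free concentrations + sigma).

    Raises
    ------
    ValueError
        If no nonnegative solution exists (conserved totals exceeded:
        degenerate parameters).
    """
    if isinstance(independent_state, np.ndarray):
        indep = {n: float(v) for n, v in zip(INDEPENDENT, independent_state)}
    else:
        indep = {n: float(independent_state[n]) for n in INDEPENDENT}
    dep = _dependent_from_free(indep["bcat"], indep["bdc"], indep["lrp_m"], params)
    if check:
        if min(dep["apc"], dep["axin_gsk"]) < -1e-9:
            raise ValueError(
                "no nonnegative solution: destruction-complex family exceeds "
                "the conserved APC or axin/GSK-3beta total (degenerate parameters)"
            )
    full = dict(indep)
    full.update(dep)
    return StateVector(full)


def algebraic_residuals(state: StateVector, params: ParameterSet) -> np.ndarray:
    """The 9 algebraic relations evaluated on a full state (0 when satisfied).

    Order: equilibria 1, 2, 6, 8, 11 (as X*Y/K - complex, nM), then the
    conservation defects for Wnt3a, APC, TCF, axin/GSK-3beta (nM).
    """
    p = params
    s = state
    res = [
        s["wnt"] * s["lrp_m"] / p.K1 - s["wnt_lrp"],
        s["wnt_lrp"] * s["bdc"] / p.K2 - s["wnt_bdc"],
        s["bcat"] * s["bdc_act"] / p.K6 - s["bdc_bcat"],
        s["bdc"] / p.K8 - s["bdc_act"],
        s["bcat"] * s["tcf"] / p.K11 - s["bcat_tcf"],
    ]
    totals = s.conserved_totals()
    for tot in ("WNT0", "APC0", "TCF0", "AXG0"):
        res.append(totals[tot] - p[tot])
    return np.array(res)


# ---------------------------------------------------------------------------
# fast-reaction invariants and their inverse map
# ---------------------------------------------------------------------------

def fast_invariants(b: float, d: float, lm: float,
                    params: ParameterSet) -> tuple[float, float, float]:
    """The rapid-reaction invariants (y_B, y_D, y_L) at given free species.

    y_B = B + DB + BT        (cytosolic unphosphorylated beta-catenin)
    y_D = D + Da + DB + WD   (assembled destruction complex, all forms)
    y_L = Lm + WL + WD       (mature LRP5/6, free and Wnt-engaged)

    These are continuous across the rapid dynamics (and across a step in
    total Wnt3a), which makes them the proper slow coordinates.
    """
    dep = _dependent_from_free(b, d, lm, params)
    y_b = b + dep["bdc_bcat"] + dep["bcat_tcf"]
    y_d = d + dep["bdc_act"] + dep["bdc_bcat"] + dep["wnt_bdc"]
    y_l = lm + dep["wnt_lrp"] + dep["wnt_bdc"]
    return y_b, y_d, y_l


def _b_given_d(y_b: float, d: float, params: ParameterSet) -> float:
    """Positive root of the beta-catenin invariant equation at fixed D."""
    p = params
    if y_b <= 0.0:
        return 0.0
    a1 = 1.0 + d / (p.K6 * p.K8)
    # a1*B^2 + (a1*K11 + TCF0 - y_b)*B - y_b*K11 = 0
    bq = a1 * p.K11 + p.TCF0 - y_b
    cq = -y_b * p.K11
    disc = bq * bq - 4.0 * a1 * cq
    return (-bq + np.sqrt(disc)) / (2.0 * a1)


def _lm_given_d(y_l: float, d: float, params: ParameterSet) -> float:
    """Positive root of the LRP invariant equation at fixed D."""
    p = params
    if y_l <= 0.0:
        return 0.0
    c = (1.0 + d / p.K2) / p.K1
    # c*Lm^2 + (1 + c*W0 - c*y_l)*Lm - y_l = 0
    bq = 1.0 + c * (p.WNT0 - y_l)
    disc = bq * bq + 4.0 * c * y_l
    return (-bq + np.sqrt(disc)) / (2.0 * c)


def free_from_invariants(y_b: float, y_d: float, y_l: float,
                         params: ParameterSet) -> tuple[float, float, float]:
    """Invert (y_B, y_D, y_L) -> free (B, D, Lm): nested closed forms plus a
    bracketed scalar solve for D."""
    p = params
    y_b = max(y_b, 0.0)
    y_d = max(y_d, 0.0)
    y_l = max(y_l, 0.0)
    if y_d == 0.0:
        return _b_given_d(y_b, 0.0, p), 0.0, _lm_given_d(y_l, 0.0, p)

    def defect(d: float) -> float:
        b = _b_given_d(y_b, d, p)
        lm = _lm_given_d(y_l, d, p)
        c = (1.0 + d / p.K2) / p.K1
        w = p.WNT0 / (1.0 + c * lm)
        wd = w * lm * d / (p.K1 * p.K2)
        return d * (1.0 + 1.0 / p.K8) + b * d / (p.K6 * p.K8) + wd - y_d

    hi = y_d
    # defect(0) = -y_d < 0 and defect(y_d) >= 0 since D*(1+1/K8) >= y_d there
    d = brentq(defect, 0.0, hi, xtol=1e-14, rtol=1e-13, maxiter=200)
    return _b_given_d(y_b, d, p), d, _lm_given_d(y_l, d, p)


def _invariant_jacobian(b: float, d: float, lm: float,
                        params: ParameterSet) -> np.ndarray:
    """Analytic 3x3 Jacobian d(y_B, y_D, y_L)/d(B, D, Lm)."""
    p = params
    a = 1.0 / (p.K6 * p.K8)
    c = (1.0 + d / p.K2) / p.K1
    denom = 1.0 + c * lm
    w = p.WNT0 / denom
    ik = 1.0 / (p.K1 * p.K2)
    dw_dd = -w * w * lm * ik / p.WNT0 if p.WNT0 > 0 else 0.0
    dw_dl = -c * w * w / p.WNT0 if p.WNT0 > 0 else 0.0

    j = np.empty((3, 3))
    # y_B = B + a*B*D + B*T0/(K11+B)
    j[0, 0] = 1.0 + a * d + p.TCF0 * p.K11 / (p.K11 + b) ** 2
    j[0, 1] = a * b
    j[0, 2] = 0.0
    # y_D = D*(1+1/K8) + a*B*D + W*Lm*D/(K1*K2)
    j[1, 0] = a * d
    j[1, 1] = (1.0 + 1.0 / p.K8) + a * b + lm * ik * (w + d * dw_dd)
    j[1, 2] = d * ik * (w + lm * dw_dl)
    # y_L = Lm*(1 + W*c)
    j[2, 0] = 0.0
    j[2, 1] = lm * (w * ik + c * dw_dd)
    j[2, 2] = 1.0 + w * c + lm * c * dw_dl
    return j


# ---------------------------------------------------------------------------
# reaction rates and right-hand sides
# ---------------------------------------------------------------------------

def reaction_rates(state: StateVector | Mapping[str, float],
                   params: ParameterSet,
                   fast_scale: float = FAST_SCALE) -> np.ndarray:
    """Net rate (nM/min) of each of the 26 processes at the given state.

    Rapid equilibria are reported with explicit mass-action kinetics at the
    ``fast_scale`` off-rate (zero exactly at equilibrium); process 24 uses
    the sigma-coupled assembly/disassembly rates.
    """
    s = state if isinstance(state, StateVector) else StateVector(dict(state))
    if any(s[n] < 0 for n in _CONC):
        raise ValueError("negative concentration in state")
    p = params
    # clamp sigma so root-finders may probe outside [0, 1] without tripping
    k24, km24 = aj_rates(float(np.clip(s["sigma_m"], 0.0, 1.0)),
                         float(np.clip(s["sigma_aj"], 0.0, 1.0)), p)
    r = np.empty(len(REACTIONS))
    r[0] = fast_scale * (s["wnt"] * s["lrp_m"] / p.K1 - s["wnt_lrp"])
    r[1] = fast_scale * (s["wnt_lrp"] * s["bdc"] / p.K2 - s["wnt_bdc"])
    r[2] = p.k3 * s["apc"] * s["axin_gsk"] - p.km3 * s["bdc"]
    r[3] = p.k4 * s["wnt_bdc"]
    r[4] = p.k5 * s["bcat_p"]
    r[5] = fast_scale * (s["bcat"] * s["bdc_act"] / p.K6 - s["bdc_bcat"])
    r[6] = p.k7 * s["bdc_bcat"]
    r[7] = fast_scale * (s["bdc"] / p.K8 - s["bdc_act"])
    r[8] = p.nu9
    r[9] = p.k10 * s["bcat"]
    r[10] = fast_scale * (s["bcat"] * s["tcf"] / p.K11 - s["bcat_tcf"])
    r[11] = transcription_rate(s["bcat_tcf"], p)
    r[12] = p.k13 * s["dpagt1_mrna"]
    r[13] = p.Pmax * s["dpagt1_mrna"]
    r[14] = p.nu15
    r[15] = p.k16 * s["gpt"] * s["lrp_i"]
    r[16] = p.k17 * s["lrp_i"]
    r[17] = p.k18 * s["lrp_m"]
    r[18] = p.k19 * s["gpt"]
    r[19] = p.nu20
    r[20] = p.K21 * s["ecad_er"]
    r[21] = p.k22 * s["ecad_m"]
    r[22] = p.k23 * s["ecad_erc"]
    r[23] = k24 * s["ecad_m"] - km24 * s["ecad_aj"]
    r[24] = p.k25 * s["ecad_erc"]
    r[25] = p.k26 * s["ecad_erc"]
    return r


def _rates_extended(s: StateVector, params: ParameterSet,
                    fast_scale: float = FAST_SCALE) -> np.ndarray:
    """27-entry flux vector for _S_EXT: process 24 split into its assembly
    (column 24, forward only) and disassembly (last column) arms."""
    p = params
    r = reaction_rates(s, params, fast_scale=fast_scale)
    k24, km24 = aj_rates(float(np.clip(s["sigma_m"], 0.0, 1.0)),
                         float(np.clip(s["sigma_aj"], 0.0, 1.0)), p)
    out = np.empty(len(r) + 1)
    out[:-1] = r
    out[_AJ_COL] = k24 * s["ecad_m"]
    out[-1] = km24 * s["ecad_aj"]
    return out


def _sigma_derivatives(arr: np.ndarray, params: ParameterSet) -> np.ndarray:
    """d(sigma)/dt for the four pools from instantaneous transport fluxes."""
    p = params
    g = max(arr[_IDX["gpt"]], 0.0)
    e_er = max(arr[_IDX["ecad_er"]], 0.0)
    e_m = max(arr[_IDX["ecad_m"]], 0.0)
    e_erc = max(arr[_IDX["ecad_erc"]], 0.0)
    e_aj = max(arr[_IDX["ecad_aj"]], 0.0)
    s_er, s_m, s_erc, s_aj = np.clip(arr[_SIGMA_IDX], 0.0, 1.0)
    k24, km24 = aj_rates(s_m, s_aj, p)

    # ER: fed by synthesis at the GPT-dependent glycosylation target
    # (clamped at 0 when lam > 1 would drive it negative)
    target = max(0.0, 1.0 - p.lam * g / (p.KM + g))
    ds_er = (p.nu20 / (e_er + EPS_POOL)) * (target - s_er)
    # membrane: fed from the ER and the recycling compartment
    flux_er_m = p.K21 * e_er
    flux_erc_m = p.k23 * e_erc
    ds_m = (flux_er_m * (s_er - s_m) + flux_erc_m * (s_erc - s_m)
            ) / (e_m + EPS_POOL)
    # ERC: fed by internalized membrane E-cadherin and disassembled junctions
    ds_erc = (p.k22 * e_m * (s_m - s_erc)
              + km24 * e_aj * (s_aj - s_erc)) / (e_erc + EPS_POOL)
    # AJ: fed by assembling membrane E-cadherin
    ds_aj = (k24 * e_m / (e_aj + EPS_POOL)) * (s_m - s_aj)
    return np.array([ds_er, ds_m, ds_erc, ds_aj])


def ode_rhs(t: float, y: np.ndarray, params: ParameterSet,
            fast_scale: float = FAST_SCALE) -> np.ndarray:
    """Full ODE right-hand side over all 24 state variables (FULL_ORDER).

    Rapid equilibria are explicit mass-action steps at ``fast_scale``; this
    is the unreduced system the DAE form approximates.
    """
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite state passed to ode_rhs")
    s = StateVector(np.maximum(arr, 0.0))
    r = _rates_extended(s, params, fast_scale=fast_scale)
    dy = _S_EXT @ r
    dy[_SIGMA_IDX] = _sigma_derivatives(arr, params)
    return dy


def pack_independent(state: StateVector | Mapping[str, float]) -> np.ndarray:
    """Extract the 15 independent variables as an array."""
    return np.array([float(state[n]) for n in INDEPENDENT])


def unpack_independent(x: np.ndarray) -> dict[str, float]:
    return {n: float(v) for n, v in zip(INDEPENDENT, x)}


def full_state_from_independent(x: np.ndarray,
                                params: ParameterSet) -> StateVector:
    """Resolve a 15-vector of independent variables into a full state."""
    return resolve_dependent(np.maximum(np.asarray(x, float), 0.0), params,
                             check=False)


def dae_rhs(t: float, x: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Reduced right-hand side: 15 ODEs over the independent variables.

    The slow reaction fluxes are projected onto the rapid-reaction invariants
    and mapped back to free-concentration coordinates through the analytic
    Jacobian of the invariant map, which makes the reduction exact in the
    fast-equilibrium limit.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to dae_rhs")
    xp = np.maximum(x, 0.0)
    sig_rows_ = [INDEPENDENT.index(n) for n in SIGMA]
    xp[sig_rows_] = np.clip(xp[sig_rows_], 0.0, 1.0)
    full = full_state_from_independent(xp, params)
    arr = full.as_array()
    # clamp dependent negatives (APC/AG overshoot) for rate evaluation
    arr = np.maximum(arr, 0.0)
    s = StateVector(arr)

    r = _rates_extended(s, params)
    r[_RAPID_COLS] = 0.0  # rapid processes are constraints, not fluxes
    dconc = _S_EXT @ r

    b, d, lm = s["bcat"], s["bdc"], s["lrp_m"]
    dy_b = dconc[_IDX["bcat"]] + dconc[_IDX["bdc_bcat"]] + dconc[_IDX["bcat_tcf"]]
    dy_d = (dconc[_IDX["bdc"]] + dconc[_IDX["bdc_act"]]
            + dconc[_IDX["bdc_bcat"]] + dconc[_IDX["wnt_bdc"]])
    dy_l = dconc[_IDX["lrp_m"]] + dconc[_IDX["wnt_lrp"]] + dconc[_IDX["wnt_bdc"]]

    jac = _invariant_jacobian(b, d, lm, params)
    db_dd_dl = np.linalg.solve(jac, np.array([dy_b, dy_d, dy_l]))

    dx = np.empty(len(INDEPENDENT))
    for i, name in enumerate(INDEPENDENT):
        if name == "bcat":
            dx[i] = db_dd_dl[0]
        elif name == "bdc":
            dx[i] = db_dd_dl[1]
        elif name == "lrp_m":
            dx[i] = db_dd_dl[2]
        elif name in SIGMA:
            dx[i] = 0.0  # filled below
        else:
            dx[i] = dconc[_IDX[name]]
    sig_rows = [INDEPENDENT.index(n) for n in SIGMA]
    dx[sig_rows] = _sigma_derivatives(arr, params)
    return dx
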