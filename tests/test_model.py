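"""Rate laws, rapid-equilibrium algebra and right-hand sides."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rcn.model import (FULL_ORDER, INDEPENDENT, StateVector, adhesivity_rate,
                       aj_rates, algebraic_residuals, dae_rhs,
                       er_adhesivity_rate, fast_invariants,
                       free_from_invariants, full_state_from_independent,
                       ode_rhs, pack_independent, reaction_rates,
                       resolve_dependent, transcription_rate,
                       _invariant_jacobian)
from rcn.parameters import reference_parameters
from rcn.scheme import REACTIONS


@pytest.fixture(scope="module")
def p():
    return reference_parameters()


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c,expected_frac", [
    (0.0, 0.0),           # no complex, no transcription (no basal term)
    ("K", 0.5),           # half-saturation at c = KTmRNA
    (1e9, 1.0),           # saturation at Tmax
])
def test_transcription_hill_anchors(p, c, expected_frac):
    c = p.KTmRNA if c == "K" else c
    assert transcription_rate(c, p) == pytest.approx(
        expected_frac * p.Tmax, rel=1e-6, abs=1e-15)


def test_adhesivity_rate_examples():
    assert adhesivity_rate(0.7, 0.7, 0.5) == 0.0          # fixed point
    assert adhesivity_rate(0.1, 0.9, 0.0) == 0.0          # no influx
    assert adhesivity_rate(0.2, 0.8, 0.1) == pytest.approx(0.06)
    with pytest.raises(ValueError):
        adhesivity_rate(1.4, 0.5, 0.1)
    with pytest.raises(ValueError):
        adhesivity_rate(0.5, 0.5, -1.0)


def test_er_adhesivity_rate_anchors(p):
    f = 0.2
    # no glycosylation -> fully adhesive target
    assert er_adhesivity_rate(0.3, 0.0, f, p) == pytest.approx(f * (1 - 0.3))
    # half-saturation with lam = 1
    p1 = p.with_overrides(lam=1.0)
    assert er_adhesivity_rate(0.1, p.KM, f, p1) == pytest.approx(f * (0.5 - 0.1))
    # saturating GPT with lam = 1 drives the target (and the rate) to 0
    assert er_adhesivity_rate(0.0, 1e12, f, p1) == pytest.approx(0.0, abs=1e-9)
    # lam > 1 with large GPT is a rejected parameterization
    with pytest.raises(ValueError):
        er_adhesivity_rate(0.5, 1e6, f, p.with_overrides(lam=2.0))


def test_aj_rates_linear_forms(p):
    k24, km24 = aj_rates(0.0, 0.3, p)
    assert k24 == 0.0                       # fully glycosylated membrane pool
    k24, km24 = aj_rates(0.5, 1.0, p)
    assert km24 == 0.0                      # maximally adhesive junctions
    k24, _ = aj_rates(1.0, 0.5, p)
    assert k24 == pytest.approx(p.kappa24)  # slope definition


# ---------------------------------------------------------------------------
# reaction rates
# ---------------------------------------------------------------------------

def test_reaction_rates_at_equilibrium(p, request):
    """At a resolved steady state every rapid net rate vanishes and the
    synthesis rates are the constants nu9, nu15, nu20."""
    off = request.getfixturevalue("off_state")
    r = reaction_rates(off, p)
    for rid in (1, 2, 6, 8, 11):
        assert abs(r[rid - 1]) < 1e-4, f"rapid process {rid} not at equilibrium"
    assert r[9 - 1] == p.nu9
    assert r[15 - 1] == p.nu15
    assert r[20 - 1] == p.nu20


def test_binding_rate_zero_when_all_zero(p):
    state = {n: 0.0 for n in FULL_ORDER}
    state.update({s: 0.5 for s in ("sigma_er", "sigma_m", "sigma_erc",
                                   "sigma_aj")})
    r = reaction_rates(state, p)
    # every bimolecular/rapid process has zero net rate on the empty state
    for rid in (1, 2, 3, 6, 8, 11):
        assert r[rid - 1] == 0.0
    # synthesis processes still run
    assert r[9 - 1] == p.nu9


def test_reaction_rates_reject_negative_concentration(p):
    state = {n: 1.0 for n in FULL_ORDER}
    state.update({s: 0.5 for s in ("sigma_er", "sigma_m", "sigma_erc",
                                   "sigma_aj")})
    state["bcat"] = -0.5
    with pytest.raises(ValueError, match="negative"):
        reaction_rates(state, p)


def test_ode_rhs_matches_hand_written_mass_action(p):
    """Cross-check a representative set of rows of the assembled right-hand
    side against independently hand-written rate expressions."""
    rng = np.random.default_rng(42)
    vals = dict(zip(FULL_ORDER, rng.uniform(0.1, 5.0, len(FULL_ORDER))))
    for s in ("sigma_er", "sigma_m", "sigma_erc", "sigma_aj"):
        vals[s] = rng.uniform(0.1, 0.9)
    y = np.array([vals[n] for n in FULL_ORDER])
    dy = ode_rhs(0.0, y, p)
    i = {n: j for j, n in enumerate(FULL_ORDER)}

    # phosphorylated beta-catenin: made by process 7, degraded by process 5
    assert dy[i["bcat_p"]] == pytest.approx(
        p.k7 * vals["bdc_bcat"] - p.k5 * vals["bcat_p"])
    # DPAGT1 mRNA: Hill synthesis minus first-order decay
    hill = p.Tmax * vals["bcat_tcf"] ** p.n / (
        p.KTmRNA ** p.n + vals["bcat_tcf"] ** p.n)
    assert dy[i["dpagt1_mrna"]] == pytest.approx(hill - p.k13 * vals["dpagt1_mrna"])
    # GPT: translation minus decay
    assert dy[i["gpt"]] == pytest.approx(
        p.Pmax * vals["dpagt1_mrna"] - p.k19 * vals["gpt"])
    # ER pool of E-cadherin: synthesis minus ER exit
    assert dy[i["ecad_er"]] == pytest.approx(p.nu20 - p.K21 * vals["ecad_er"])
    # junctional pool: sigma-coupled assembly/disassembly
    k24 = p.kappa24 * vals["sigma_m"]
    km24 = p.kappa24 * (1 - vals["sigma_aj"])
    assert dy[i["ecad_aj"]] == pytest.approx(
        k24 * vals["ecad_m"] - km24 * vals["ecad_aj"])
    # free beta-catenin: slow terms plus the two rapid binding steps
    from rcn.model import FAST_SCALE
    rapid6 = FAST_SCALE * (vals["bcat"] * vals["bdc_act"] / p.K6
                           - vals["bdc_bcat"])
    rapid11 = FAST_SCALE * (vals["bcat"] * vals["tcf"] / p.K11
                            - vals["bcat_tcf"])
    assert dy[i["bcat"]] == pytest.approx(
        p.nu9 - p.k10 * vals["bcat"] + p.k26 * vals["ecad_erc"]
        - rapid6 - rapid11)


# ---------------------------------------------------------------------------
# rapid-equilibrium algebra
# ---------------------------------------------------------------------------

def test_resolve_dependent_zero_partners(p):
    indep = {n: 0.0 for n in INDEPENDENT}
    state = resolve_dependent(indep, p)
    for c in ("wnt_lrp", "wnt_bdc", "bdc_act", "bdc_bcat", "bcat_tcf"):
        assert state[c] == 0.0
    # conservation puts all TCF/APC/axin free
    assert state["tcf"] == pytest.approx(p.TCF0)
    assert state["apc"] == pytest.approx(p.APC0)
    assert state["axin_gsk"] == pytest.approx(p.AXG0)


def test_resolve_dependent_residuals_small(p, off_state):
    res = algebraic_residuals(off_state, p)
    scale = max(1.0, max(abs(off_state[n]) for n in FULL_ORDER))
    assert np.all(np.abs(res) < 1e-9 * scale)


def test_resolve_dependent_degenerate_error(p):
    indep = {n: 1.0 for n in INDEPENDENT}
    indep["bdc"] = 10.0 * p.AXG0  # more complex than conserved axin allows
    with pytest.raises(ValueError, match="conserved"):
        resolve_dependent(indep, p)


def test_dependent_match_fast_equilibrium_ode(p, off_state):
    """Perturbing the rapid-complex partition and integrating the full ODE
    briefly relaxes the dependent species back to the algebraic solution."""
    y0 = off_state.as_array()
    i = {n: j for j, n in enumerate(FULL_ORDER)}
    # move half of the beta-catenin/TCF complex back to free pools
    shift = 0.5 * y0[i["bcat_tcf"]]
    y0[i["bcat_tcf"]] -= shift
    y0[i["bcat"]] += shift
    y0[i["tcf"]] += shift
    sol = solve_ivp(ode_rhs, (0.0, 0.5), y0, args=(p,), method="BDF",
                    rtol=1e-10, atol=1e-12)
    assert sol.success
    relaxed = sol.y[:, -1]
    for n in ("bcat_tcf", "tcf", "bcat"):
        assert relaxed[i[n]] == pytest.approx(off_state[n], rel=2e-3)


def test_invariant_jacobian_matches_finite_differences(p):
    b, d, lm = 20.0, 0.01, 1.5
    jac = _invariant_jacobian(b, d, lm, p)
    h = 1e-7
    num = np.empty((3, 3))
    base = np.array(fast_invariants(b, d, lm, p))
    for j, (db, dd, dl) in enumerate(np.eye(3)):
        pert = np.array(fast_invariants(b + h * db, d + h * dd, lm + h * dl, p))
        num[:, j] = (pert - base) / h
    assert np.allclose(jac, num, rtol=1e-4, atol=1e-8)


def test_free_from_invariants_round_trip(p):
    rng = np.random.default_rng(7)
    for _ in range(20):
        b = rng.uniform(0.1, 80.0)
        d = rng.uniform(1e-5, p.AXG0 * 0.8)
        lm = rng.uniform(0.01, 5.0)
        y = fast_invariants(b, d, lm, p)
        b2, d2, lm2 = free_from_invariants(*y, p)
        assert b2 == pytest.approx(b, rel=1e-8)
        assert d2 == pytest.approx(d, rel=1e-6)
        assert lm2 == pytest.approx(lm, rel=1e-8)


def test_rhs_reject_non_finite(p):
    x = np.ones(len(INDEPENDENT))
    x[0] = np.nan
    with pytest.raises(ValueError):
        dae_rhs(0.0, x, p)
    y = np.ones(len(FULL_ORDER))
    y[3] = np.inf
    with pytest.raises(ValueError):
        ode_rhs(0.0, y, p)
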