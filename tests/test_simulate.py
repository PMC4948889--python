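"""Steady states, activation time courses, fold changes and presets."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rcn.model import FULL_ORDER, INDEPENDENT, dae_rhs, pack_independent
from rcn.simulate import (WNT_OFF, WNT_ON, find_steady_state, fold_change,
                          run_preset, steady_state_time, time_course)


def test_steady_state_persists_under_reintegration(ref_params, off_state):
    x0 = pack_independent(off_state)
    sol = solve_ivp(dae_rhs, (0.0, 1000.0), x0, args=(ref_params,),
                    method="BDF", rtol=1e-10, atol=1e-12)
    assert sol.success
    drift = np.abs(sol.y[:, -1] - x0) / (np.abs(x0) + 1e-9)
    assert drift.max() < 1e-4


def test_flat_trajectory_when_wnt_unchanged(ref_params, off_state):
    traj = time_course(ref_params, initial=off_state, wnt0_on=WNT_OFF,
                       t_grid_min=[1.0, 500.0, 1440.0])
    for k in range(len(traj.times_min)):
        assert np.allclose(traj.states[k], off_state.as_array(),
                           rtol=1e-5, atol=1e-8)


def test_fold_change_identity_when_on_equals_off(ref_params, off_state):
    traj = time_course(ref_params, initial=off_state, wnt0_on=WNT_OFF,
                       t_grid_min=[100.0, 1440.0])
    fc = fold_change(traj, off_state)
    assert np.allclose(fc.to_numpy(), 1.0, rtol=1e-5)


def test_cytoplasmic_bcat_fold_above_one_after_activation(ref_params,
                                                          off_state, on_state):
    assert on_state["bcat"] / off_state["bcat"] > 1.0


def test_fold_change_rejects_zero_off_value(ref_params, off_state):
    traj = time_course(ref_params, initial=off_state,
                       t_grid_min=[100.0])
    bad = dict(off_state)
    bad["gpt"] = 0.0
    with pytest.raises(ValueError, match="zero Wnt OFF"):
        fold_change(traj, bad)


def test_fold_change_matches_independent_reintegration(ref_params, off_state):
    """Fold changes at 72 h equal those from a re-integration on a different
    grid with a different stiff method."""
    traj = time_course(ref_params, initial=off_state)
    fc = fold_change(traj, off_state, times_min=[4320.0])

    x0 = pack_independent(off_state)
    p_on = ref_params.with_overrides(WNT0=WNT_ON)
    from rcn.model import (fast_invariants, free_from_invariants,
                           full_state_from_independent)
    y = fast_invariants(off_state["bcat"], off_state["bdc"],
                        off_state["lrp_m"], ref_params)
    b, d, lm = free_from_invariants(*y, p_on)
    x0[INDEPENDENT.index("bcat")] = b
    x0[INDEPENDENT.index("bdc")] = d
    x0[INDEPENDENT.index("lrp_m")] = lm
    sol = solve_ivp(dae_rhs, (0.0, 4320.0), x0, args=(p_on,), method="Radau",
                    rtol=1e-9, atol=1e-11)
    assert sol.success
    other = full_state_from_independent(sol.y[:, -1], p_on)
    for v in ("bcat", "gpt", "ecad_aj", "sigma_aj", "dpagt1_mrna"):
        assert fc[v].iloc[0] == pytest.approx(other[v] / off_state[v],
                                              rel=1e-4)


def test_conserved_totals_constant_along_reduced_trajectory(ref_params,
                                                            off_state):
    traj = time_course(ref_params, initial=off_state,
                       t_grid_min=[1.0, 500.0, 1440.0, 4320.0])
    p_on = traj.params
    for k in range(len(traj.times_min)):
        totals = traj.state_at(traj.times_min[k]).conserved_totals()
        for name, val in totals.items():
            assert val == pytest.approx(p_on[name], rel=1e-6), name


def test_activation_reaches_steady_state_in_reported_window(ref_params):
    t_h = steady_state_time(ref_params)
    assert 0.0 < t_h < 72.0


def test_aj_fold_settles_before_adhesivity(ref_params, off_state):
    """The AJ fold change reaches its steady value earlier than the
    adhesivity fold change in the reference condition."""
    grid = np.arange(0.0, 4320.0 + 1, 30.0)
    traj = time_course(ref_params, initial=off_state, t_grid_min=grid)
    fc = fold_change(traj, off_state, variables=["ecad_aj", "sigma_aj"])

    def settle_time(series):
        # time at which the curve has covered 98% of its total excursion
        final = series.iloc[-1]
        excursion = abs(final - series.iloc[0])
        dev = np.abs(series - final) > 0.02 * excursion
        last_bad = np.nonzero(dev.to_numpy())[0]
        return series.index[last_bad[-1] + 1] if len(last_bad) else series.index[0]

    assert settle_time(fc["ecad_aj"]) < settle_time(fc["sigma_aj"])


def test_bcat_fold_monotone_in_wnt_dose(ref_params, off_state):
    """Steady-state cytoplasmic beta-catenin fold change is non-decreasing
    in total Wnt3a over [1, 28.062] nM."""
    folds = []
    for w in (1.0, 5.0, 12.0, 28.062):
        s = find_steady_state(ref_params, wnt0=w,
                              x0=pack_independent(off_state))
        folds.append(s["bcat"] / off_state["bcat"])
    assert folds[0] == pytest.approx(1.0, rel=1e-6)
    assert np.all(np.diff(folds) >= -1e-9)


class TestPresets:
    def test_reference_off_equals_steady_state(self, ref_params, off_state):
        res = run_preset("reference", "wnt_off")
        assert np.allclose(res.state.as_array(), off_state.as_array(),
                           rtol=1e-6, atol=1e-10)

    def test_dysregulated_raises_aj_and_adhesivity(self):
        """Doubling K11 (ICG-001) increases AJ abundance and adhesivity in
        both Wnt states."""
        for wnt in ("wnt_off", "wnt_on"):
            ref = run_preset("reference", wnt)
            dys = run_preset("dysregulated", wnt)
            assert dys.aj > ref.aj, wnt
            assert dys.sigma > ref.sigma, wnt

    def test_presets_deterministic(self):
        a = run_preset("reference:wnt_on")
        b = run_preset("reference", "wnt_on")
        assert np.array_equal(a.state.as_array(), b.state.as_array())

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            run_preset("nonsense", "wnt_on")
        with pytest.raises(ValueError):
            run_preset("reference", "wnt_sideways")
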