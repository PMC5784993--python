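"""Coupled muscle-tendon-load stepping: phases, termination, energetics."""

import numpy as np
import pytest

from mtcsim import (LoadSpec, MuscleSpec, SimConfig, SimState, TendonSpec,
                    ballistic_apex, hill_power_optimum, initial_equilibrium,
                    muscle_force, passive_fl_scale, run_simulation,
                    solve_step)

G = 9.81


# ---------------------------------------------------------------- ballistics

@pytest.mark.parametrize("h, v, expected", [
    (0.05, 0.0, 0.05),
    (0.0, 1.0, 1.0 / (2 * 9.81)),
    (0.02, -0.3, 0.02),  # a descending load gains no height
])
def test_ballistic_apex(h, v, expected):
    assert ballistic_apex(h, v, 9.81) == pytest.approx(expected, rel=1e-12)


def test_ballistic_apex_rejects_negative_height():
    with pytest.raises(ValueError):
        ballistic_apex(-0.01, 1.0)


# ------------------------------------------------------- initial equilibrium

def test_initial_equilibrium_no_prestrain_at_optimal_length(muscle):
    # the passive cubic is discontinuously clamped below 100% L0, so the
    # static equilibrium at a 100% start sits at (numerically) zero strain
    lm0, e0 = initial_equilibrium(muscle, TendonSpec(0.0159e9), 100.0)
    assert e0 == pytest.approx(0.0, abs=1e-12)
    assert lm0 == pytest.approx(0.10)


def test_initial_equilibrium_stretched_start_balances_passive(muscle):
    tendon = TendonSpec(0.0159e9)
    lm0, e0 = initial_equilibrium(muscle, tendon, 120.0)
    assert e0 > 0
    pct = 100.0 * lm0 / muscle.rest_length
    passive = muscle.p0_force * passive_fl_scale(pct)
    assert tendon.stiffness * e0 == pytest.approx(passive, abs=1e-9)
    assert lm0 + e0 == pytest.approx(0.12)  # geometric closure of the span


# ----------------------------------------------------------- per-step solve

def _python_residual(e_new, state, muscle, tendon, load, dt, airborne):
    """Independent pure-Python residual of the per-step force balance:
    step-average tendon force vs midpoint muscle force."""
    k = tendon.stiffness
    f_avg = 0.5 * (k * state.tendon_elongation + k * e_new)
    if airborne:
        v2 = state.load_velocity + (f_avg / load.mass - G) * dt
        y2 = state.load_height + 0.5 * (state.load_velocity + v2) * dt
    else:
        v2, y2 = 0.0, state.load_height
    de = e_new - state.tendon_elongation
    lm2 = state.muscle_length - (y2 - state.load_height) - de
    vm = (0.5 * (state.load_velocity + v2) + de / dt) / muscle.rest_length
    lm_mid = 0.5 * (state.muscle_length + lm2)
    fm = muscle_force(muscle, state.t + 0.5 * dt,
                      100.0 * lm_mid / muscle.rest_length, vm)
    return f_avg - fm


@pytest.mark.parametrize("t_grab", [0.03, 0.08, 0.15])
def test_solve_step_agrees_with_dense_grid_oracle(muscle, load_20pct,
                                                  tendon_compliant, t_grab):
    """The bisection root lies in the sign-change bracket of a dense scan."""
    cfg = SimConfig(max_time=2.0)
    trace, _ = run_simulation(muscle, tendon_compliant, load_20pct, cfg)
    df = trace.df
    i = int(np.searchsorted(df["t_s"].to_numpy(), t_grab))
    row = df.iloc[i]
    phase = {0: "caught", 1: "grounded", 2: "airborne"}[int(row.phase)]
    state = SimState(t=row.t_s, muscle_length=row.muscle_len_m,
                     tendon_elongation=row.tendon_elong_m,
                     load_height=row.load_h_m, load_velocity=row.load_v_mps,
                     force=row.force_N, phase=phase)
    new = solve_step(state, muscle, tendon_compliant, load_20pct, cfg)

    airborne = new.phase == "airborne"
    grid = np.linspace(0.0, 2.0 * new.tendon_elongation + 1e-4, 100_000)
    res = np.array([_python_residual(e, state, muscle, tendon_compliant,
                                     load_20pct, cfg.dt, airborne)
                    for e in grid])
    sign_change = np.nonzero(np.diff(np.sign(res)) != 0)[0]
    assert sign_change.size >= 1
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    assert lo <= new.tendon_elongation <= hi
    # and the residual at the accepted root is tiny
    assert abs(_python_residual(new.tendon_elongation, state, muscle,
                                tendon_compliant, load_20pct, cfg.dt,
                                airborne)) < 1e-6


def test_caught_phase_muscle_velocity_is_tendon_stretch_rate(run_catch_pair):
    """While the catch holds the load, V_m = d(elongation)/dt exactly."""
    trace, _ = run_catch_pair["compliant"]
    df = trace.df
    caught = df[df.phase == 0]
    assert len(caught) > 500  # 100 ms catch at 0.1 ms steps
    de_dt = np.diff(caught.tendon_elong_m.to_numpy()) / 1e-4
    vm = caught.vm_mps.to_numpy()[1:]
    assert np.allclose(vm, de_dt, atol=1e-9)
    assert np.all(caught.load_v_mps.to_numpy() == 0.0)


def test_rigid_limit_muscle_velocity_tracks_load(muscle, load_20pct):
    """In the rigid limit the tendon stretch rate vanishes: V_m ~ v_load
    (step-average velocities, since V_m is a per-step quantity)."""
    tendon = TendonSpec(youngs_modulus=5e9, cross_sectional_area=4e-2)
    assert tendon.stiffness == pytest.approx(1e10)
    trace, _ = run_simulation(muscle, tendon, load_20pct,
                              SimConfig(max_time=1.0))
    df = trace.df
    air = (df.phase == 2).to_numpy()
    v = df.load_v_mps.to_numpy()
    v_avg = 0.5 * (v[1:] + v[:-1])
    vm = df.vm_mps.to_numpy()[1:]
    both_air = air[1:] & air[:-1]
    diff = np.abs(vm[both_air] - v_avg[both_air]) / muscle.rest_length
    assert diff.max() < 1e-6  # lengths per second


# ------------------------------------------------------------- whole runs

def test_heavy_load_never_lifts(muscle, tendon_rigid):
    """A load heavier than any achievable force terminates cleanly at 0."""
    heavy = LoadSpec(mass=3.0)  # 29.4 N > P0 * (1.05 + 0.05)
    _, res = run_simulation(muscle, tendon_rigid, heavy,
                            SimConfig(max_time=2.0, record_trace=False))
    assert res.apex_height == 0.0
    assert res.termination_reason == "stalled"
    assert res.peak_load_velocity == 0.0


def test_peak_mtc_power_bounded_by_hill_power_no_catch(muscle, load_20pct,
                                                       tendon_rigid):
    """Without catch or recoil the MTC cannot beat the muscle's isotonic
    power optimum P0 * L0 * max(v fv(v))."""
    _, res = run_simulation(muscle, tendon_rigid, load_20pct,
                            SimConfig(max_time=2.0, record_trace=False))
    _, p_opt = hill_power_optimum(muscle.hill_a_rel, muscle.hill_b)
    bound = muscle.p0_force * muscle.rest_length * p_opt
    assert bound == pytest.approx(2.60, abs=0.01)
    assert res.peak_mtc_power <= bound * (1 + 1e-9)


def test_energy_closure(run_catch_pair):
    """Muscle work = load KE + load PE + tendon elastic energy, audited
    from the kinematics independently of the work bookkeeping."""
    for label in ("compliant", "rigid"):
        trace, res = run_catch_pair[label]
        df = trace.df
        k_t = df.force_N.iloc[-1] / df.tendon_elong_m.iloc[-1]
        final = df.iloc[-1]
        ke = 0.5 * 0.100 * final.load_v_mps ** 2
        pe = 0.100 * G * final.load_h_m
        tendon_e = 0.5 * k_t * (final.tendon_elong_m ** 2
                                - df.tendon_elong_m.iloc[0] ** 2)
        w = res.total_muscle_work
        assert abs(w - (ke + pe + tendon_e)) / w < 0.005


def test_work_height_identity_for_flight_terminated_run(muscle,
                                                        tendon_rigid):
    """m g apex = work done on the load when the run ends mid-flight."""
    load = LoadSpec(mass=0.01214)
    trace, res = run_simulation(muscle, tendon_rigid, load,
                                SimConfig(max_time=2.0))
    assert res.termination_reason in ("force_zero", "active_force_exhausted")
    w_load = trace.df.work_load_J.iloc[-1]
    assert load.mass * G * res.apex_height == pytest.approx(w_load, rel=5e-3)


def test_work_split_sums_to_total(run_catch_pair):
    for label in ("compliant", "rigid"):
        _, res = run_catch_pair[label]
        assert res.work_before_release + res.work_after_release == \
            pytest.approx(res.total_muscle_work, rel=1e-12)


def test_stiffness_sufficiency_bitwise(muscle, load_20pct):
    """Tendons with identical E*A/L give bit-identical traces."""
    cfg = SimConfig(max_time=1.0)
    base = TendonSpec(youngs_modulus=0.0159e9, rest_length=0.02,
                      cross_sectional_area=0.95e-6)
    same_k = [
        TendonSpec(youngs_modulus=2 * 0.0159e9, rest_length=0.02,
                   cross_sectional_area=0.95e-6 / 2),
        TendonSpec(youngs_modulus=0.0159e9 / 2, rest_length=0.01,
                   cross_sectional_area=0.95e-6),
    ]
    t0, r0 = run_simulation(muscle, base, load_20pct, cfg)
    for other in same_k:
        assert other.stiffness == base.stiffness  # exact fp equality
        t1, r1 = run_simulation(muscle, other, load_20pct, cfg)
        assert r1.apex_height == r0.apex_height
        assert np.array_equal(t0.df.force_N.to_numpy(),
                              t1.df.force_N.to_numpy())
        assert np.array_equal(t0.df.load_h_m.to_numpy(),
                              t1.df.load_h_m.to_numpy())


def _no_tendon_reference(muscle, load, dt=1e-4, max_time=2.0):
    """Analytically reduced model: muscle welded straight onto the load.

    Grounded: isometric force rise until it exceeds the weight. Airborne:
    solve m (v2 - v) = (F(t2, L - dy, v2) - m g) dt for v2 by bisection.
    Pure Python, independent of the package's stepping kernel.
    """
    t, lm, y, v = 0.0, muscle.rest_length, 0.0, 0.0
    apex = 0.0
    L0 = muscle.rest_length
    while t < max_time:
        t2 = t + dt
        if v == 0.0 and y == 0.0:
            f = muscle_force(muscle, t2, 100.0 * lm / L0, 0.0)
            if f <= load.mass * G:
                t = t2
                continue
        lo, hi = v - 10.0, v + 10.0

        def resid(v2):
            lm2 = lm - v2 * dt
            f2 = muscle_force(muscle, t2, 100.0 * lm2 / L0, v2 / L0)
            return load.mass * (v2 - v) - (f2 - load.mass * G) * dt

        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if resid(mid) < 0:
                lo = mid
            else:
                hi = mid
        v2 = 0.5 * (lo + hi)
        lm2 = lm - v2 * dt
        y2 = y + v2 * dt
        f2 = muscle_force(muscle, t2, 100.0 * lm2 / L0, v2 / L0)
        apex = max(apex, ballistic_apex(max(y2, 0.0), v2))
        t, lm, y, v = t2, lm2, y2, v2
        from mtcsim import active_fl_scale
        if active_fl_scale(100.0 * lm / L0) <= 0 or f2 <= 1e-7:
            break
    return apex


def test_rigid_limit_matches_no_tendon_reduction(muscle):
    """A 5 GPa tendon behaves like no tendon at all (independent model)."""
    load = LoadSpec(mass=0.01214)
    _, res = run_simulation(muscle, TendonSpec(youngs_modulus=5e9), load,
                            SimConfig(max_time=2.0, record_trace=False))
    apex_ref = _no_tendon_reference(muscle, load)
    assert res.apex_height == pytest.approx(apex_ref, rel=5e-3)


def test_dt_halving_convergence(muscle):
    """Halving the step changes the apex by < 0.1%."""
    tendon = TendonSpec(youngs_modulus=0.0159e9)
    load = LoadSpec(mass=0.100, catch_delay=0.100)
    apexes = []
    for dt in (1e-4, 5e-5):
        _, res = run_simulation(muscle, tendon, load,
                                SimConfig(dt=dt, max_time=2.0,
                                          record_trace=False))
        apexes.append(res.apex_height)
    assert abs(apexes[1] - apexes[0]) / apexes[0] < 1e-3


def test_short_catch_is_null_at_default_load(muscle, tendon_compliant,
                                             load_20pct):
    """Catch delays shorter than the time activation needs to reach the
    load-supporting force change nothing; longer delays add height."""
    cfg = SimConfig(max_time=2.0, record_trace=False)
    base = run_simulation(muscle, tendon_compliant, load_20pct, cfg)[1]
    short = run_simulation(
        muscle, tendon_compliant,
        LoadSpec(mass=load_20pct.mass, catch_delay=0.020), cfg)[1]
    assert short.apex_height == pytest.approx(base.apex_height, rel=1e-9)
    longer = run_simulation(
        muscle, tendon_compliant,
        LoadSpec(mass=load_20pct.mass, catch_delay=0.200), cfg)[1]
    assert longer.apex_height > base.apex_height * 1.02


def test_apex_not_below_final_height(run_20pct_compliant):
    trace, res = run_20pct_compliant
    assert res.apex_height >= trace.df.load_h_m.iloc[-1] - 1e-12
    assert res.apex_height >= trace.df.load_h_m.max() - 1e-12


def test_cumulative_work_nondecreasing_while_powered(run_20pct_compliant):
    trace, _ = run_20pct_compliant
    df = trace.df
    powered = df.p_muscle_W.to_numpy()[1:] >= 0
    dw = np.diff(df.work_muscle_J.to_numpy())
    assert np.all(dw[powered] >= -1e-12)


def test_stretched_start_with_catch_boosts_lift(muscle, load_20pct):
    """Starting at 120% L0 with a long catch stores extra tendon strain
    (passive pre-strain plus the descending-limb start) and lifts higher
    than the same contraction from optimal length."""
    tendon = TendonSpec(youngs_modulus=0.00909e9)
    load = LoadSpec(mass=load_20pct.mass, catch_delay=0.5)
    results = {}
    for pct in (100.0, 120.0):
        _, results[pct] = run_simulation(
            muscle, tendon, load,
            SimConfig(max_time=2.0, record_trace=False,
                      initial_muscle_length_pct=pct))
    assert results[120.0].apex_height > 1.5 * results[100.0].apex_height
    # the stretched start pre-strains the tendon against passive force
    lm0, e0 = initial_equilibrium(muscle, tendon, 120.0)
    assert e0 > 1e-3


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(dt=0.0)
    with pytest.raises(ValueError):
        SimConfig(initial_muscle_length_pct=160.0)
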