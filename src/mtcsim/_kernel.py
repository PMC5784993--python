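"""JIT-compiled fixed-step integration kernel for the muscle-tendon-load system.

Each 100 us step solves a scalar root problem in the new tendon elongation
``e``: the Hookean tendon force ``k e`` must equal the muscle force evaluated
at the end-of-step muscle length and shortening velocity, which themselves
depend on ``e`` through the load update and the geometric closure
(muscle shortening = load rise + tendon elongation change). The residual
``k e - F_muscle(e)`` is strictly increasing in ``e`` (the 1/dt velocity
sensitivity dominates), so a bracketed Illinois (modified regula falsi)
search finds the unique root.

The load update is implicit-trapezoidal: the step-average tendon force
drives the velocity update and the step-average velocity drives the
position update, so trapezoid work integrals match the load's energy change
exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# phases
CAUGHT = 0
GROUNDED = 1
AIRBORNE = 2

# termination / step status codes
STEP_OK = 0
TERM_ACTIVE_EXHAUSTED = 1
TERM_FORCE_ZERO = 2
TERM_MAX_TIME = 3
TERM_STALLED = 4
TERM_NO_CONVERGENCE = 5

# trace columns
NCOL = 16
(COL_T, COL_F, COL_LM, COL_E, COL_Y, COL_V, COL_ACT, COL_FL, COL_FV,
 COL_VM, COL_PMUSC, COL_PMTC, COL_WMUSC, COL_ESTORED, COL_WLOAD,
 COL_PHASE) = range(NCOL)


@njit(cache=True)
def _muscle_force(t, lm, vm_mps, p0f, L0, afl, pfl, a_rel, b, act_t, act_a,
                  afl_peak):
    """Muscle force and its scaling factors; ``fla_raw`` keeps the sign of
    the active force-length cubic for the shortening-limit test."""
    pct = 100.0 * lm / L0
    act = np.interp(t, act_t, act_a)
    fla_raw = (afl[0] + pct * (afl[1] + pct * (afl[2] + pct * afl[3]))) / afl_peak
    fla = fla_raw if fla_raw > 0.0 else 0.0
    fp = 0.0
    if pct >= 100.0:
        fp = pfl[0] + pct * (pfl[1] + pct * (pfl[2] + pct * pfl[3]))
        if fp < 0.0:
            fp = 0.0
    v = vm_mps / L0
    if v <= 0.0:
        fv = 1.0
    else:
        fv = b * (1.0 + a_rel) / (v + b) - a_rel
        if fv < 0.0:
            fv = 0.0
        elif fv > 1.0:
            fv = 1.0
    return p0f * (act * fla * fv + fp), act, fla_raw, fv


@njit(cache=True)
def _fla_raw(lm, L0, afl, afl_peak):
    pct = 100.0 * lm / L0
    return (afl[0] + pct * (afl[1] + pct * (afl[2] + pct * afl[3]))) \
        / afl_peak


@njit(cache=True)
def _trial(e_new, t2, phase, e, y, v, lm, dt, k, m, g, p0f, L0, afl, pfl,
           a_rel, b, act_t, act_a, afl_peak):
    """Midpoint residual of a candidate end-of-step elongation: the
    step-average tendon force minus the muscle force at the step midpoint.
    Returns the end-of-step state the candidate implies."""
    f_avg = 0.5 * (k * e + k * e_new)
    if phase == AIRBORNE:
        # trapezoidal load update: the step-average tendon force drives the
        # velocity, the step-average velocity the position, which makes
        # trapezoid work integrals identical to the load's KE + PE change
        v2 = v + (f_avg / m - g) * dt
        y2 = y + 0.5 * (v + v2) * dt
    else:
        v2 = 0.0
        y2 = y
    de = e_new - e
    lm2 = lm - (y2 - y) - de
    # step-average muscle shortening velocity (m/s, shortening positive);
    # in the caught/grounded phases this reduces to de/dt exactly
    vm = 0.5 * (v + v2) + de / dt
    fm, act, fla_raw, fv = _muscle_force(t2 - 0.5 * dt, 0.5 * (lm + lm2),
                                         vm, p0f, L0, afl, pfl, a_rel, b,
                                         act_t, act_a, afl_peak)
    return f_avg - fm, v2, y2, lm2, vm, act, fla_raw, fv


@njit(cache=True)
def advance(t, dt, phase, e, y, v, lm, k, m, g, catch_delay, p0f, L0, afl,
            pfl, a_rel, b, act_t, act_a, afl_peak, tol, allow_zero):
    """One fixed step: phase transitions, root solve, end-of-step state.

    Returns ``(status, phase, e2, y2, v2, lm2, vm, act, fla_raw, fv)``;
    ``fla_raw`` is the (unclamped) active force-length factor at the
    end-of-step muscle length, used for the shortening-limit test.
    ``allow_zero`` permits a zero-force step instead of termination while
    the muscle has not yet produced any force (early activation).
    On ``TERM_FORCE_ZERO`` / ``TERM_NO_CONVERGENCE`` the incoming state is
    returned unchanged (no step is taken).
    """
    # release the catch once the delay has elapsed, then lift off as soon as
    # the tendon force exceeds the load's weight
    if phase == CAUGHT and t >= catch_delay - 1e-12:
        phase = GROUNDED
    if phase == GROUNDED and k * e > m * g:
        phase = AIRBORNE
    t2 = t + dt

    for _attempt in range(2):
        r0, v2, y2, lm2, vm, act, fla_raw, fv = _trial(
            0.0, t2, phase, e, y, v, lm, dt, k, m, g, p0f, L0, afl, pfl,
            a_rel, b, act_t, act_a, afl_peak)
        if r0 >= 0.0:
            if allow_zero and phase != AIRBORNE:
                # activation has not produced force yet: idle zero-force step
                fla0 = _fla_raw(lm, L0, afl, afl_peak)
                return STEP_OK, phase, 0.0, y, 0.0, lm + e, 0.0, act, fla0, fv
            # even a fully recoiled tendon carries no tension: the muscle
            # can no longer generate force
            return TERM_FORCE_ZERO, phase, e, y, v, lm, 0.0, act, fla_raw, fv

        # bracket the root: expand upward from the previous elongation
        lo = 0.0
        flo = r0
        hi = e * 1.5 if e > 1e-8 else 1e-8
        fhi = 0.0
        found = False
        for _ in range(200):
            fhi, v2, y2, lm2, vm, act, fla_raw, fv = _trial(
                hi, t2, phase, e, y, v, lm, dt, k, m, g, p0f, L0, afl, pfl,
                a_rel, b, act_t, act_a, afl_peak)
            if fhi >= 0.0:
                found = True
                break
            lo = hi
            flo = fhi
            hi *= 2.0
            if hi > 2.0:  # elongation beyond any physical reach
                break
        if not found:
            return TERM_NO_CONVERGENCE, phase, e, y, v, lm, 0.0, act, fla_raw, fv

        # Illinois method on [lo, hi]
        em = hi
        fm_r = fhi
        side = 0
        for _ in range(300):
            if abs(fm_r) < tol or (hi - lo) < 1e-18 + 1e-16 * hi:
                break
            denom = fhi - flo
            if denom != 0.0:
                em = hi - fhi * (hi - lo) / denom
            else:
                em = 0.5 * (lo + hi)
            if not (lo < em < hi):
                em = 0.5 * (lo + hi)
            fm_r, v2, y2, lm2, vm, act, fla_raw, fv = _trial(
                em, t2, phase, e, y, v, lm, dt, k, m, g, p0f, L0, afl, pfl,
                a_rel, b, act_t, act_a, afl_peak)
            if fm_r > 0.0:
                hi = em
                fhi = fm_r
                if side == 1:
                    flo *= 0.5
                side = 1
            else:
                lo = em
                flo = fm_r
                if side == -1:
                    fhi *= 0.5
                side = -1

        # evaluate the accepted step at the root
        _, v2, y2, lm2, vm, act, fla_raw, fv = _trial(
            em, t2, phase, e, y, v, lm, dt, k, m, g, p0f, L0, afl, pfl,
            a_rel, b, act_t, act_a, afl_peak)
        if phase == AIRBORNE and y2 < 0.0:
            # the load cannot fall below its resting position: re-solve the
            # step with the ground supplying the reaction
            phase = GROUNDED
            continue
        fla_end = _fla_raw(lm2, L0, afl, afl_peak)
        return STEP_OK, phase, em, y2, v2, lm2, vm, act, fla_end, fv

    # grounded re-solve cannot descend, so this is unreachable in practice
    return TERM_NO_CONVERGENCE, phase, e, y, v, lm, 0.0, 0.0, 0.0, 0.0


@njit(cache=True)
def simulate(k, m, g, catch_delay, p0f, L0, afl, pfl, a_rel, b, act_t, act_a,
             afl_peak, dt, max_time, lm0, e0, tol, record):
    """Full run from rest. Returns the trace array (``n`` rows used), the
    termination code, and the scalar outcome summary."""
    n_max = int(max_time / dt) + 2
    rows = n_max + 1 if record else 2
    tr = np.zeros((rows, NCOL))

    t = 0.0
    phase = CAUGHT if catch_delay > 0.0 else GROUNDED
    e = e0
    y = 0.0
    v = 0.0
    lm = lm0
    force = k * e0
    f_eps = 1e-7 * p0f  # force resolution below which the muscle is spent

    w_musc = 0.0
    w_load = 0.0
    e_stored = 0.0
    w_before = 0.0
    peak_pmtc = 0.0
    peak_pmusc = 0.0
    peak_v = 0.0
    apex = 0.0  # running max of the instantaneous ballistic apex
    t_apex = 0.0  # time the apex last improved

    fm0, act0, fla0, fv0 = _muscle_force(0.0, lm, 0.0, p0f, L0, afl, pfl,
                                         a_rel, b, act_t, act_a, afl_peak)
    tr[0, COL_T] = 0.0
    tr[0, COL_F] = force
    tr[0, COL_LM] = lm
    tr[0, COL_E] = e
    tr[0, COL_ACT] = act0
    tr[0, COL_FL] = fla0 if fla0 > 0.0 else 0.0
    tr[0, COL_FV] = fv0
    tr[0, COL_PHASE] = phase
    n = 1

    term = TERM_MAX_TIME
    act_end = act_t[-1]
    had_force = force > f_eps
    while t < max_time - 0.5 * dt:
        status, phase, e2, y2, v2, lm2, vm, act, fla_raw, fv = advance(
            t, dt, phase, e, y, v, lm, k, m, g, catch_delay, p0f, L0, afl,
            pfl, a_rel, b, act_t, act_a, afl_peak, tol, not had_force)
        if status != STEP_OK:
            term = status
            break
        t2 = t + dt
        f2 = k * e2
        if f2 > f_eps:
            had_force = True
        de = e2 - e
        dy = y2 - y
        f_avg = 0.5 * (force + f2)
        w_musc += f_avg * (dy + de)
        w_load += f_avg * dy
        e_stored += f_avg * de
        if t2 <= catch_delay + 1e-12:
            w_before = w_musc
        p_musc = f2 * vm
        p_mtc = f2 * v2
        if p_mtc > peak_pmtc:
            peak_pmtc = p_mtc
        if p_musc > peak_pmusc:
            peak_pmusc = p_musc
        if v2 > peak_v:
            peak_v = v2
        if phase == AIRBORNE:
            inst = y2 + v2 * v2 / (2.0 * g) if v2 > 0.0 else y2
            if inst > apex:
                apex = inst
                t_apex = t2

        ri = n if record else 1
        tr[ri, COL_T] = t2
        tr[ri, COL_F] = f2
        tr[ri, COL_LM] = lm2
        tr[ri, COL_E] = e2
        tr[ri, COL_Y] = y2
        tr[ri, COL_V] = v2
        tr[ri, COL_ACT] = act
        tr[ri, COL_FL] = fla_raw if fla_raw > 0.0 else 0.0
        tr[ri, COL_FV] = fv
        tr[ri, COL_VM] = vm
        tr[ri, COL_PMUSC] = p_musc
        tr[ri, COL_PMTC] = p_mtc
        tr[ri, COL_WMUSC] = w_musc
        tr[ri, COL_ESTORED] = e_stored
        tr[ri, COL_WLOAD] = w_load
        tr[ri, COL_PHASE] = phase
        n += 1

        t = t2
        e = e2
        y = y2
        v = v2
        lm = lm2
        force = f2

        if fla_raw <= 0.0:
            term = TERM_ACTIVE_EXHAUSTED
            break
        if had_force and f2 < f_eps:
            term = TERM_FORCE_ZERO
            break
        if (phase != AIRBORNE and t > act_end and abs(de) < 1e-14
                and f2 <= m * g):
            # activation saturated, strain static, force below the weight:
            # the load can never lift
            term = TERM_STALLED
            break
        if phase == AIRBORNE and t > act_end:
            if abs(v2) < 1e-9 and abs(de) < 1e-14:
                # settled into a static hover (force equals weight)
                term = TERM_STALLED
                break
            if t - t_apex > 0.5:
                # activation saturated and the apex has not improved for
                # half a second of damped bouncing: it never will
                term = TERM_STALLED
                break

    n_used = n if record else min(n, 2)
    return (tr[:n_used], n, term, apex, peak_pmtc, peak_pmusc, w_musc,
            w_before, peak_v, t, phase, e, y, v, lm, force, e_stored, w_load)
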