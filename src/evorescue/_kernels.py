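"""Numba kernels for the exact (Gillespie) and tau-leaping simulators.

The nine event channels, in fixed order:

    0  sensitive birth        (+1,  0,  0)   rate lam_bs * s
    1  sensitive death        (-1,  0,  0)   rate (mu_s + lam_s n/K) * s
    2  missegregation         ( 0, +1,  0)   rate u lam_s * s
    3  sensitive mutation     ( 0,  0, +1)   rate v lam_s * s
    4  aneuploid birth        ( 0, +1,  0)   rate lam_ba * a
    5  aneuploid death        ( 0, -1,  0)   rate (mu_a + lam_a n/K) * a
    6  aneuploid mutation     ( 0,  0, +1)   rate v_a lam_a * a
    7  mutant birth           ( 0,  0, +1)   rate lam_m * m
    8  mutant death           ( 0,  0, -1)   rate (mu_m + lam_m n/K) * m

Missegregation and mutation add a daughter of the new type and leave the
parent count unchanged.  ``lam_bs`` / ``lam_ba`` are the birth rates
actually used (by default equal to ``lam_s`` / ``lam_a``; optionally
reduced by the (1-u-v) / (1-v_a) division factors).  ``inv_k = 1/K`` is 0
for density-independent growth.

The exact kernel additionally tags every mutant-founding event as a new
lineage and tracks lineage sizes, so the *rescue time* -- the birth time
of the first mutant lineage still alive when the establishment threshold
is crossed -- can be recorded.

Outcome codes: 0 extinct, 1 rescued, 2 recurred, 3 censored.
"""

import numpy as np
from numba import njit

_LINEAGE_CAP = 8192


@njit(cache=True)
def ssa_run(
    lam_bs, mu_s, lam_ba, mu_a, lam_m, mu_m,
    ulam_s, vlam_s, valam_a,
    lam_s, lam_a, inv_k,
    s0, a0, m0,
    m_establish, m_recur, m_detect,
    t_max, max_events, seed,
    rec_times,
):
    np.random.seed(seed)
    s = s0
    a = a0
    m = m0
    t = 0.0
    counts = np.zeros(9, dtype=np.int64)

    n_rec = rec_times.shape[0]
    rec_s = np.zeros(n_rec, dtype=np.int64)
    rec_a = np.zeros(n_rec, dtype=np.int64)
    rec_m = np.zeros(n_rec, dtype=np.int64)
    i_rec = 0

    lin_birth = np.zeros(_LINEAGE_CAP, dtype=np.float64)
    lin_size = np.zeros(_LINEAGE_CAP, dtype=np.int64)
    n_lin = 0
    lin_ok = True

    nan = np.nan
    rescue_time = nan
    establish_time = nan
    recur_time = nan
    detect_time = nan
    first_mut_time = nan

    stop_m = m_establish
    if m_recur > stop_m:
        stop_m = m_recur
    if m_detect > stop_m:
        stop_m = m_detect

    outcome = 3  # censored unless a terminating condition fires
    events = 0

    # initial state may already satisfy a condition
    if s + a + m == 0:
        outcome = 0
    while outcome == 3:
        if m >= stop_m:
            break
        tot_cells = s + a + m
        dens = inv_k * tot_cells
        r0 = lam_bs * s
        r1 = (mu_s + lam_s * dens) * s
        r2 = ulam_s * s
        r3 = vlam_s * s
        r4 = lam_ba * a
        r5 = (mu_a + lam_a * dens) * a
        r6 = valam_a * a
        r7 = lam_m * m
        r8 = (mu_m + lam_m * dens) * m
        total = r0 + r1 + r2 + r3 + r4 + r5 + r6 + r7 + r8

        dt = np.random.exponential(1.0 / total)
        t_new = t + dt
        if t_new > t_max:
            # record grid points up to t_max with the current (held) state
            while i_rec < n_rec and rec_times[i_rec] <= t_max:
                rec_s[i_rec] = s
                rec_a[i_rec] = a
                rec_m[i_rec] = m
                i_rec += 1
            t = t_max
            outcome = 3
            break
        # state holds on [t, t_new)
        while i_rec < n_rec and rec_times[i_rec] < t_new:
            rec_s[i_rec] = s
            rec_a[i_rec] = a
            rec_m[i_rec] = m
            i_rec += 1
        t = t_new

        x = np.random.random() * total
        if x < r0:
            s += 1
            counts[0] += 1
        elif x < r0 + r1:
            s -= 1
            counts[1] += 1
        elif x < r0 + r1 + r2:
            a += 1
            counts[2] += 1
        elif x < r0 + r1 + r2 + r3:
            m += 1
            counts[3] += 1
            if np.isnan(first_mut_time):
                first_mut_time = t
            if lin_ok:
                if n_lin < _LINEAGE_CAP:
                    lin_birth[n_lin] = t
                    lin_size[n_lin] = 1
                    n_lin += 1
                else:
                    lin_ok = False
        elif x < r0 + r1 + r2 + r3 + r4:
            a += 1
            counts[4] += 1
        elif x < r0 + r1 + r2 + r3 + r4 + r5:
            a -= 1
            counts[5] += 1
        elif x < r0 + r1 + r2 + r3 + r4 + r5 + r6:
            m += 1
            counts[6] += 1
            if np.isnan(first_mut_time):
                first_mut_time = t
            if lin_ok:
                if n_lin < _LINEAGE_CAP:
                    lin_birth[n_lin] = t
                    lin_size[n_lin] = 1
                    n_lin += 1
                else:
                    lin_ok = False
        elif x < r0 + r1 + r2 + r3 + r4 + r5 + r6 + r7:
            counts[7] += 1
            if lin_ok and m > 0:
                y = np.random.random() * m
                acc = 0.0
                for i in range(n_lin):
                    acc += lin_size[i]
                    if y < acc:
                        lin_size[i] += 1
                        break
            m += 1
        else:
            counts[8] += 1
            if lin_ok and m > 0:
                y = np.random.random() * m
                acc = 0.0
                for i in range(n_lin):
                    acc += lin_size[i]
                    if y < acc:
                        lin_size[i] -= 1
                        break
            m -= 1

        events += 1

        if m >= m_establish and np.isnan(establish_time):
            establish_time = t
            if lin_ok:
                best = np.inf
                for i in range(n_lin):
                    if lin_size[i] > 0 and lin_birth[i] < best:
                        best = lin_birth[i]
                if np.isfinite(best):
                    rescue_time = best
        if m_recur > 0 and m >= m_recur and np.isnan(recur_time):
            recur_time = t
        if m_detect > 0 and m >= m_detect and np.isnan(detect_time):
            detect_time = t

        if m >= stop_m:
            outcome = 2 if (m_recur > 0 and not np.isnan(recur_time)) else 1
            break
        if s + a + m == 0:
            outcome = 0
            break
        if events >= max_events:
            outcome = 3
            break

    if outcome == 0:
        # extinction is absorbing: remaining grid points hold the zero state
        while i_rec < n_rec and rec_times[i_rec] <= t_max:
            rec_s[i_rec] = s
            rec_a[i_rec] = a
            rec_m[i_rec] = m
            i_rec += 1
    if outcome == 1 and m_recur <= 0 and np.isnan(establish_time):
        establish_time = t

    return (
        t, s, a, m, outcome, events, counts,
        rescue_time, establish_time, recur_time, detect_time, first_mut_time,
        rec_s, rec_a, rec_m, i_rec, lin_ok,
    )


@njit(cache=True)
def tau_leap_run_kernel(
    lam_bs, mu_s, lam_ba, mu_a, lam_m, mu_m,
    ulam_s, vlam_s, valam_a,
    lam_s, lam_a, inv_k,
    s0, a0, m0,
    m_establish, m_recur, m_detect,
    t_max, max_events, seed, step,
    rec_times,
):
    """Tau-leaping: Poisson event counts per channel over fixed steps.

    Negative genotype counts are clamped to zero after each leap.  No
    lineage tagging: the rescue time is reported as the first time a
    mutant appeared, for rescued runs only.
    """
    np.random.seed(seed)
    s = s0
    a = a0
    m = m0
    t = 0.0
    counts = np.zeros(9, dtype=np.int64)

    n_rec = rec_times.shape[0]
    rec_s = np.zeros(n_rec, dtype=np.int64)
    rec_a = np.zeros(n_rec, dtype=np.int64)
    rec_m = np.zeros(n_rec, dtype=np.int64)
    i_rec = 0

    nan = np.nan
    establish_time = nan
    recur_time = nan
    detect_time = nan
    first_mut_time = nan

    stop_m = m_establish
    if m_recur > stop_m:
        stop_m = m_recur
    if m_detect > stop_m:
        stop_m = m_detect

    outcome = 3
    events = 0
    if s + a + m == 0:
        outcome = 0

    while outcome == 3:
        if m >= stop_m:
            break
        if t >= t_max:
            break
        while i_rec < n_rec and rec_times[i_rec] <= t:
            rec_s[i_rec] = s
            rec_a[i_rec] = a
            rec_m[i_rec] = m
            i_rec += 1

        tot_cells = s + a + m
        dens = inv_k * tot_cells
        n0 = np.random.poisson(lam_bs * s * step)
        n1 = np.random.poisson((mu_s + lam_s * dens) * s * step)
        n2 = np.random.poisson(ulam_s * s * step)
        n3 = np.random.poisson(vlam_s * s * step)
        n4 = np.random.poisson(lam_ba * a * step)
        n5 = np.random.poisson((mu_a + lam_a * dens) * a * step)
        n6 = np.random.poisson(valam_a * a * step)
        n7 = np.random.poisson(lam_m * m * step)
        n8 = np.random.poisson((mu_m + lam_m * dens) * m * step)
        counts[0] += n0
        counts[1] += n1
        counts[2] += n2
        counts[3] += n3
        counts[4] += n4
        counts[5] += n5
        counts[6] += n6
        counts[7] += n7
        counts[8] += n8
        events += n0 + n1 + n2 + n3 + n4 + n5 + n6 + n7 + n8

        s += n0 - n1
        a += n2 + n4 - n5
        m += n3 + n6 + n7 - n8
        if s < 0:
            s = 0
        if a < 0:
            a = 0
        if m < 0:
            m = 0
        t += step

        if m > 0 and np.isnan(first_mut_time):
            first_mut_time = t
        if m >= m_establish and np.isnan(establish_time):
            establish_time = t
        if m_recur > 0 and m >= m_recur and np.isnan(recur_time):
            recur_time = t
        if m_detect > 0 and m >= m_detect and np.isnan(detect_time):
            detect_time = t

        if m >= stop_m:
            outcome = 2 if (m_recur > 0 and not np.isnan(recur_time)) else 1
            break
        if s + a + m == 0:
            outcome = 0
            break
        if events >= max_events:
            break

    while i_rec < n_rec and rec_times[i_rec] <= min(t, t_max):
        rec_s[i_rec] = s
        rec_a[i_rec] = a
        rec_m[i_rec] = m
        i_rec += 1

    return (
        t, s, a, m, outcome, events, counts,
        establish_time, recur_time, detect_time, first_mut_time,
        rec_s, rec_a, rec_m, i_rec,
    )
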