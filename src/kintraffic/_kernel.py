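"""Numba kernel for the Gillespie simulation of the ring lattice gas.

Implements the continuous-time Markov chain exactly: at each step the six
channel-class rates (hop, attach, spontaneous detach, facilitated detach,
inactivate, activate) are summed from incrementally maintained counts, an
exponential waiting time is drawn, a class is chosen proportionally to its
rate and a uniformly random member of the class is selected by rejection
sampling.  After every event only the flags of the sites and motors in the
neighbourhood of the event are recomputed (each recomputation is idempotent,
so overlapping refreshes are safe); a full recount used for validation lives
in :func:`recount_channels`.

Conventions: ``occ[s]`` holds the motor slot occupying site ``s`` (-1 when
empty) and ``isfront[s]`` distinguishes front from back heads.  A motor with
front head at ``i`` has its back head at ``i-1`` (mod L).  ``pe[i]`` flags
that the pair ``(i-1, i)`` is empty, i.e. a dimer could land with its front
head at ``i``.  Unwrapped positions are ``attach_site + steps`` so ring
wrap-around never corrupts run lengths.
"""

import numpy as np
from numba import njit

# detach causes recorded in run records
CAUSE_SPONTANEOUS = 0
CAUSE_FACILITATED = 1
CAUSE_TRUNCATED = 2


@njit(cache=True)
def _refresh_pe(i, occ, pe, L):
    new = occ[i] == -1 and occ[(i - 1) % L] == -1
    if new != pe[i]:
        pe[i] = new
        return 1 if new else -1
    return 0


@njit(cache=True)
def _refresh_motor(m, occ, isfront, front, active, can_hop, fac, L):
    t = (front[m] + 1) % L
    ch = active[m] and occ[t] == -1
    fc = occ[t] != -1 and (not isfront[t])
    d_hop = (1 if ch else 0) - (1 if can_hop[m] else 0)
    d_fac = (1 if fc else 0) - (1 if fac[m] else 0)
    can_hop[m] = ch
    fac[m] = fc
    return d_hop, d_fac


@njit(cache=True)
def _touch(s, occ, isfront, front, active, can_hop, fac, pe, L):
    """Refresh all flags that depend on the occupancy of site ``s``."""
    d_pe = _refresh_pe(s, occ, pe, L)
    d_pe += _refresh_pe((s + 1) % L, occ, pe, L)
    d_hop = 0
    d_fac = 0
    p = (s - 1) % L
    if occ[p] != -1 and isfront[p]:
        a, b = _refresh_motor(occ[p], occ, isfront, front, active,
                              can_hop, fac, L)
        d_hop += a
        d_fac += b
    if occ[s] != -1 and isfront[s]:
        a, b = _refresh_motor(occ[s], occ, isfront, front, active,
                              can_hop, fac, L)
        d_hop += a
        d_fac += b
    return d_pe, d_hop, d_fac


@njit(cache=True)
def recount_channels(occ, isfront, front, active, can_hop, fac, pe,
                     blist, n_bound, L):
    """Recompute channel counts from scratch (validation path)."""
    n_hop = 0
    n_fac = 0
    n_pe = 0
    for i in range(L):
        if occ[i] == -1 and occ[(i - 1) % L] == -1:
            n_pe += 1
    for idx in range(n_bound):
        m = blist[idx]
        t = (front[m] + 1) % L
        if active[m] and occ[t] == -1:
            n_hop += 1
        if occ[t] != -1 and not isfront[t]:
            n_fac += 1
    return n_hop, n_fac, n_pe


@njit(cache=True)
def run_kernel(L, nu, omega_A, omega_D, theta, r_in, r_act,
               t_end, burn_in, frame_dt, frame_start_k, record_frames,
               seed, initial_fronts,
               run_uid, run_t0, run_t1, run_site0, run_steps, run_cause,
               fr_uid, fr_k, fr_pos, fr_active):
    np.random.seed(seed)
    cap = L // 2

    occ = np.full(L, -1, np.int32)
    isfront = np.zeros(L, np.bool_)
    front = np.full(cap, -1, np.int32)
    active = np.zeros(cap, np.bool_)
    steps = np.zeros(cap, np.int64)
    attach_t = np.zeros(cap, np.float64)
    attach_site = np.zeros(cap, np.int32)
    uid = np.full(cap, -1, np.int64)

    can_hop = np.zeros(cap, np.bool_)
    fac = np.zeros(cap, np.bool_)
    pe = np.zeros(L, np.bool_)

    # free-slot stack and dense bound list for O(1) uniform sampling
    free_stack = np.empty(cap, np.int32)
    for k in range(cap):
        free_stack[k] = cap - 1 - k
    n_free = cap
    blist = np.empty(cap, np.int32)
    bpos = np.full(cap, -1, np.int32)
    n_bound = 0
    n_act = 0

    n_hop = 0
    n_fac = 0
    n_pe = 0
    for i in range(L):
        pe[i] = True
    n_pe = L

    uid_counter = 0
    run_count = 0
    frame_count = 0
    frames_dropped = 0
    runs_dropped = 0

    # place any initial motors (active) at time zero
    for fi in initial_fronts:
        m = free_stack[n_free - 1]
        n_free -= 1
        f = fi % L
        b = (f - 1) % L
        occ[f] = m
        occ[b] = m
        isfront[f] = True
        front[m] = f
        active[m] = True
        steps[m] = 0
        attach_t[m] = 0.0
        attach_site[m] = f
        uid[m] = uid_counter
        uid_counter += 1
        blist[n_bound] = m
        bpos[m] = n_bound
        n_bound += 1
        n_act += 1
        d_pe, d_hop, d_fac = _touch(b, occ, isfront, front, active,
                                    can_hop, fac, pe, L)
        n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
        d_pe, d_hop, d_fac = _touch(f, occ, isfront, front, active,
                                    can_hop, fac, pe, L)
        n_pe += d_pe; n_hop += d_hop; n_fac += d_fac

    t = 0.0
    frame_k = 0
    nframes_total = int(np.floor(t_end / frame_dt)) + 1

    acc_bound = 0.0
    acc_pe = 0.0
    hops_measured = 0
    attach_count = 0
    det_s_count = 0
    det_f_count = 0

    while True:
        R = (nu * n_hop + omega_A * n_pe + omega_D * n_bound
             + theta * n_fac + r_in * n_act + r_act * (n_bound - n_act))
        if R > 0.0:
            dt = -np.log(np.random.random()) / R
        else:
            dt = t_end - t + 1.0
        t_new = t + dt

        # frames fall strictly inside the waiting interval, so the state at
        # a frame time is the current state
        while frame_k < nframes_total and frame_k * frame_dt <= t_new:
            if record_frames and frame_k >= frame_start_k:
                for idx in range(n_bound):
                    m = blist[idx]
                    if frame_count < fr_uid.shape[0]:
                        fr_uid[frame_count] = uid[m]
                        fr_k[frame_count] = frame_k
                        fr_pos[frame_count] = attach_site[m] + steps[m]
                        fr_active[frame_count] = active[m]
                        frame_count += 1
                    else:
                        frames_dropped += 1
            frame_k += 1

        # time-average accumulators over the part of the waiting interval
        # inside the measurement window [burn_in, t_end]
        lo = t if t > burn_in else burn_in
        hi = t_new if t_new < t_end else t_end
        if hi > lo:
            acc_bound += (hi - lo) * n_bound
            acc_pe += (hi - lo) * n_pe

        if t_new >= t_end or R <= 0.0:
            break
        t = t_new

        r = np.random.random() * R
        edge = nu * n_hop
        if r < edge:
            # --- hop ---
            while True:
                m = blist[int(np.random.random() * n_bound)]
                if can_hop[m]:
                    break
            i = front[m]
            b = (i - 1) % L
            tg = (i + 1) % L
            occ[b] = -1
            isfront[i] = False
            occ[tg] = m
            isfront[tg] = True
            front[m] = tg
            steps[m] += 1
            if t >= burn_in:
                hops_measured += 1
            d_pe, d_hop, d_fac = _touch(b, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            d_pe, d_hop, d_fac = _touch(i, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            d_pe, d_hop, d_fac = _touch(tg, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            continue
        r -= edge
        edge = omega_A * n_pe
        if r < edge:
            # --- attach (front head at i, back at i-1) ---
            while True:
                i = int(np.random.random() * L)
                if pe[i]:
                    break
            m = free_stack[n_free - 1]
            n_free -= 1
            b = (i - 1) % L
            occ[i] = m
            occ[b] = m
            isfront[i] = True
            front[m] = i
            active[m] = True
            steps[m] = 0
            attach_t[m] = t
            attach_site[m] = i
            uid[m] = uid_counter
            uid_counter += 1
            blist[n_bound] = m
            bpos[m] = n_bound
            n_bound += 1
            n_act += 1
            attach_count += 1
            d_pe, d_hop, d_fac = _touch(b, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            d_pe, d_hop, d_fac = _touch(i, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            continue
        r -= edge
        edge = omega_D * n_bound
        cause = -1
        if r < edge:
            m = blist[int(np.random.random() * n_bound)]
            cause = CAUSE_SPONTANEOUS
        else:
            r -= edge
            edge = theta * n_fac
            if r < edge:
                while True:
                    m = blist[int(np.random.random() * n_bound)]
                    if fac[m]:
                        break
                cause = CAUSE_FACILITATED
        if cause >= 0:
            # --- detach ---
            if run_count < run_uid.shape[0]:
                run_uid[run_count] = uid[m]
                run_t0[run_count] = attach_t[m]
                run_t1[run_count] = t
                run_site0[run_count] = attach_site[m]
                run_steps[run_count] = steps[m]
                run_cause[run_count] = cause
                run_count += 1
            else:
                runs_dropped += 1
            if cause == CAUSE_SPONTANEOUS:
                det_s_count += 1
            else:
                det_f_count += 1
            i = front[m]
            b = (i - 1) % L
            occ[i] = -1
            occ[b] = -1
            isfront[i] = False
            if can_hop[m]:
                can_hop[m] = False
                n_hop -= 1
            if fac[m]:
                fac[m] = False
                n_fac -= 1
            if active[m]:
                n_act -= 1
            # swap-remove from bound list, return slot
            last = blist[n_bound - 1]
            pos = bpos[m]
            blist[pos] = last
            bpos[last] = pos
            bpos[m] = -1
            n_bound -= 1
            front[m] = -1
            free_stack[n_free] = m
            n_free += 1
            d_pe, d_hop, d_fac = _touch(b, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            d_pe, d_hop, d_fac = _touch(i, occ, isfront, front, active,
                                        can_hop, fac, pe, L)
            n_pe += d_pe; n_hop += d_hop; n_fac += d_fac
            continue
        r -= edge
        edge = r_in * n_act
        if r < edge:
            # --- inactivate ---
            while True:
                m = blist[int(np.random.random() * n_bound)]
                if active[m]:
                    break
            active[m] = False
            n_act -= 1
            d_hop, d_fac = _refresh_motor(m, occ, isfront, front, active,
                                          can_hop, fac, L)
            n_hop += d_hop; n_fac += d_fac
            continue
        # --- activate ---
        while True:
            m = blist[int(np.random.random() * n_bound)]
            if not active[m]:
                break
        active[m] = True
        n_act += 1
        d_hop, d_fac = _refresh_motor(m, occ, isfront, front, active,
                                      can_hop, fac, L)
        n_hop += d_hop; n_fac += d_fac

    # close still-bound runs as truncated
    for idx in range(n_bound):
        m = blist[idx]
        if run_count < run_uid.shape[0]:
            run_uid[run_count] = uid[m]
            run_t0[run_count] = attach_t[m]
            run_t1[run_count] = t_end
            run_site0[run_count] = attach_site[m]
            run_steps[run_count] = steps[m]
            run_cause[run_count] = CAUSE_TRUNCATED
            run_count += 1
        else:
            runs_dropped += 1

    # consistency sweep: recount and compare (cheap, once per run)
    chk_hop, chk_fac, chk_pe = recount_channels(
        occ, isfront, front, active, can_hop, fac, pe, blist, n_bound, L)
    consistent = (chk_hop == n_hop and chk_fac == n_fac and chk_pe == n_pe)

    return (run_count, frame_count, acc_bound, acc_pe, hops_measured,
            attach_count, det_s_count, det_f_count,
            frames_dropped, runs_dropped, consistent)
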