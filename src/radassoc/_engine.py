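"""Compiled Monte Carlo engine.

Implements the fixed-time-step clone dynamics of :mod:`radassoc.clones` as
numba kernels that simulate whole persons.  The per-step law is identical to
the reference operations: one multinomial over divide/die/transform/stay per
clone per step, with coupled clones stepped under both worlds' parameters —
by independent draws compared for equality (default) or by death-thinning —
until they fork.  Three exact accelerations keep the cost proportional to
the number of *events* rather than the number of steps:

* clone initiation times are drawn from the homogeneous Poisson process per
  constant-rate segment instead of one Poisson draw per step;
* malignant transformation (per-cell probability ``mu*dt``, ~1e-8) is
  sampled as a geometric number of cell-trials until the first success;
  each step consumes ``m`` trials.  Conditional on no transformation the
  division/death probabilities are ``alpha*dt/(1-mu*dt)`` and
  ``beta*dt/(1-mu*dt)``.  By memorylessness a fresh geometric draw per
  simulation phase is exact;
* for small clones the division/death events are likewise sampled from the
  per-cell Bernoulli trial stream (m trials per step) with geometric gaps
  between successes, so whole event-free steps are skipped; chopping an
  i.i.d. Bernoulli stream into m-trial blocks gives exactly Binomial(m, p)
  events per step.

All three are distributionally identical to stepping through every step.
Clones are processed in birth order and each clone's simulation is capped at
the person's currently earliest shared transformation: later events cannot
change the two recorded first cancers.

Status codes: 0 = extinct, 1 = reached the phase end, 2 = transformed,
3 = forked; 4/5 (independent coupling only) = forked with a simultaneous
spontaneous-only / radiation-only transformation.  Event ages are assigned
to the end of the step in which they occur.

Randomness is numba's per-thread legacy NumPy state, re-seeded per person
from a 32-bit seed array, so cohorts are reproducible and order-independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf

# coupling schemes
THINNING = 0
INDEPENDENT = 1

# model mechanisms
KIND_INITIATION = 0
KIND_PROMO_INST = 1
KIND_PROMO_LL = 2

#: clone sizes up to this use the geometric event-skip fast path
_SMALL = 16


@njit(cache=True)
def _sim_single(m, t0, t_end, alpha, beta, mu, dt):
    """Evolve one uncoupled lineage from (t0, m) to t_end.

    Returns (status, t, m): extinct at t / survived to t_end with m cells /
    first transformed at t.
    """
    if m <= 0:
        return 0, t0, 0
    nsteps = int(np.ceil((t_end - t0) / dt - 1e-12))
    if nsteps <= 0:
        return 1, t_end, m
    pm = mu * dt
    pa = alpha * dt / (1.0 - pm)
    pb = beta * dt / (1.0 - pm)
    pev = pa + pb
    if pev <= 0.0 and pm <= 0.0:
        return 1, t_end, m
    # cell-trials until the first malignant transformation
    B = np.random.geometric(pm) if pm > 0.0 else np.int64(2) ** 62
    if pev <= 0.0:
        k_tr = (B + m - 1) // m
        if k_tr <= nsteps:
            return 2, t0 + k_tr * dt, m
        return 1, t_end, m
    ca = pa / pev
    inv_lq = 1.0 / np.log(1.0 - pev)
    pb1 = pb / (1.0 - pa)
    G = np.int64(0)  # live gap to the next division/death trial success
    k = 0
    while k < nsteps:
        if m == 0:
            return 0, t0 + k * dt, 0
        if G == 0 and m <= _SMALL:
            G = np.int64(np.log(1.0 - np.random.random()) * inv_lq) + 1
        if G > 0:
            # stream mode: jump to the step holding the next success
            kG = (G + m - 1) // m
            kB = (B + m - 1) // m
            if kB <= kG:
                if k + kB <= nsteps:
                    return 2, t0 + (k + kB) * dt, m
                return 1, t_end, m
            if k + kG > nsteps:
                return 1, t_end, m
            B -= kG * m
            k += kG
            pos = G - (kG - 1) * m  # trial index of the success, 1..m
            births = 0
            deaths = 0
            if np.random.random() < ca:
                births += 1
            else:
                deaths += 1
            rem = m - pos
            if m <= _SMALL:
                # gap-walk any further successes within this step
                G = np.int64(np.log(1.0 - np.random.random()) * inv_lq) + 1
                while G <= rem:
                    rem -= G
                    if np.random.random() < ca:
                        births += 1
                    else:
                        deaths += 1
                    G = np.int64(np.log(1.0 - np.random.random()) * inv_lq) + 1
                G -= rem
            else:
                # drain the unrevealed remainder of the step binomially
                extra = np.random.binomial(rem, pev) if rem > 0 else 0
                if extra > 0:
                    be = np.random.binomial(extra, ca)
                    births += be
                    deaths += extra - be
                G = np.int64(0)
            m += births - deaths
        else:
            # per-step binomial mode (large clones)
            if B <= m:
                return 2, t0 + (k + 1) * dt, m
            B -= m
            na = np.random.binomial(m, pa)
            nb = np.random.binomial(m - na, pb1)
            k += 1
            m += na - nb
    if m == 0:
        return 0, t_end, 0
    return 1, t_end, m


@njit(cache=True)
def _sim_single_ramp(m, t0, t_end, alpha, beta_start, beta_slope, mu, dt):
    """Uncoupled lineage with linearly time-varying beta (plain stepping)."""
    if m <= 0:
        return 0, t0, 0
    nsteps = int(np.ceil((t_end - t0) / dt - 1e-12))
    pm = mu * dt
    pa = alpha * dt / (1.0 - pm)
    budget = np.random.geometric(pm) if pm > 0.0 else np.int64(2 ** 62)
    for k in range(nsteps):
        if m == 0:
            return 0, t0 + k * dt, 0
        if budget <= m:
            return 2, t0 + (k + 1) * dt, m
        budget -= m
        pb = (beta_start + beta_slope * (k * dt)) * dt / (1.0 - pm)
        na = np.random.binomial(m, pa)
        nb = np.random.binomial(m - na, pb / (1.0 - pa))
        m += na - nb
    if m == 0:
        return 0, t_end, 0
    return 1, t_end, m


@njit(cache=True)
def _sim_coupled(m, t0, t_end, alpha, beta0, mu, beta_rad_start,
                 beta_rad_slope, dt, scheme):
    """Evolve an unforked clone in both worlds until fork/transform/end.

    beta_rad(t) = beta_rad_start + beta_rad_slope * (t - t0); deaths are
    drawn at the spontaneous rate beta0 and thinned for the radiation
    lineage (default scheme).  Returns (status, t, m_spont, m_rad); for
    status 2 (shared transformation) both worlds develop the malignancy at
    t; for status 3 the sizes just diverged.
    """
    if m <= 0:
        return 0, t0, 0, 0
    nsteps = int(np.ceil((t_end - t0) / dt - 1e-12))
    if nsteps <= 0:
        return 1, t_end, m, m
    pm = mu * dt

    if scheme == INDEPENDENT:
        pa_ = alpha * dt
        pb0_ = beta0 * dt
        for k in range(nsteps):
            if m == 0:
                return 0, t0 + k * dt, 0, 0
            br = beta_rad_start + beta_rad_slope * (k * dt)
            pbr_ = br * dt
            na_s = np.random.binomial(m, pa_)
            nb_s = np.random.binomial(m - na_s, pb0_ / (1.0 - pa_))
            nm_s = np.random.binomial(m - na_s - nb_s, pm / (1.0 - pa_ - pb0_))
            na_r = np.random.binomial(m, pa_)
            nb_r = np.random.binomial(m - na_r, pbr_ / (1.0 - pa_))
            nm_r = np.random.binomial(m - na_r - nb_r, pm / (1.0 - pa_ - pbr_))
            t = t0 + (k + 1) * dt
            if nm_s > 0 and nm_r > 0:
                return 2, t, m, m
            ms = m + na_s - nb_s
            mr = m + na_r - nb_r
            if nm_s > 0:
                return 4, t, m, mr
            if nm_r > 0:
                return 5, t, ms, m
            if ms != mr:
                return 3, t, ms, mr
            m = ms
        if m == 0:
            return 0, t_end, 0, 0
        return 1, t_end, m, m

    # thinning scheme: divisions and transformations are shared, deaths are
    # drawn at beta0 and accepted for the radiation lineage w.p. br/beta0
    pa = alpha * dt / (1.0 - pm)
    pb0 = beta0 * dt / (1.0 - pm)
    pev = pa + pb0
    ca = pa / pev
    inv_lq = 1.0 / np.log(1.0 - pev)
    pb1 = pb0 / (1.0 - pa)
    accept = beta_rad_start / beta0
    c_both = ca + (1.0 - ca) * accept
    use_stream = beta_rad_slope == 0.0
    B = np.random.geometric(pm) if pm > 0.0 else np.int64(2) ** 62
    G = np.int64(0)
    k = 0
    while k < nsteps:
        if m == 0:
            return 0, t0 + k * dt, 0, 0
        if G == 0 and m <= _SMALL and use_stream:
            G = np.int64(np.log(1.0 - np.random.random()) * inv_lq) + 1
        if G > 0:
            kG = (G + m - 1) // m
            kB = (B + m - 1) // m
            if kB <= kG:
                if k + kB <= nsteps:
                    return 2, t0 + (k + kB) * dt, m, m
                return 1, t_end, m, m
            if k + kG > nsteps:
                return 1, t_end, m, m
            B -= kG * m
            k += kG
            pos = G - (kG - 1) * m
            births = 0
            die_both = 0
            die_sp = 0
            u2 = np.random.random()
            if u2 < ca:
                births += 1
            elif u2 < c_both:
                die_both += 1
            else:
                die_sp += 1
            rem = m - pos
            if m <= _SMALL:
                G = np.int64(np.log(1.0 - np.random.random()) * inv_lq) + 1
                while G <= rem:
                    rem -= G
                    u2 = np.random.random()
                    if u2 < ca:
                        births += 1
                    elif u2 < c_both:
                        die_both += 1
                    else:
                        die_sp += 1
                    G = np.int64(np.log(1.0 - np.random.random()) * inv_lq) + 1
                G -= rem
            else:
                extra = np.random.binomial(rem, pev) if rem > 0 else 0
                if extra > 0:
                    na_e = np.random.binomial(extra, ca)
                    nd_e = extra - na_e
                    nacc_e = np.random.binomial(nd_e, accept) if nd_e > 0 else 0
                    births += na_e
                    die_both += nacc_e
                    die_sp += nd_e - nacc_e
                G = np.int64(0)
            if die_sp > 0:
                return (3, t0 + k * dt,
                        m + births - die_both - die_sp,
                        m + births - die_both)
            m += births - die_both
        else:
            if B <= m:
                return 2, t0 + (k + 1) * dt, m, m
            B -= m
            br = beta_rad_start + beta_rad_slope * (k * dt)
            na = np.random.binomial(m, pa)
            nd = np.random.binomial(m - na, pb1)
            nacc = np.random.binomial(nd, br / beta0) if nd > 0 else 0
            k += 1
            if nd > nacc:
                return 3, t0 + k * dt, m + na - nd, m + na - nacc
            m += na - nd
    if m == 0:
        return 0, t_end, 0, 0
    return 1, t_end, m, m


@njit(cache=True)
def _initiation_clone(b, t_end, alpha, beta, mu, dt):
    """Full life of an uncoupled clone born at b; returns transform age or inf."""
    st, t, m = _sim_single(1, b, t_end, alpha, beta, mu, dt)
    if st == 2:
        return t
    return INF


@njit(cache=True)
def _promotion_clone(kind, b, alpha, beta0, mu, slope, d, dtot,
                     es, ee, t_end, cap_sp, cap_rad, dt, scheme):
    """Full life of a spontaneously initiated clone under a promotion-type
    radiation effect.

    ``t_end`` caps the shared (pre-fork) phases; ``cap_sp``/``cap_rad`` cap
    the post-fork lineages (transformations beyond a cap cannot change the
    person's recorded outcome).  Returns (t_shared, t_sp, t_rad): first
    transformation age of the coupled both-worlds lineage, of the post-fork
    spontaneous-only lineage, and of the post-fork radiation-associated
    lineage (inf if none).
    """
    t_shared = INF
    t_sp = INF
    t_rad = INF
    m = 1
    t = b

    # -- phase 1: before the radiation action (both worlds identical)
    if t < es:
        end1 = es if es < t_end else t_end
        st, t1, m = _sim_single(m, t, end1, alpha, beta0, mu, dt)
        if st == 0:
            return t_shared, t_sp, t_rad
        if st == 2:
            return t1, t_sp, t_rad
        if end1 >= t_end:
            return t_shared, t_sp, t_rad
        t = es

    # -- phase 2: coupled stepping while the radiation action differs
    if kind == KIND_PROMO_INST:
        if t < ee:
            end2 = ee if ee < t_end else t_end
            br = beta0 - slope * d
            st, t2, ms, mr = _sim_coupled(m, t, end2, alpha, beta0, mu,
                                          br, 0.0, dt, scheme)
            if st == 0:
                return t_shared, t_sp, t_rad
            if st == 2:
                return t2, t_sp, t_rad
            if st == 1:
                if end2 >= t_end:
                    return t_shared, t_sp, t_rad
                # unforked at exposure end: worlds identical again
                st3, t3, m3 = _sim_single(ms, ee, t_end, alpha, beta0, mu, dt)
                if st3 == 2:
                    return t3, t_sp, t_rad
                return t_shared, t_sp, t_rad
            # forked (st 3/4/5)
            if st == 4:
                t_sp = t2
                ms = 0
            if st == 5:
                t_rad = t2
                mr = 0
            # spontaneous lineage: baseline rates for the rest of life
            if ms > 0 and t2 < cap_sp:
                st3, t3, m3 = _sim_single(ms, t2, cap_sp, alpha, beta0, mu, dt)
                if st3 == 2:
                    t_sp = t3
            # radiation lineage: reduced beta until exposure end, then baseline
            if mr > 0 and t2 < cap_rad:
                endr = ee if ee < cap_rad else cap_rad
                st4, t4, m4 = _sim_single(mr, t2, endr, alpha, br, mu, dt)
                if st4 == 2:
                    t_rad = t4
                elif st4 == 1 and endr < cap_rad:
                    st5, t5, m5 = _sim_single(m4, ee, cap_rad, alpha, beta0,
                                              mu, dt)
                    if st5 == 2:
                        t_rad = t5
            return t_shared, t_sp, t_rad
        # born after the exposure: never any radiation action
        st, t1, m = _sim_single(m, t, t_end, alpha, beta0, mu, dt)
        if st == 2:
            return t1, t_sp, t_rad
        return t_shared, t_sp, t_rad

    # kind == KIND_PROMO_LL: coupled for the rest of life
    b_ll = beta0 - slope * dtot
    ms = 0
    mr = 0
    t2 = t
    forked = False
    if t < ee:
        # dose still accumulating: beta_rad ramps down linearly
        end2 = ee if ee < t_end else t_end
        br0 = beta0 - slope * d * (t - es)
        st, t2, ms, mr = _sim_coupled(m, t, end2, alpha, beta0, mu,
                                      br0, -slope * d, dt, scheme)
        if st == 0:
            return t_shared, t_sp, t_rad
        if st == 2:
            return t2, t_sp, t_rad
        if st == 1:
            if end2 >= t_end:
                return t_shared, t_sp, t_rad
            m = ms
            t = ee
            t2 = ee
        else:
            forked = True
            if st == 4:
                t_sp = t2
                ms = 0
            if st == 5:
                t_rad = t2
                mr = 0
            if mr > 0 and t2 < cap_rad:
                # radiation lineage: finish the ramp, then the lifelong beta
                endr = ee if ee < cap_rad else cap_rad
                br1 = beta0 - slope * d * (t2 - es)
                st4, t4, m4 = _sim_single_ramp(mr, t2, endr, alpha, br1,
                                               -slope * d, mu, dt)
                if st4 == 2:
                    t_rad = t4
                elif st4 == 1 and endr < cap_rad:
                    st5, t5, m5 = _sim_single(m4, ee, cap_rad, alpha, b_ll,
                                              mu, dt)
                    if st5 == 2:
                        t_rad = t5
    if not forked:
        # constant lifelong reduction from max(birth, exposure end)
        st, t2, ms, mr = _sim_coupled(m, t, t_end, alpha, beta0, mu,
                                      b_ll, 0.0, dt, scheme)
        if st == 0 or st == 1:
            return t_shared, t_sp, t_rad
        if st == 2:
            return t2, t_sp, t_rad
        if st == 4:
            t_sp = t2
            ms = 0
        if st == 5:
            t_rad = t2
            mr = 0
        if mr > 0 and t2 < cap_rad:
            st4, t4, m4 = _sim_single(mr, t2, cap_rad, alpha, b_ll, mu, dt)
            if st4 == 2:
                t_rad = t4
    # post-fork spontaneous lineage (common to both branches above)
    if ms > 0 and t2 < cap_sp:
        st3, t3, m3 = _sim_single(ms, t2, cap_sp, alpha, beta0, mu, dt)
        if st3 == 2:
            t_sp = t3
    return t_shared, t_sp, t_rad


@njit(cache=True)
def _simulate_person(kind, n_nu0, alpha, beta0, mu, slope, d, dtot,
                     es, ee, t_end, dt, scheme):
    """One person, both worlds.  Returns first transformation ages
    (t_shared, t_sp, t_rad): shared = occurs identically in both worlds,
    t_sp = counterfactual-world only (post-fork spontaneous lineage),
    t_rad = exposed-world radiation-associated lineage.
    """
    t_shared = INF
    t_sp = INF
    t_rad = INF

    no_dose = d == 0.0 or dtot == 0.0
    n = np.random.poisson(n_nu0 * t_end)
    births = np.random.random(n) * t_end
    births.sort()
    for i in range(n):
        b = births[i]
        if b >= t_shared:
            break  # cannot change either recorded first cancer
        if kind == KIND_INITIATION or no_dose:
            cap = t_end if t_end < t_shared else t_shared
            tt = _initiation_clone(b, cap, alpha, beta0, mu, dt)
            if tt < t_shared:
                t_shared = tt
        else:
            cap = t_end if t_end < t_shared else t_shared
            cap_sp = cap if cap < t_sp else t_sp
            cap_rad = cap if cap < t_rad else t_rad
            ts, tp, tr = _promotion_clone(kind, b, alpha, beta0, mu, slope,
                                          d, dtot, es, ee, cap, cap_sp,
                                          cap_rad, dt, scheme)
            if ts < t_shared:
                t_shared = ts
            if tp < t_sp:
                t_sp = tp
            if tr < t_rad:
                t_rad = tr

    # radiation-induced excess initiation during exposure (exposed world only)
    if kind == KIND_INITIATION and not no_dose:
        excess_rate = n_nu0 * slope * d
        dur = min(ee, t_end) - es
        if dur > 0.0:
            ne = np.random.poisson(excess_rate * dur)
            for _ in range(ne):
                b = es + np.random.random() * dur
                cap = t_shared if t_shared < t_rad else t_rad
                if t_end < cap:
                    cap = t_end
                if b >= cap:
                    continue
                tt = _initiation_clone(b, cap, alpha, beta0, mu, dt)
                if tt < t_rad:
                    t_rad = tt
    return t_shared, t_sp, t_rad


@njit(cache=True)
def one_step_census(seeds, alpha, beta, mu, dt):
    """Tally one-step transitions of a single-cell clone, one per seed:
    (grew, died, stayed, transformed).  Test support."""
    counts = np.zeros(4, dtype=np.int64)
    for i in range(seeds.shape[0]):
        np.random.seed(seeds[i])
        st, t, m = _sim_single(1, 0.0, dt, alpha, beta, mu, dt)
        if st == 2:
            counts[3] += 1
        elif st == 0:
            counts[1] += 1
        elif m == 2:
            counts[0] += 1
        else:
            counts[2] += 1
    return counts


@njit(cache=True)
def simulate_chunk(seeds, kind, n_nu0, alpha, beta0, mu, slope, d, dtot,
                   es, ee, t_end, dt, scheme, out_shared, out_sp, out_rad):
    """Simulate one person per seed, filling the output arrays."""
    for i in range(seeds.shape[0]):
        np.random.seed(seeds[i])
        ts, tp, tr = _simulate_person(kind, n_nu0, alpha, beta0, mu, slope,
                                      d, dtot, es, ee, t_end, dt, scheme)
        out_shared[i] = ts
        out_sp[i] = tp
        out_rad[i] = tr
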