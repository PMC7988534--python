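"""Event-driven dynamics kernel (numba).

Everything here operates on flat numpy arrays packed by :mod:`absheet.engine`.
Beads move ballistically; the kernel maintains an event heap of analytically
predicted discontinuity crossings:

* hard-core collisions (stable quadratic roots),
* square-well edges for sidechain pairs (capture / escape / inner reflection),
* directional NH...CO hydrogen-bond wells (formation gated by four
  auxiliary-bead distances, one bond per donor and per acceptor),
* bond / pseudobond hard walls,
* cell-list crossings (neighbour bookkeeping only),
* Andersen-thermostat ghost collisions (Poisson stream, Maxwell-Boltzmann
  resampling).

Positions are updated lazily (per bead, at its own events); events carry the
per-bead event counters ("stamps") at scheduling time and are discarded as
stale if a participant has moved on.  All randomness comes from an internal
splitmix64 counter so that identical (config, seed) reproduce the event
sequence exactly.

Units: length A, mass u, energy eps_HB, time tau = A sqrt(u / eps_HB).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event kinds
EV_CORE = 0      # hard-core bounce
EV_SCWELL = 1    # sidechain square-well edge (capture/escape decided on the fly)
EV_HB = 2        # hydrogen-bond well edge (formation attempt or break attempt)
EV_BOND = 3      # bond / pseudobond hard wall
EV_CELL = 4      # cell-list crossing
EV_GHOST = 5     # thermostat ghost collision (global stream)

# bead kinds (match model.py)
K_NH, K_CA, K_CO, K_SC = 0, 1, 2, 3

# iscal layout
I_HEAPN = 0
I_NEVENT = 1     # physical events (core, well, hb, bond, ghost)
I_NCELL = 2
I_ERR = 3
I_HBFORM = 4
I_HBBREAK = 5
I_NCORE = 6
I_WELLIN = 7
I_WELLESC = 8
I_WELLREFL = 9
I_NBOND = 10
I_NGHOST = 11
I_NSTALE = 12
I_HBATTEMPT = 13
NSCAL_I = 16

# fscal layout
F_CLOCK = 0
F_PE = 1
F_NEXT_GHOST = 2
NSCAL_F = 4

STATUS_OK = 0
STATUS_TIME_REGRESSION = 1
STATUS_EVENT_BUDGET = 2
STATUS_HEAP_FULL = 3

_TINY = 1e-12
_EDGE = 1e-9
# floor on post-reflection radial speed (A/tau): breaks tangent-graze
# freezes; the kinetic-energy perturbation is ~mu*V_MIN^2/2 ~ 1e-15 eps_HB,
# far below the 1e-9/event conservation budget
V_MIN = 1e-8


@njit(cache=True, inline="always")
def _next_u64(rng):
    rng[0] = rng[0] + np.uint64(0x9E3779B97F4A7C15)
    z = rng[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rand_u(rng):
    # uniform in (0, 1)
    return (np.float64(_next_u64(rng) >> np.uint64(11)) + 0.5) * (2.0 ** -53)


@njit(cache=True, inline="always")
def _rand_norm(rng):
    u1 = _rand_u(rng)
    u2 = _rand_u(rng)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True, inline="always")
def _mi(d, L):
    return d - L * np.rint(d / L)


# --- event heap ---------------------------------------------------------------

@njit(cache=True, inline="always")
def _enc1(k, i, j):
    # kind in 4 bits, bead ids (+1, so -1 is representable) in 21 bits each
    return (np.int64(k) << 42) | (np.int64(i + 1) << 21) | np.int64(j + 1)


@njit(cache=True, inline="always")
def _enc2(si, sj):
    return ((si & 0xFFFFFFFF) << 32) | (sj & 0xFFFFFFFF)


@njit(cache=True)
def _hpush(ht, hm1, hm2, iscal, t, k, i, j, si, sj):
    n = iscal[I_HEAPN]
    if n >= ht.shape[0]:
        return False
    ht[n] = t
    hm1[n] = _enc1(k, i, j)
    hm2[n] = _enc2(si, sj)
    c = n
    while c > 0:
        p = (c - 1) >> 1
        if ht[p] <= ht[c]:
            break
        ht[p], ht[c] = ht[c], ht[p]
        hm1[p], hm1[c] = hm1[c], hm1[p]
        hm2[p], hm2[c] = hm2[c], hm2[p]
        c = p
    iscal[I_HEAPN] = n + 1
    return True


@njit(cache=True)
def _hpop(ht, hm1, hm2, iscal):
    n = iscal[I_HEAPN] - 1
    t = ht[0]
    m1 = hm1[0]
    m2 = hm2[0]
    ht[0] = ht[n]; hm1[0] = hm1[n]; hm2[0] = hm2[n]
    iscal[I_HEAPN] = n
    c = 0
    while True:
        l = 2 * c + 1
        if l >= n:
            break
        r = l + 1
        m = l
        if r < n and ht[r] < ht[l]:
            m = r
        if ht[c] <= ht[m]:
            break
        ht[c], ht[m] = ht[m], ht[c]
        hm1[c], hm1[m] = hm1[m], hm1[c]
        hm2[c], hm2[m] = hm2[m], hm2[c]
        c = m
    k = np.int64(m1 >> 42)
    i = np.int64((m1 >> 21) & 0x1FFFFF) - 1
    j = np.int64(m1 & 0x1FFFFF) - 1
    si = (m2 >> 32) & 0xFFFFFFFF
    sj = m2 & 0xFFFFFFFF
    return t, k, i, j, si, sj


@njit(cache=True, inline="always")
def _stale(m1, m2, stamp):
    i = np.int64((m1 >> 21) & 0x1FFFFF) - 1
    if i < 0:
        return False
    if ((m2 >> 32) & 0xFFFFFFFF) != (stamp[i] & 0xFFFFFFFF):
        return True
    j = np.int64(m1 & 0x1FFFFF) - 1
    if j >= 0 and (m2 & 0xFFFFFFFF) != (stamp[j] & 0xFFFFFFFF):
        # a bond aggregate whose argmin partner moved on is NOT discardable:
        # it is the only calendar entry guarding bead i's walls, and the pop
        # path re-predicts it.  Dropping it here would leave the bond
        # uncovered until i's next event (walls can then be crossed unseen).
        if (m1 >> 42) == EV_BOND:
            return False
        return True
    return False


@njit(cache=True)
def _heap_rebuild(ht, hm1, hm2, iscal, stamp):
    """Drop stale entries in place, then heapify."""
    n = iscal[I_HEAPN]
    m = 0
    for a in range(n):
        if not _stale(hm1[a], hm2[a], stamp):
            ht[m] = ht[a]; hm1[m] = hm1[a]; hm2[m] = hm2[a]
            m += 1
    iscal[I_HEAPN] = m
    for s in range(m // 2 - 1, -1, -1):
        c = s
        while True:
            l = 2 * c + 1
            if l >= m:
                break
            r = l + 1
            k = l
            if r < m and ht[r] < ht[l]:
                k = r
            if ht[c] <= ht[k]:
                break
            ht[c], ht[k] = ht[k], ht[c]
            hm1[c], hm1[k] = hm1[k], hm1[c]
            hm2[c], hm2[k] = hm2[k], hm2[c]
            c = k


# --- geometry helpers ---------------------------------------------------------

@njit(cache=True, inline="always")
def _rel(i, j, t, pos, vel, t_last, L):
    """Minimum-image relative position and velocity of pair (i, j) at time t."""
    rx = (pos[i, 0] + vel[i, 0] * (t - t_last[i])) - (pos[j, 0] + vel[j, 0] * (t - t_last[j]))
    ry = (pos[i, 1] + vel[i, 1] * (t - t_last[i])) - (pos[j, 1] + vel[j, 1] * (t - t_last[j]))
    rz = (pos[i, 2] + vel[i, 2] * (t - t_last[i])) - (pos[j, 2] + vel[j, 2] * (t - t_last[j]))
    rx = _mi(rx, L); ry = _mi(ry, L); rz = _mi(rz, L)
    vx = vel[i, 0] - vel[j, 0]
    vy = vel[i, 1] - vel[j, 1]
    vz = vel[i, 2] - vel[j, 2]
    return rx, ry, rz, vx, vy, vz


@njit(cache=True, inline="always")
def _dist2_at(i, j, t, pos, vel, t_last, L):
    rx, ry, rz, vx, vy, vz = _rel(i, j, t, pos, vel, t_last, L)
    return rx * rx + ry * ry + rz * rz


@njit(cache=True)
def _is_bonded(i, j, badj_ptr, badj_other):
    for a in range(badj_ptr[i], badj_ptr[i + 1]):
        if badj_other[a] == j:
            return True
    return False


# pair classes
CLS_NONE = 0
CLS_CORE = 1
CLS_SC = 2
CLS_HB = 3


@njit(cache=True, inline="always")
def _classify(i, j, chain, resi, kind, rtype, badj_ptr, badj_other, E20):
    if chain[i] == chain[j]:
        dr = resi[i] - resi[j]
        if dr < 0:
            dr = -dr
        if _is_bonded(i, j, badj_ptr, badj_other):
            return CLS_NONE
        if dr <= 1:
            return CLS_NONE
        ki = kind[i]; kj = kind[j]
        if ki == K_SC and kj == K_SC:
            if E20[rtype[i], rtype[j]] > 0.0:
                return CLS_SC
            return CLS_CORE
        if (ki == K_NH and kj == K_CO) or (ki == K_CO and kj == K_NH):
            # hydrogen bonding is inter-chain only: a short strand cannot
            # pair with itself in beta geometry, and i,i+3 "turn" bonds
            # (which the simplified bead geometry would admit) lock donors
            # away from sheet formation
            return CLS_CORE
        return CLS_CORE
    ki = kind[i]; kj = kind[j]
    if ki == K_SC and kj == K_SC:
        if E20[rtype[i], rtype[j]] > 0.0:
            return CLS_SC
        return CLS_CORE
    if (ki == K_NH and kj == K_CO) or (ki == K_CO and kj == K_NH):
        return CLS_HB
    return CLS_CORE


@njit(cache=True)
def _pair_candidate(i, j, t_now, pos, vel, t_last, L,
                    chain, resi, kind, rtype, sigma,
                    badj_ptr, badj_other, W20, E20,
                    hb_w, hb_partner):
    """Earliest future discontinuity for a nonbonded pair.

    Returns (t_event, kind); kind = -1 means no event.
    """
    cls = _classify(i, j, chain, resi, kind, rtype, badj_ptr, badj_other, E20)
    if cls == CLS_NONE:
        return 0.0, -1
    rx, ry, rz, vx, vy, vz = _rel(i, j, t_now, pos, vel, t_last, L)
    r2 = rx * rx + ry * ry + rz * rz
    v2 = vx * vx + vy * vy + vz * vz
    if v2 <= 0.0:
        return 0.0, -1
    b = rx * vx + ry * vy + rz * vz
    dc = 0.5 * (sigma[i] + sigma[j])
    core2 = dc * dc

    if cls == CLS_CORE:
        if b >= 0.0:
            return 0.0, -1
        disc = b * b - v2 * (r2 - core2)
        if disc <= 0.0:
            return 0.0, -1
        t = (r2 - core2) / (np.sqrt(disc) - b)
        if t < 0.0:
            t = 0.0
        return t_now + t, EV_CORE

    if cls == CLS_SC:
        w = W20[rtype[i], rtype[j]]
        w2 = w * w
        ev_kind = EV_SCWELL
        bonded_like = r2 < w2 * (1.0 - _EDGE) or (r2 < w2 * (1.0 + _EDGE) and b < 0.0)
    else:
        w2 = hb_w * hb_w
        ev_kind = EV_HB
        if hb_partner[i] == j:
            bonded_like = True
        else:
            # unbonded pair: only an inward crossing of the well edge matters
            inside = r2 < w2 * (1.0 - _EDGE) or (r2 < w2 * (1.0 + _EDGE) and b < 0.0)
            if inside:
                # no formation chance until it exits and re-enters: core only
                if b >= 0.0:
                    return 0.0, -1
                disc = b * b - v2 * (r2 - core2)
                if disc <= 0.0:
                    return 0.0, -1
                t = (r2 - core2) / (np.sqrt(disc) - b)
                if t < 0.0:
                    t = 0.0
                return t_now + t, EV_CORE
            if b >= 0.0:
                return 0.0, -1
            disc = b * b - v2 * (r2 - w2)
            if disc <= 0.0:
                return 0.0, -1
            t = (r2 - w2) / (np.sqrt(disc) - b)
            if t < 0.0:
                t = 0.0
            return t_now + t, EV_HB

    if bonded_like:
        # inside the well (or H-bonded): earliest of core hit and outer edge
        t_core = 1e300
        if b < 0.0:
            disc = b * b - v2 * (r2 - core2)
            if disc > 0.0:
                t_core = (r2 - core2) / (np.sqrt(disc) - b)
                if t_core < 0.0:
                    t_core = 0.0
        disc2 = b * b - v2 * (r2 - w2)
        if disc2 < 0.0:
            disc2 = 0.0
        t_out = (-b + np.sqrt(disc2)) / v2
        if t_out < 0.0:
            t_out = 0.0
        if t_core < t_out:
            return t_now + t_core, EV_CORE
        return t_now + t_out, ev_kind
    else:
        if b >= 0.0:
            return 0.0, -1
        disc = b * b - v2 * (r2 - w2)
        if disc <= 0.0:
            return 0.0, -1
        t = (r2 - w2) / (np.sqrt(disc) - b)
        if t < 0.0:
            t = 0.0
        return t_now + t, ev_kind


@njit(cache=True)
def _bond_candidate(i, j, lo2, hi2, t_now, pos, vel, t_last, L):
    """Next hard-wall crossing of a bonded pair (inner or outer)."""
    rx, ry, rz, vx, vy, vz = _rel(i, j, t_now, pos, vel, t_last, L)
    r2 = rx * rx + ry * ry + rz * rz
    v2 = vx * vx + vy * vy + vz * vz
    if v2 <= 0.0:
        return -1.0
    b = rx * vx + ry * vy + rz * vz
    if b < 0.0:
        disc = b * b - v2 * (r2 - lo2)
        if disc > 0.0:
            t = (r2 - lo2) / (np.sqrt(disc) - b)
            if t < 0.0:
                t = 0.0
            return t_now + t
    disc = b * b - v2 * (r2 - hi2)
    if disc < 0.0:
        disc = 0.0
    t = (-b + np.sqrt(disc)) / v2
    if t < 0.0:
        t = 0.0
    return t_now + t


@njit(cache=True)
def _bond_aggregate(i, t_now, pos, vel, t_last, L,
                    bond_lo2, bond_hi2, badj_ptr, badj_bond, badj_other):
    """Earliest wall crossing over all bonds/pseudobonds of bead i.

    One aggregated calendar entry per bead keeps the heap small; every bond
    appears in both endpoints' aggregates, so a partner deflection that makes
    some wall earlier is always covered by that partner's own entry.
    """
    t_min = 1e300
    j_min = -1
    for a in range(badj_ptr[i], badj_ptr[i + 1]):
        bidx = badj_bond[a]
        j = badj_other[a]
        t = _bond_candidate(i, j, bond_lo2[bidx], bond_hi2[bidx], t_now,
                            pos, vel, t_last, L)
        if t >= 0.0 and t < t_min:
            t_min = t
            j_min = j
    return t_min, j_min


@njit(cache=True)
def _hb_geom_ok(nh, co, t, pos, vel, t_last, L, aux_a, aux_b, aux_min):
    """Directionality test: the four auxiliary neighbour beads (CaH and CO
    flanking the NH; CaH and NH flanking the CO) must each be farther than
    ``aux_min`` from the partner bead, enforcing local linearity."""
    am2 = aux_min * aux_min
    for a in (aux_a[nh], aux_b[nh]):
        if a >= 0:
            if _dist2_at(a, co, t, pos, vel, t_last, L) < am2:
                return False
    for a in (aux_a[co], aux_b[co]):
        if a >= 0:
            if _dist2_at(a, nh, t, pos, vel, t_last, L) < am2:
                return False
    return True


# --- cells --------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cell_flat(cx, cy, cz, ncell):
    return (cx * ncell + cy) * ncell + cz


@njit(cache=True)
def _cell_insert(i, c, cell_head, cell_next, cell_prev):
    h = cell_head[c]
    cell_next[i] = h
    cell_prev[i] = -1
    if h >= 0:
        cell_prev[h] = i
    cell_head[c] = i


@njit(cache=True)
def _cell_remove(i, c, cell_head, cell_next, cell_prev):
    p = cell_prev[i]
    n = cell_next[i]
    if p >= 0:
        cell_next[p] = n
    else:
        cell_head[c] = n
    if n >= 0:
        cell_prev[n] = p


@njit(cache=True)
def _cell_cross_time(i, t_now, pos, vel, t_last, L, celli, ncell):
    """Time (absolute) of the next cell-boundary crossing, or -1 if none."""
    if ncell < 3:
        return -1.0
    h = L / ncell
    t_min = 1e300
    for ax in range(3):
        x = pos[i, ax] + vel[i, ax] * (t_now - t_last[i])
        x -= L * np.floor(x / L)
        rel = x - celli[i, ax] * h
        if rel < -0.5 * L:
            rel += L
        elif rel > 0.5 * L:
            rel -= L
        if rel < 0.0:
            rel = 0.0
        elif rel > h:
            rel = h
        v = vel[i, ax]
        if v > _TINY:
            t = (h - rel) / v
        elif v < -_TINY:
            t = rel / (-v)
        else:
            continue
        if t < t_min:
            t_min = t
    if t_min >= 1e300:
        return -1.0
    return t_now + t_min


@njit(cache=True)
def _predict_bead(i, t_now, pos, vel, t_last, stamp, L,
                  chain, resi, kind, rtype, sigma,
                  bond_i, bond_j, bond_lo2, bond_hi2,
                  badj_ptr, badj_bond, badj_other,
                  W20, E20, hb_w, hb_partner,
                  celli, ncell, cell_head, cell_next, cell_prev,
                  ht, hm1, hm2, iscal):
    si = stamp[i]
    ok = True
    # bonds and pseudobonds: one aggregated entry (earliest wall)
    tb, jb = _bond_aggregate(i, t_now, pos, vel, t_last, L,
                             bond_lo2, bond_hi2, badj_ptr, badj_bond, badj_other)
    if jb >= 0:
        ok = ok and _hpush(ht, hm1, hm2, iscal,
                           tb, EV_BOND, i, jb, si, stamp[jb])
    # nonbonded neighbours
    if ncell >= 3:
        cx = celli[i, 0]; cy = celli[i, 1]; cz = celli[i, 2]
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    c = _cell_flat((cx + dx) % ncell, (cy + dy) % ncell,
                                   (cz + dz) % ncell, ncell)
                    j = cell_head[c]
                    while j >= 0:
                        if j != i:
                            t, k = _pair_candidate(
                                i, j, t_now, pos, vel, t_last, L,
                                chain, resi, kind, rtype, sigma,
                                badj_ptr, badj_other, W20, E20, hb_w, hb_partner)
                            if k >= 0:
                                ok = ok and _hpush(ht, hm1, hm2, iscal,
                                                   t, k, i, j, si, stamp[j])
                        j = cell_next[j]
        t = _cell_cross_time(i, t_now, pos, vel, t_last, L, celli, ncell)
        if t >= 0.0:
            ok = ok and _hpush(ht, hm1, hm2, iscal,
                               t, EV_CELL, i, -1, si, 0)
    else:
        for j in range(pos.shape[0]):
            if j != i:
                t, k = _pair_candidate(
                    i, j, t_now, pos, vel, t_last, L,
                    chain, resi, kind, rtype, sigma,
                    badj_ptr, badj_other, W20, E20, hb_w, hb_partner)
                if k >= 0:
                    ok = ok and _hpush(ht, hm1, hm2, iscal,
                                       t, k, i, j, si, stamp[j])
    return ok


@njit(cache=True, inline="always")
def _advance(i, t, pos, vel, t_last):
    dt = t - t_last[i]
    pos[i, 0] += vel[i, 0] * dt
    pos[i, 1] += vel[i, 1] * dt
    pos[i, 2] += vel[i, 2] * dt
    t_last[i] = t


@njit(cache=True)
def init_events(pos, vel, t_last, stamp, L,
                chain, resi, kind, rtype, sigma,
                bond_i, bond_j, bond_lo2, bond_hi2,
                badj_ptr, badj_bond, badj_other,
                W20, E20, hb_w, hb_partner,
                celli, ncell, cell_head, cell_next, cell_prev,
                ht, hm1, hm2, iscal, fscal,
                ghost_rate, rng):
    """Assign cells, predict every bead, start the thermostat stream."""
    n = pos.shape[0]
    iscal[I_HEAPN] = 0
    for c in range(cell_head.shape[0]):
        cell_head[c] = -1
    if ncell >= 3:
        h = L / ncell
        for i in range(n):
            for ax in range(3):
                x = pos[i, ax] - L * np.floor(pos[i, ax] / L)
                c = int(x / h)
                if c >= ncell:
                    c = ncell - 1
                celli[i, ax] = c
            _cell_insert(i, _cell_flat(celli[i, 0], celli[i, 1], celli[i, 2], ncell),
                         cell_head, cell_next, cell_prev)
    ok = True
    for i in range(n):
        ok = ok and _predict_bead(i, fscal[F_CLOCK], pos, vel, t_last, stamp, L,
                                  chain, resi, kind, rtype, sigma,
                                  bond_i, bond_j, bond_lo2, bond_hi2,
                                  badj_ptr, badj_bond, badj_other,
                                  W20, E20, hb_w, hb_partner,
                                  celli, ncell, cell_head, cell_next, cell_prev,
                                  ht, hm1, hm2, iscal)
    if ghost_rate > 0.0:
        dt = -np.log(_rand_u(rng)) / (ghost_rate * n)
        fscal[F_NEXT_GHOST] = fscal[F_CLOCK] + dt
        ok = ok and _hpush(ht, hm1, hm2, iscal,
                           fscal[F_NEXT_GHOST], EV_GHOST, -1, -1, 0, 0)
    if not ok:
        iscal[I_ERR] = STATUS_HEAP_FULL
        return STATUS_HEAP_FULL
    return STATUS_OK


@njit(cache=True)
def run_until(t_target, max_events,
              pos, vel, t_last, stamp, L,
              chain, resi, kind, rtype, sigma, inv_mass,
              bond_i, bond_j, bond_lo2, bond_hi2,
              badj_ptr, badj_bond, badj_other,
              W20, E20, hb_w, hb_depth, aux_a, aux_b, aux_min, hb_partner,
              celli, ncell, cell_head, cell_next, cell_prev,
              ht, hm1, hm2, iscal, fscal,
              t_star, ghost_rate, rng):
    """Process events until the clock reaches ``t_target`` (then synchronize
    every bead to it) or ``max_events`` physical events have run."""
    n = pos.shape[0]
    n_exec = 0
    while iscal[I_HEAPN] > 0:
        if ht[0] > t_target:
            break
        if n_exec >= max_events:
            # synchronize before handing control back
            for i2 in range(n):
                _advance(i2, fscal[F_CLOCK], pos, vel, t_last)
            return STATUS_EVENT_BUDGET
        t, k, i, j, si, sj = _hpop(ht, hm1, hm2, iscal)
        # staleness
        if i >= 0:
            if si != (stamp[i] & 0xFFFFFFFF):
                iscal[I_NSTALE] += 1
                continue
            if j >= 0 and sj != (stamp[j] & 0xFFFFFFFF):
                if k == EV_BOND:
                    # partner moved on: this bead still needs bond coverage
                    tb, jb = _bond_aggregate(i, fscal[F_CLOCK], pos, vel, t_last, L,
                                             bond_lo2, bond_hi2,
                                             badj_ptr, badj_bond, badj_other)
                    if jb >= 0:
                        if not _hpush(ht, hm1, hm2, iscal, tb, EV_BOND, i, jb,
                                      si, stamp[jb]):
                            _heap_rebuild(ht, hm1, hm2, iscal, stamp)
                            if not _hpush(ht, hm1, hm2, iscal, tb, EV_BOND, i, jb,
                                          si, stamp[jb]):
                                iscal[I_ERR] = STATUS_HEAP_FULL
                                return STATUS_HEAP_FULL
                iscal[I_NSTALE] += 1
                continue
        if t < fscal[F_CLOCK] - 1e-9:
            iscal[I_ERR] = STATUS_TIME_REGRESSION
            return STATUS_TIME_REGRESSION
        if t > fscal[F_CLOCK]:
            fscal[F_CLOCK] = t

        if k == EV_GHOST:
            gi = int(_rand_u(rng) * n)
            if gi >= n:
                gi = n - 1
            _advance(gi, t, pos, vel, t_last)
            s = np.sqrt(t_star * inv_mass[gi])
            vel[gi, 0] = s * _rand_norm(rng)
            vel[gi, 1] = s * _rand_norm(rng)
            vel[gi, 2] = s * _rand_norm(rng)
            stamp[gi] += 1
            if not _predict_bead(gi, t, pos, vel, t_last, stamp, L,
                                 chain, resi, kind, rtype, sigma,
                                 bond_i, bond_j, bond_lo2, bond_hi2,
                                 badj_ptr, badj_bond, badj_other,
                                 W20, E20, hb_w, hb_partner,
                                 celli, ncell, cell_head, cell_next, cell_prev,
                                 ht, hm1, hm2, iscal):
                _heap_rebuild(ht, hm1, hm2, iscal, stamp)
                stamp[gi] += 1
                if not _predict_bead(gi, t, pos, vel, t_last, stamp, L,
                                     chain, resi, kind, rtype, sigma,
                                     bond_i, bond_j, bond_lo2, bond_hi2,
                                     badj_ptr, badj_bond, badj_other,
                                     W20, E20, hb_w, hb_partner,
                                     celli, ncell, cell_head, cell_next, cell_prev,
                                     ht, hm1, hm2, iscal):
                    iscal[I_ERR] = STATUS_HEAP_FULL
                    return STATUS_HEAP_FULL
            dt = -np.log(_rand_u(rng)) / (ghost_rate * n)
            fscal[F_NEXT_GHOST] = t + dt
            if not _hpush(ht, hm1, hm2, iscal,
                          fscal[F_NEXT_GHOST], EV_GHOST, -1, -1, 0, 0):
                _heap_rebuild(ht, hm1, hm2, iscal, stamp)
                if not _hpush(ht, hm1, hm2, iscal,
                              fscal[F_NEXT_GHOST], EV_GHOST, -1, -1, 0, 0):
                    iscal[I_ERR] = STATUS_HEAP_FULL
                    return STATUS_HEAP_FULL
            iscal[I_NGHOST] += 1
            iscal[I_NEVENT] += 1
            n_exec += 1
            continue

        if k == EV_CELL:
            _advance(i, t, pos, vel, t_last)
            # which boundary: recompute axis crossing times
            h = L / ncell
            best_ax = -1
            best_t = 1e300
            for ax in range(3):
                x = pos[i, ax] - L * np.floor(pos[i, ax] / L)
                rel = x - celli[i, ax] * h
                if rel < -0.5 * L:
                    rel += L
                elif rel > 0.5 * L:
                    rel -= L
                if rel < 0.0:
                    rel = 0.0
                elif rel > h:
                    rel = h
                v = vel[i, ax]
                if v > _TINY:
                    ta = (h - rel) / v
                elif v < -_TINY:
                    ta = rel / (-v)
                else:
                    continue
                if ta < best_t:
                    best_t = ta
                    best_ax = ax
            if best_ax >= 0:
                old = _cell_flat(celli[i, 0], celli[i, 1], celli[i, 2], ncell)
                step = 1 if vel[i, best_ax] > 0.0 else -1
                celli[i, best_ax] = (celli[i, best_ax] + step) % ncell
                new = _cell_flat(celli[i, 0], celli[i, 1], celli[i, 2], ncell)
                if new != old:
                    _cell_remove(i, old, cell_head, cell_next, cell_prev)
                    _cell_insert(i, new, cell_head, cell_next, cell_prev)
            stamp[i] += 1
            if not _predict_bead(i, t, pos, vel, t_last, stamp, L,
                                 chain, resi, kind, rtype, sigma,
                                 bond_i, bond_j, bond_lo2, bond_hi2,
                                 badj_ptr, badj_bond, badj_other,
                                 W20, E20, hb_w, hb_partner,
                                 celli, ncell, cell_head, cell_next, cell_prev,
                                 ht, hm1, hm2, iscal):
                _heap_rebuild(ht, hm1, hm2, iscal, stamp)
                stamp[i] += 1
                if not _predict_bead(i, t, pos, vel, t_last, stamp, L,
                                     chain, resi, kind, rtype, sigma,
                                     bond_i, bond_j, bond_lo2, bond_hi2,
                                     badj_ptr, badj_bond, badj_other,
                                     W20, E20, hb_w, hb_partner,
                                     celli, ncell, cell_head, cell_next, cell_prev,
                                     ht, hm1, hm2, iscal):
                    iscal[I_ERR] = STATUS_HEAP_FULL
                    return STATUS_HEAP_FULL
            iscal[I_NCELL] += 1
            continue

        # pair event
        _advance(i, t, pos, vel, t_last)
        _advance(j, t, pos, vel, t_last)
        rx = _mi(pos[i, 0] - pos[j, 0], L)
        ry = _mi(pos[i, 1] - pos[j, 1], L)
        rz = _mi(pos[i, 2] - pos[j, 2], L)
        d = np.sqrt(rx * rx + ry * ry + rz * rz)
        if d <= 0.0:
            iscal[I_ERR] = STATUS_TIME_REGRESSION
            return STATUS_TIME_REGRESSION
        ux = rx / d; uy = ry / d; uz = rz / d
        vr = ((vel[i, 0] - vel[j, 0]) * ux + (vel[i, 1] - vel[j, 1]) * uy
              + (vel[i, 2] - vel[j, 2]) * uz)
        mu = 1.0 / (inv_mass[i] + inv_mass[j])
        J = 0.0
        if k == EV_CORE:
            # reflect only an approaching pair (a receding one here is a
            # roundoff echo); regularize tangent grazes so the pair cannot
            # freeze at the contact with vr ~ 0
            if vr < 0.0:
                vrp = -vr
                if vrp < V_MIN:
                    vrp = V_MIN
                J = mu * (vrp - vr)
            iscal[I_NCORE] += 1
        elif k == EV_BOND:
            # find this bond's walls to decide which side we are on; reflect
            # only when actually leaving the legal range (robust to roundoff)
            lo2 = 0.0; hi2 = 1e300
            for a in range(badj_ptr[i], badj_ptr[i + 1]):
                if badj_other[a] == j:
                    bidx = badj_bond[a]
                    lo2 = bond_lo2[bidx]; hi2 = bond_hi2[bidx]
                    break
            at_outer = d * d > 0.5 * (lo2 + hi2)
            vrp = vr
            if at_outer:
                if vr > 0.0 or d * d > hi2:
                    vrp = -np.abs(vr)
                    if vrp > -V_MIN:
                        vrp = -V_MIN
            else:
                if vr < 0.0 or d * d < lo2:
                    vrp = np.abs(vr)
                    if vrp < V_MIN:
                        vrp = V_MIN
            J = mu * (vrp - vr)
            # a tangent graze can let the pair drift past the wall before the
            # next scheduled crossing; project it back onto the wall (tiny,
            # mass-weighted, no energy or momentum change)
            wall2 = hi2 if at_outer else lo2
            if (at_outer and d * d > wall2) or ((not at_outer) and d * d < wall2):
                excess = d - np.sqrt(wall2)
                fi = excess * mu * inv_mass[i]
                fj = excess * mu * inv_mass[j]
                pos[i, 0] -= fi * ux; pos[i, 1] -= fi * uy; pos[i, 2] -= fi * uz
                pos[j, 0] += fj * ux; pos[j, 1] += fj * uy; pos[j, 2] += fj * uz
            iscal[I_NBOND] += 1
        elif k == EV_SCWELL:
            e = E20[rtype[i], rtype[j]]
            if vr < 0.0:  # capture
                vrp = -np.sqrt(vr * vr + 2.0 * e / mu)
                fscal[F_PE] -= e
                J = mu * (vrp - vr)
                iscal[I_WELLIN] += 1
            else:         # escape attempt at the outer edge
                if vr * vr > 2.0 * e / mu:
                    vrp = np.sqrt(vr * vr - 2.0 * e / mu)
                    fscal[F_PE] += e
                    J = mu * (vrp - vr)
                    iscal[I_WELLESC] += 1
                else:
                    vrp = -vr
                    if vrp > -V_MIN:
                        vrp = -V_MIN
                    J = mu * (vrp - vr)
                    iscal[I_WELLREFL] += 1
        elif k == EV_HB:
            if hb_partner[i] == j:
                # break attempt at the outer edge (vr <= 0 is a roundoff echo)
                if vr > 0.0:
                    if vr * vr > 2.0 * hb_depth / mu:
                        vrp = np.sqrt(vr * vr - 2.0 * hb_depth / mu)
                        fscal[F_PE] += hb_depth
                        J = mu * (vrp - vr)
                        hb_partner[i] = -1
                        hb_partner[j] = -1
                        iscal[I_HBBREAK] += 1
                    else:
                        vrp = -vr
                        if vrp > -V_MIN:
                            vrp = -V_MIN
                        J = mu * (vrp - vr)
                        iscal[I_WELLREFL] += 1
            else:
                # formation attempt on inward crossing
                iscal[I_HBATTEMPT] += 1
                nh = i if kind[i] == K_NH else j
                co = j if nh == i else i
                if (hb_partner[nh] < 0 and hb_partner[co] < 0 and vr < 0.0
                        and _hb_geom_ok(nh, co, t, pos, vel, t_last, L,
                                        aux_a, aux_b, aux_min)):
                    vrp = -np.sqrt(vr * vr + 2.0 * hb_depth / mu)
                    fscal[F_PE] -= hb_depth
                    J = mu * (vrp - vr)
                    hb_partner[nh] = co
                    hb_partner[co] = nh
                    iscal[I_HBFORM] += 1
                else:
                    J = 0.0  # transparent crossing
        vel[i, 0] += J * ux * inv_mass[i]
        vel[i, 1] += J * uy * inv_mass[i]
        vel[i, 2] += J * uz * inv_mass[i]
        vel[j, 0] -= J * ux * inv_mass[j]
        vel[j, 1] -= J * uy * inv_mass[j]
        vel[j, 2] -= J * uz * inv_mass[j]
        stamp[i] += 1
        stamp[j] += 1
        ok = _predict_bead(i, t, pos, vel, t_last, stamp, L,
                           chain, resi, kind, rtype, sigma,
                           bond_i, bond_j, bond_lo2, bond_hi2,
                           badj_ptr, badj_bond, badj_other,
                           W20, E20, hb_w, hb_partner,
                           celli, ncell, cell_head, cell_next, cell_prev,
                           ht, hm1, hm2, iscal)
        ok = _predict_bead(j, t, pos, vel, t_last, stamp, L,
                           chain, resi, kind, rtype, sigma,
                           bond_i, bond_j, bond_lo2, bond_hi2,
                           badj_ptr, badj_bond, badj_other,
                           W20, E20, hb_w, hb_partner,
                           celli, ncell, cell_head, cell_next, cell_prev,
                           ht, hm1, hm2, iscal) and ok
        if not ok:
            _heap_rebuild(ht, hm1, hm2, iscal, stamp)
            ok = _predict_bead(i, t, pos, vel, t_last, stamp, L,
                               chain, resi, kind, rtype, sigma,
                               bond_i, bond_j, bond_lo2, bond_hi2,
                               badj_ptr, badj_bond, badj_other,
                               W20, E20, hb_w, hb_partner,
                               celli, ncell, cell_head, cell_next, cell_prev,
                               ht, hm1, hm2, iscal)
            ok = _predict_bead(j, t, pos, vel, t_last, stamp, L,
                               chain, resi, kind, rtype, sigma,
                               bond_i, bond_j, bond_lo2, bond_hi2,
                               badj_ptr, badj_bond, badj_other,
                               W20, E20, hb_w, hb_partner,
                               celli, ncell, cell_head, cell_next, cell_prev,
                               ht, hm1, hm2, iscal) and ok
            if not ok:
                iscal[I_ERR] = STATUS_HEAP_FULL
                return STATUS_HEAP_FULL
        iscal[I_NEVENT] += 1
        n_exec += 1

    for i2 in range(n):
        _advance(i2, t_target, pos, vel, t_last)
    fscal[F_CLOCK] = t_target
    return STATUS_OK
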