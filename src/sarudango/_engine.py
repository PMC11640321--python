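"""Compiled per-tick update kernel.

The world is a flat array-of-struct layout so the whole tick loop can run
under numba with ``nogil``:

* per-agent arrays: position, heading, registry slot (-1 = lone), huddle time;
* per-slot cluster registry: in-use flag, monotone cluster id, size, anchor;
* a free-slot stack and a small ``meta`` array ``[next_cluster_id, tick,
  free_count]``.

All randomness is drawn as raw uniform doubles from a ``numpy.random.Generator``
passed in by the caller (numba's Generator support consumes the identical
PCG64 stream as numpy itself), so the pure-python reference implementation in
``world.py`` reproduces every trajectory draw for draw.  Any edit to the
decision logic here must be mirrored there.

Neighbour search is a dense scan over all agents: at the model's scales
(tens to a few hundred agents on a 16x16 torus) the vectorised distance loop
beats any spatial index, and it trivially honours the mid-pass semantics
(agents act on positions as they currently stand within the shuffled pass).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi
_BIG = np.int64(2**62)


@njit(cache=True, nogil=True)
def _step_forward(x, y, h, W, H):
    """One-patch step along heading ``h`` with toroidal wrap.

    Shared by the kernel and the python reference path so both see the exact
    same floating-point result (codegen context can otherwise differ by an
    ulp, e.g. through fused multiply-adds).
    """
    return (x + np.cos(h)) % W, (y + np.sin(h)) % H


@njit(cache=True, nogil=True)
def _circle_point(ax, ay, rc, t, m, W, H):
    """Position of member ``t`` of ``m`` on the spacing circle round (ax, ay)."""
    ang = TWO_PI * t / m
    return (ax + rc * np.cos(ang)) % W, (ay + rc * np.sin(ang)) % H


@njit(cache=True, nogil=True, inline="always")
def _tor_d2(x1, y1, x2, y2, W, H):
    dx = abs(x1 - x2)
    if dx > W - dx:
        dx = W - dx
    dy = abs(y1 - y2)
    if dy > H - dy:
        dy = H - dy
    return dx * dx + dy * dy


@njit(cache=True, nogil=True)
def _reposition(s, pos_x, pos_y, slot, slot_ax, slot_ay, slot_size, W, H, R):
    # members evenly spaced on a circle around the anchor, ascending agent id
    m = slot_size[s]
    rc = R / 2.0
    if rc > 1.0:
        rc = 1.0
    t = 0
    for a in range(pos_x.shape[0]):
        if slot[a] == s:
            nx, ny = _circle_point(slot_ax[s], slot_ay[s], rc, t, m, W, H)
            pos_x[a] = nx
            pos_y[a] = ny
            t += 1


@njit(cache=True, nogil=True)
def _tick_impl(pos_x, pos_y, heading, slot, huddle_time,
               slot_used, slot_cid, slot_size, slot_ax, slot_ay,
               free_stack, meta, W, H, R, T, J, L, policy, leave_mode,
               nuc_pool, sel_nuc_only, rng, nbuf, order, d2buf):
    """Advance the world one tick in place; returns the number of lone agents.

    ``policy`` selects the candidate rule: 0 = one in-range agent drawn
    uniformly (consumes one extra selection draw when neighbours exist),
    1 = deterministic largest in-range cluster / lowest-id lone fallback.
    ``nbuf``/``order`` (int64) and ``d2buf`` (float64) are reusable length-N
    scratch arrays.
    """
    N = pos_x.shape[0]
    n_cmax = N

    # shuffled processing order (explicit Fisher-Yates over uniform doubles)
    for a in range(N):
        order[a] = a
    for i in range(N - 1, 0, -1):
        j = int(rng.random() * (i + 1))
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp

    r2 = R * R
    for k in range(N):
        i = order[k]
        if slot[i] < 0:
            # exploratory move: new uniform heading, one patch forward
            h = rng.random() * TWO_PI
            heading[i] = h
            nx, ny = _step_forward(pos_x[i], pos_y[i], h, W, H)
            pos_x[i] = nx
            pos_y[i] = ny

            # everyone currently within sensing range, ascending agent id
            # (two passes: a branch-free SIMD distance pass, then collection)
            xi = pos_x[i]
            yi = pos_y[i]
            for j in range(N):
                dx = abs(xi - pos_x[j])
                dx = min(dx, W - dx)
                dy = abs(yi - pos_y[j])
                dy = min(dy, H - dy)
                d2buf[j] = dx * dx + dy * dy
            k_nb = 0
            for j in range(N):
                if d2buf[j] <= r2 and j != i:
                    nbuf[k_nb] = j
                    k_nb += 1

            # pick the candidate to evaluate
            cand_slot = np.int64(-1)
            cand_size = np.int64(0)
            cand_lone = np.int64(-1)
            if k_nb > 0:
                if policy == 0:
                    jsel = nbuf[int(rng.random() * k_nb)]
                    sj = slot[jsel]
                    if sj >= 0:
                        cand_slot = sj
                        cand_size = slot_size[sj]
                    else:
                        cand_lone = jsel
                else:
                    best_cid = _BIG
                    for q in range(k_nb):
                        j = nbuf[q]
                        sj = slot[j]
                        if sj >= 0:
                            sz = slot_size[sj]
                            cid = slot_cid[sj]
                            if sz > cand_size or (sz == cand_size and cid < best_cid):
                                cand_slot = sj
                                cand_size = sz
                                best_cid = cid
                        elif cand_lone < 0:
                            cand_lone = j
                    if cand_slot >= 0:
                        cand_lone = -1

            u = rng.random()  # exactly one decision draw per agent
            if cand_slot >= 0:
                # an established huddle pulls by size and temperature; the
                # selectivity divisor applies here only in 'all_joins'
                p = (cand_size / n_cmax) * (1.0 / T)
                if sel_nuc_only == 0:
                    p = p * (1.0 / J)
                if u < p:
                    slot[i] = cand_slot
                    huddle_time[i] = 0
                    slot_size[cand_slot] += 1
                    _reposition(cand_slot, pos_x, pos_y, slot, slot_ax,
                                slot_ay, slot_size, W, H, R)
            elif cand_lone >= 0:
                if nuc_pool == 1:
                    # candidate "cluster" = the whole unhuddled pool (all
                    # unhuddled agents share the no-huddle tag); founding a
                    # pair needs both sides' consent, hence 1/J twice
                    n_lone_now = 0
                    for a in range(N):
                        if slot[a] < 0:
                            n_lone_now += 1
                    p = ((n_lone_now / n_cmax) * (1.0 / T)
                         * (1.0 / J) * (1.0 / J))
                else:
                    p = (1 / n_cmax) * (1.0 / T) * (1.0 / J)
                if u < p:
                    # nucleate a fresh 2-member cluster anchored at the joiner
                    meta[2] -= 1
                    s = free_stack[meta[2]]
                    slot_used[s] = True
                    slot_cid[s] = meta[0]
                    meta[0] += 1
                    slot_size[s] = 2
                    slot_ax[s] = pos_x[i]
                    slot_ay[s] = pos_y[i]
                    slot[i] = s
                    slot[cand_lone] = s
                    huddle_time[i] = 0
                    huddle_time[cand_lone] = 0
                    _reposition(s, pos_x, pos_y, slot, slot_ax, slot_ay,
                                slot_size, W, H, R)
        else:
            u = rng.random()
            s = slot[i]
            sz = slot_size[s]
            p = ((n_cmax - sz) / n_cmax) * (1.0 / L)
            if leave_mode == 1:
                p = p / sz  # at most ~one departure per huddle per tick
            elif leave_mode == 2 and huddle_time[i] < L:
                p = -1.0  # residence-time gate: committed for the first L ticks
            if u < p:
                slot[i] = -1
                huddle_time[i] = 0
                slot_size[s] -= 1
                if slot_size[s] == 1:
                    # a huddle of one is not a cluster: release the remnant
                    for a in range(N):
                        if slot[a] == s:
                            slot[a] = -1
                            huddle_time[a] = 0
                            break
                    slot_used[s] = False
                    slot_size[s] = 0
                    free_stack[meta[2]] = s
                    meta[2] += 1
                else:
                    _reposition(s, pos_x, pos_y, slot, slot_ax, slot_ay,
                                slot_size, W, H, R)
            else:
                huddle_time[i] += 1

    meta[1] += 1
    n_lone = 0
    for a in range(N):
        if slot[a] < 0:
            n_lone += 1
    return n_lone


@njit(cache=True, nogil=True)
def _run_impl(pos_x, pos_y, heading, slot, huddle_time,
              slot_used, slot_cid, slot_size, slot_ax, slot_ay,
              free_stack, meta, W, H, R, T, J, L, policy, leave_mode,
              nuc_pool, sel_nuc_only, step_cap, rng):
    """Tick until every agent is huddled or the step cap is hit.

    Returns (all_joined, steps_elapsed).
    """
    N = pos_x.shape[0]
    nbuf = np.empty(N, np.int64)
    order = np.empty(N, np.int64)
    d2buf = np.empty(N, np.float64)
    for _ in range(step_cap):
        n_lone = _tick_impl(pos_x, pos_y, heading, slot, huddle_time,
                            slot_used, slot_cid, slot_size, slot_ax, slot_ay,
                            free_stack, meta, W, H, R, T, J, L, policy,
                            leave_mode, nuc_pool, sel_nuc_only, rng,
                            nbuf, order, d2buf)
        if n_lone == 0:
            return True, meta[1]
    return False, np.int64(step_cap)
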