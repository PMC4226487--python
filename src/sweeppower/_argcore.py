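"""Compiled event loop for the ancestral-recombination-graph simulation.

Internal module: flat-array state operated on by numba-compiled kernels.

Layout
------
Segments live in a global pool of parallel arrays forming singly linked,
position-sorted chains (one chain of ancestral-material intervals per
lineage).  Sample-subtree membership is a 128-bit mask split over two uint64
words, so up to 128 chromosomes can be tracked.  Lineages are slots in
parallel arrays; an explicit active list plus a Fenwick tree over material
spans gives O(log k) span-weighted lineage sampling for recombination.

Mutations are dropped eagerly whenever a lineage is destroyed (its branch is
then complete): Poisson with rate mu * duration * material length, placed
uniformly on the material.

Scalar state is carried in two small arrays so the kernels can mutate it:
``sf = [t]`` (float64) and ``si = [n_active, n_mut, seg_free_head,
lin_free_top, err]`` (int64).  ``err`` reports pool exhaustion: 1 = segment
pool, 2 = lineage slots, 3 = mutation buffer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# scalar indices
SF_T = 0
SI_NACT = 0
SI_NMUT = 1
SI_SEGFREE = 2
SI_LINFREE = 3
SI_ERR = 4
SI_STAMP = 5

ERR_SEG, ERR_LIN, ERR_MUT = 1, 2, 3


# ---------------------------------------------------------------------------
# Fenwick tree over lineage-slot spans
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _fen_update(fen, fen_n, i, delta):
    i += 1
    while i <= fen_n:
        fen[i] += delta
        i += i & (-i)


@njit(cache=True, inline="always")
def _fen_total(fen, fen_n):
    s = 0.0
    i = fen_n
    while i > 0:
        s += fen[i]
        i -= i & (-i)
    return s


@njit(cache=True)
def _fen_sample(fen, fen_n, u):
    """Smallest 0-based slot index whose cumulative span exceeds u."""
    pos = 0
    bm = fen_n
    while bm:
        nxt = pos + bm
        if nxt <= fen_n and fen[nxt] < u:
            u -= fen[nxt]
            pos = nxt
        bm >>= 1
    return pos


@njit(cache=True)
def _fen_rebuild(fen, fen_n, active, n_act, lin_left, lin_right):
    fen[:] = 0.0
    for ii in range(n_act):
        slot = active[ii]
        _fen_update(fen, fen_n, slot, lin_right[slot] - lin_left[slot])


# ---------------------------------------------------------------------------
# Segment pool
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _seg_alloc(seg_next, si):
    idx = si[SI_SEGFREE]
    if idx < 0:
        si[SI_ERR] = ERR_SEG
        return -1
    si[SI_SEGFREE] = seg_next[idx]
    return idx


@njit(cache=True)
def _seg_free_chain(seg_next, si, head):
    cur = head
    while cur != -1:
        nxt = seg_next[cur]
        seg_next[cur] = si[SI_SEGFREE]
        si[SI_SEGFREE] = cur
        cur = nxt


@njit(cache=True)
def _out_push(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
              head, tail, l, r, m0, m1, full0, full1):
    """Append an interval to an output chain, dropping complete (MRCA) pieces
    and fusing adjacent pieces with identical masks."""
    if m0 == full0 and m1 == full1:
        return head, tail
    if tail != -1 and seg_r[tail] == l and seg_m0[tail] == m0 and seg_m1[tail] == m1:
        seg_r[tail] = r
        return head, tail
    idx = _seg_alloc(seg_next, si)
    if idx < 0:
        return head, tail
    seg_l[idx] = l
    seg_r[idx] = r
    seg_m0[idx] = m0
    seg_m1[idx] = m1
    seg_next[idx] = -1
    if tail == -1:
        return idx, idx
    seg_next[tail] = idx
    return head, idx


@njit(cache=True)
def _merge_chains(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                  h1, h2, full0, full1):
    """Union of two sorted chains into a freshly allocated chain."""
    head = -1
    tail = -1
    c1, c2 = h1, h2
    have1 = c1 != -1
    have2 = c2 != -1
    l1 = r1 = l2 = r2 = 0.0
    a0 = a1 = b0 = b1 = np.uint64(0)
    if have1:
        l1, r1, a0, a1 = seg_l[c1], seg_r[c1], seg_m0[c1], seg_m1[c1]
    if have2:
        l2, r2, b0, b1 = seg_l[c2], seg_r[c2], seg_m0[c2], seg_m1[c2]
    while have1 or have2:
        if si[SI_ERR] != 0:
            return -1
        if have1 and (not have2 or r1 <= l2):
            head, tail = _out_push(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                                   head, tail, l1, r1, a0, a1, full0, full1)
            c1 = seg_next[c1]
            have1 = c1 != -1
            if have1:
                l1, r1, a0, a1 = seg_l[c1], seg_r[c1], seg_m0[c1], seg_m1[c1]
        elif have2 and (not have1 or r2 <= l1):
            head, tail = _out_push(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                                   head, tail, l2, r2, b0, b1, full0, full1)
            c2 = seg_next[c2]
            have2 = c2 != -1
            if have2:
                l2, r2, b0, b1 = seg_l[c2], seg_r[c2], seg_m0[c2], seg_m1[c2]
        else:
            lo = l1 if l1 > l2 else l2
            if l1 < lo:
                head, tail = _out_push(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                                       head, tail, l1, lo, a0, a1, full0, full1)
            elif l2 < lo:
                head, tail = _out_push(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                                       head, tail, l2, lo, b0, b1, full0, full1)
            hi = r1 if r1 < r2 else r2
            head, tail = _out_push(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                                   head, tail, lo, hi, a0 | b0, a1 | b1,
                                   full0, full1)
            if r1 > hi:
                l1 = hi
            else:
                c1 = seg_next[c1]
                have1 = c1 != -1
                if have1:
                    l1, r1, a0, a1 = seg_l[c1], seg_r[c1], seg_m0[c1], seg_m1[c1]
            if r2 > hi:
                l2 = hi
            else:
                c2 = seg_next[c2]
                have2 = c2 != -1
                if have2:
                    l2, r2, b0, b1 = seg_l[c2], seg_r[c2], seg_m0[c2], seg_m1[c2]
    return head


@njit(cache=True)
def _split_chain(seg_l, seg_r, seg_m0, seg_m1, seg_next, si, head, xb):
    """Cut a chain at physical position xb; both sides non-empty when
    left < xb < right (guaranteed by callers)."""
    prev = -1
    cur = head
    while cur != -1 and seg_r[cur] <= xb:
        prev = cur
        cur = seg_next[cur]
    if cur != -1 and seg_l[cur] < xb:
        ns = _seg_alloc(seg_next, si)
        if ns < 0:
            return -1, -1
        seg_l[ns] = xb
        seg_r[ns] = seg_r[cur]
        seg_m0[ns] = seg_m0[cur]
        seg_m1[ns] = seg_m1[cur]
        seg_next[ns] = seg_next[cur]
        seg_r[cur] = xb
        seg_next[cur] = -1
        return head, ns
    if prev == -1:
        return -1, cur
    seg_next[prev] = -1
    return head, cur


# ---------------------------------------------------------------------------
# Lineages
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lin_new(seg_l, seg_r, seg_next,
             lin_head, lin_birth, lin_bg, lin_left, lin_right, lin_stamp,
             active, pos_in_active, lin_free, fen, fen_n, si,
             head, birth, bg):
    if si[SI_LINFREE] == 0:
        si[SI_ERR] = ERR_LIN
        return -1
    slot = lin_free[si[SI_LINFREE] - 1]
    si[SI_LINFREE] -= 1
    left = seg_l[head]
    cur = head
    right = seg_r[cur]
    while seg_next[cur] != -1:
        cur = seg_next[cur]
        right = seg_r[cur]
    lin_head[slot] = head
    lin_birth[slot] = birth
    lin_bg[slot] = bg
    lin_stamp[slot] = si[SI_STAMP]
    si[SI_STAMP] += 1
    lin_left[slot] = left
    lin_right[slot] = right
    active[si[SI_NACT]] = slot
    pos_in_active[slot] = si[SI_NACT]
    si[SI_NACT] += 1
    _fen_update(fen, fen_n, slot, right - left)
    return slot


@njit(cache=True)
def _lin_kill(lin_head, lin_left, lin_right,
              active, pos_in_active, lin_free, fen, fen_n, si, slot):
    _fen_update(fen, fen_n, slot, lin_left[slot] - lin_right[slot])
    pos = pos_in_active[slot]
    last = active[si[SI_NACT] - 1]
    active[pos] = last
    pos_in_active[last] = pos
    si[SI_NACT] -= 1
    lin_free[si[SI_LINFREE]] = slot
    si[SI_LINFREE] += 1
    lin_head[slot] = -1


@njit(cache=True)
def _emit_mutations(seg_l, seg_r, seg_m0, seg_m1, seg_next,
                    lin_head, lin_birth, mut_pos, mut_m0, mut_m1,
                    sf, si, slot, mu, rng):
    dur = sf[SF_T] - lin_birth[slot]
    if dur <= 0.0:
        return
    material = 0.0
    cur = lin_head[slot]
    while cur != -1:
        material += seg_r[cur] - seg_l[cur]
        cur = seg_next[cur]
    lam = mu * dur * material
    if lam <= 0.0:
        return
    # exact Poisson count via cumulative exponentials (lam is modest here)
    acc = rng.exponential(1.0)
    count = 0
    while acc < lam:
        count += 1
        acc += rng.exponential(1.0)
    for _ in range(count):
        if si[SI_NMUT] >= mut_pos.shape[0]:
            si[SI_ERR] = ERR_MUT
            return
        u = rng.random() * material
        cur = lin_head[slot]
        pos = -1.0
        m0 = np.uint64(0)
        m1 = np.uint64(0)
        while cur != -1:
            seg_len = seg_r[cur] - seg_l[cur]
            if u < seg_len:
                pos = seg_l[cur] + u
                m0 = seg_m0[cur]
                m1 = seg_m1[cur]
                break
            u -= seg_len
            cur = seg_next[cur]
        if pos < 0.0:  # float edge: place at the very end of the material
            cur = lin_head[slot]
            while seg_next[cur] != -1:
                cur = seg_next[cur]
            pos = seg_r[cur] - 1e-9
            m0 = seg_m0[cur]
            m1 = seg_m1[cur]
        mut_pos[si[SI_NMUT]] = pos
        mut_m0[si[SI_NMUT]] = m0
        mut_m1[si[SI_NMUT]] = m1
        si[SI_NMUT] += 1


@njit(cache=True)
def _coalesce(seg_l, seg_r, seg_m0, seg_m1, seg_next,
              lin_head, lin_birth, lin_bg, lin_left, lin_right, lin_stamp,
              active, pos_in_active, lin_free, fen, fen_n,
              mut_pos, mut_m0, mut_m1, sf, si,
              slot_a, slot_b, full0, full1, mu, rng):
    """Merge two lineages; returns the new slot, or -1 if all material
    reached its MRCA (or on pool exhaustion)."""
    _emit_mutations(seg_l, seg_r, seg_m0, seg_m1, seg_next, lin_head, lin_birth,
                    mut_pos, mut_m0, mut_m1, sf, si, slot_a, mu, rng)
    _emit_mutations(seg_l, seg_r, seg_m0, seg_m1, seg_next, lin_head, lin_birth,
                    mut_pos, mut_m0, mut_m1, sf, si, slot_b, mu, rng)
    bg = lin_bg[slot_a]
    h1 = lin_head[slot_a]
    h2 = lin_head[slot_b]
    merged = _merge_chains(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                           h1, h2, full0, full1)
    _lin_kill(lin_head, lin_left, lin_right, active, pos_in_active, lin_free,
              fen, fen_n, si, slot_a)
    _lin_kill(lin_head, lin_left, lin_right, active, pos_in_active, lin_free,
              fen, fen_n, si, slot_b)
    _seg_free_chain(seg_next, si, h1)
    _seg_free_chain(seg_next, si, h2)
    if merged == -1 or si[SI_ERR] != 0:
        return -1
    return _lin_new(seg_l, seg_r, seg_next, lin_head, lin_birth, lin_bg,
                    lin_left, lin_right, lin_stamp, active, pos_in_active,
                    lin_free, fen, fen_n, si, merged, sf[SF_T], bg)


@njit(cache=True)
def _recombine(seg_l, seg_r, seg_m0, seg_m1, seg_next,
               lin_head, lin_birth, lin_bg, lin_left, lin_right, lin_stamp,
               active, pos_in_active, lin_free, fen, fen_n,
               mut_pos, mut_m0, mut_m1, sf, si,
               slot, xb, mu, rng):
    """Split a lineage at xb; returns (left_slot, right_slot)."""
    _emit_mutations(seg_l, seg_r, seg_m0, seg_m1, seg_next, lin_head, lin_birth,
                    mut_pos, mut_m0, mut_m1, sf, si, slot, mu, rng)
    bg = lin_bg[slot]
    hl, hr = _split_chain(seg_l, seg_r, seg_m0, seg_m1, seg_next, si,
                          lin_head[slot], xb)
    _lin_kill(lin_head, lin_left, lin_right, active, pos_in_active, lin_free,
              fen, fen_n, si, slot)
    if si[SI_ERR] != 0 or hl == -1 or hr == -1:
        si[SI_ERR] = ERR_SEG if si[SI_ERR] == 0 else si[SI_ERR]
        return -1, -1
    sl = _lin_new(seg_l, seg_r, seg_next, lin_head, lin_birth, lin_bg,
                  lin_left, lin_right, lin_stamp, active, pos_in_active,
                  lin_free, fen, fen_n, si, hl, sf[SF_T], bg)
    sr = _lin_new(seg_l, seg_r, seg_next, lin_head, lin_birth, lin_bg,
                  lin_left, lin_right, lin_stamp, active, pos_in_active,
                  lin_free, fen, fen_n, si, hr, sf[SF_T], bg)
    return sl, sr


# ---------------------------------------------------------------------------
# Phase drivers
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_neutral(seg_l, seg_r, seg_m0, seg_m1, seg_next,
                lin_head, lin_birth, lin_bg, lin_left, lin_right, lin_stamp,
                active, pos_in_active, lin_free, fen, fen_n,
                mut_pos, mut_m0, mut_m1, sf, si,
                t_end, n_dip, rec_per_bp, mu, full0, full1, rng):
    """Coalescent with recombination at constant diploid size until t_end.

    Returns 0 on reaching t_end, 1 when fully coalesced, -1 on error.
    """
    events = 0
    while si[SI_NACT] > 1:
        if si[SI_ERR] != 0:
            return -1
        k = si[SI_NACT]
        tot_span = _fen_total(fen, fen_n)
        rec_rate = rec_per_bp * tot_span
        coal_rate = 0.25 * k * (k - 1) / n_dip
        total = rec_rate + coal_rate
        dt = rng.exponential(1.0 / total)
        if sf[SF_T] + dt >= t_end:
            sf[SF_T] = t_end
            return 0
        sf[SF_T] += dt
        events += 1
        if events % 65536 == 0:
            _fen_rebuild(fen, fen_n, active, si[SI_NACT], lin_left, lin_right)
        if rng.random() * total < coal_rate:
            i = rng.integers(0, k)
            j = rng.integers(0, k - 1)
            if j >= i:
                j += 1
            _coalesce(seg_l, seg_r, seg_m0, seg_m1, seg_next,
                      lin_head, lin_birth, lin_bg, lin_left, lin_right,
                      lin_stamp, active, pos_in_active, lin_free, fen, fen_n,
                      mut_pos, mut_m0, mut_m1, sf, si,
                      active[i], active[j], full0, full1, mu, rng)
        else:
            u = rng.random() * tot_span
            slot = _fen_sample(fen, fen_n, u)
            if lin_head[slot] == -1:  # float residue hit a dead slot; skip
                continue
            span = lin_right[slot] - lin_left[slot]
            if span <= 0.0:
                continue
            xb = lin_left[slot] + rng.random() * span
            if lin_left[slot] < xb < lin_right[slot]:
                _recombine(seg_l, seg_r, seg_m0, seg_m1, seg_next,
                           lin_head, lin_birth, lin_bg, lin_left, lin_right,
                           lin_stamp, active, pos_in_active, lin_free, fen,
                           fen_n,
                           mut_pos, mut_m0, mut_m1, sf, si,
                           slot, xb, mu, rng)
    if si[SI_ERR] != 0:
        return -1
    if si[SI_NACT] <= 1:
        return 1
    return 0


@njit(cache=True)
def run_sweep(seg_l, seg_r, seg_m0, seg_m1, seg_next,
              lin_head, lin_birth, lin_bg, lin_left, lin_right, lin_stamp,
              active, pos_in_active, lin_free, fen, fen_n,
              mut_pos, mut_m0, mut_m1, sf, si,
              freqs_forward, two_nb, x_sel, rec_per_bp, mu,
              full0, full1, rng):
    """Structured coalescent through the sweep phase, generation by generation.

    ``freqs_forward`` is the fixation-conditioned trajectory indexed by
    forward generation (freqs_forward[0] = 1/(2*N_b), last = 1).  Backward
    generation j uses the parent-generation frequency freqs_forward[dur - j];
    at j = dur the beneficial class has one chromosome, which coalesces all
    remaining B lineages into the founding mutant.

    Returns 0 normally, 1 if fully coalesced early, -1 on error.
    """
    dur = freqs_forward.shape[0] - 1
    parent_slot = np.full(2 * two_nb, -1, dtype=np.int64)
    parent_gen = np.full(2 * two_nb, -1, dtype=np.int64)
    snap = np.empty(active.shape[0], dtype=np.int64)
    snap_st = np.empty(active.shape[0], dtype=np.int64)
    for ii in range(si[SI_NACT]):
        lin_bg[active[ii]] = 0  # all sampled chromosomes carry the allele
    for j in range(1, dur + 1):
        if si[SI_NACT] <= 1:
            break
        if si[SI_ERR] != 0:
            return -1
        x = freqs_forward[dur - j]
        n_benef = np.int64(two_nb * x + 0.5)
        if n_benef < 1:
            n_benef = 1
        n_wild = two_nb - n_benef
        if n_wild < 1:
            n_wild = 1
        sf[SF_T] += 1.0

        # recombination pass over a snapshot of the current lineages
        k0 = si[SI_NACT]
        for ii in range(k0):
            snap[ii] = active[ii]
            snap_st[ii] = lin_stamp[active[ii]]
        for ii in range(k0):
            slot = snap[ii]
            if lin_head[slot] == -1 or lin_stamp[slot] != snap_st[ii]:
                continue
            lo = lin_left[slot] if lin_left[slot] < x_sel else x_sel
            hi = lin_right[slot] if lin_right[slot] > x_sel else x_sel
            if rng.random() >= rec_per_bp * (hi - lo):
                continue
            xb = lo + rng.random() * (hi - lo)
            new_bg = 0 if rng.random() < x else 1
            if lin_left[slot] < xb < lin_right[slot]:
                sl, sr = _recombine(seg_l, seg_r, seg_m0, seg_m1, seg_next,
                                    lin_head, lin_birth, lin_bg, lin_left,
                                    lin_right, lin_stamp, active,
                                    pos_in_active, lin_free, fen, fen_n,
                                    mut_pos, mut_m0, mut_m1,
                                    sf, si, slot, xb, mu, rng)
                if sl == -1:
                    return -1
                distal = sl if x_sel >= xb else sr
                lin_bg[distal] = new_bg
            else:
                # crossover between the material and the selected site
                lin_bg[slot] = new_bg

        # Wright-Fisher coalescence: lineages drawing the same parent merge
        k0 = si[SI_NACT]
        for ii in range(k0):
            snap[ii] = active[ii]
            snap_st[ii] = lin_stamp[active[ii]]
        for ii in range(k0):
            slot = snap[ii]
            if lin_head[slot] == -1 or lin_stamp[slot] != snap_st[ii]:
                continue
            if lin_bg[slot] == 0:
                p = rng.integers(0, n_benef)
            else:
                p = two_nb + rng.integers(0, n_wild)
            if parent_gen[p] != j or parent_slot[p] == -1:
                parent_gen[p] = j
                parent_slot[p] = slot
            else:
                occ = parent_slot[p]
                merged = _coalesce(seg_l, seg_r, seg_m0, seg_m1, seg_next,
                                   lin_head, lin_birth, lin_bg, lin_left,
                                   lin_right, lin_stamp, active, pos_in_active,
                                   lin_free, fen, fen_n, mut_pos, mut_m0,
                                   mut_m1, sf, si, occ, slot, full0, full1,
                                   mu, rng)
                if si[SI_ERR] != 0:
                    return -1
                parent_slot[p] = merged
    for ii in range(si[SI_NACT]):
        lin_bg[active[ii]] = 0
    if si[SI_ERR] != 0:
        return -1
    return 1 if si[SI_NACT] <= 1 else 0
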