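"""Numba core of the particle simulation.

State layout (n = total receptors, fixed for a run):
  pos      (n, 2) float64   positions, um; dimer members share the position
  species  (n,)   int64     0 = ErbB2, 1 = ErbB3
  liganded (n,)   bool      ErbB3 only; static per run
  open_    (n,)   bool      dimer competence, re-drawn per step for
                            unliganded ErbB3 monomers
  phos     (n, 2) bool      per-site phosphate (ErbB2 uses site 0 only)
  partner  (n,)   int64     index of the dimer partner, -1 if monomeric
  role     (n,)   int64     0 none, 1 activator, 2 receiver

Dimer composition kind k = species[i] + species[j]: 0 ErbB2/2, 1 ErbB2/3,
2 ErbB3/3.  Escape-table index: monomer -> species (0, 1); dimer -> 2 + k.

Sub-step order (fixed; see the methods note): conformation update,
diffusion with domain-gated and periodic boundaries, dissociation,
dimerization, phosphorylation/dephosphorylation, observation.

Randomness comes from an explicit xorshift128+ stream (state passed in as
a uint64[2] array) with a ziggurat normal sampler, so runs are exactly
reproducible from the seed and independent of the global numpy state.
"""

import math

import numpy as np
from numba import njit

# observation channels
NCH = 12
CH_TIME = 0
CH_MONO2 = 1
CH_MONO3 = 2
CH_D23 = 3
CH_D33 = 4
CH_D22 = 5
CH_P2 = 6       # ErbB2 receptors with their site phosphorylated
CH_P3 = 7       # ErbB3 receptors with >= 1 phosphorylated site
CH_P3_SITES = 8  # total phosphorylated ErbB3 sites
CH_IN2 = 9      # ErbB2 receptors currently inside an ErbB2 domain
CH_IN3 = 10     # ErbB3 receptors currently inside an ErbB3 domain
CH_OPEN3 = 11   # currently dimer-competent ErbB3 monomers

_EPS = 1e-12

# ---------------------------------------------------------------------------
# random numbers: xorshift128+ and a 128-layer ziggurat normal sampler
# ---------------------------------------------------------------------------

_ZIG_N = 128
_ZIG_R = 3.442619855899
_ZIG_V = 9.91256303526217e-3


def _zig_tables():
    f = math.exp(-0.5 * _ZIG_R * _ZIG_R)
    x = np.zeros(_ZIG_N + 1)
    x[0] = _ZIG_V / f  # pseudo-width of the base strip
    x[1] = _ZIG_R
    for i in range(2, _ZIG_N):
        x[i] = math.sqrt(-2.0 * math.log(_ZIG_V / x[i - 1] + math.exp(-0.5 * x[i - 1] ** 2)))
    x[_ZIG_N] = 0.0
    ratio = x[1 : _ZIG_N + 1] / x[:_ZIG_N]
    return x, ratio


_ZIG_X, _ZIG_RATIO = _zig_tables()

_U64_23 = np.uint64(23)
_U64_17 = np.uint64(17)
_U64_26 = np.uint64(26)
_U64_11 = np.uint64(11)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True)
def seed_rng(seed):
    """xorshift128+ state from a seed via splitmix64."""
    rng = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z += np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        rng[i] = t ^ (t >> np.uint64(31))
    if rng[0] == 0 and rng[1] == 0:
        rng[0] = np.uint64(1)
    return rng


# Scalar-state variants: the xorshift128+ state is threaded through the
# hot loops as two uint64 locals so it stays in registers.


@njit(cache=True, inline="always")
def _u01_s(s0, s1):
    x = s0
    y = s1
    s0 = y
    x ^= x << _U64_23
    s1 = x ^ y ^ (x >> _U64_17) ^ (y >> _U64_26)
    return s0, s1, float((s1 + y) >> _U64_11) * _INV_2_53


@njit(cache=True)
def _normal_slow_s(s0, s1, zx, zratio, i, u):
    """Wedge/tail path of the ziggurat (rarely taken)."""
    while True:
        if i == 0:
            # tail beyond R
            while True:
                s0, s1, u1 = _u01_s(s0, s1)
                s0, s1, u2 = _u01_s(s0, s1)
                if u1 <= 0.0 or u2 <= 0.0:
                    continue
                xt = -math.log(u1) / _ZIG_R
                yt = -math.log(u2)
                if yt + yt > xt * xt:
                    t = _ZIG_R + xt
                    return s0, s1, t if u > 0.0 else -t
        else:
            x = u * zx[i]
            f0 = math.exp(-0.5 * (zx[i] * zx[i] - x * x))
            f1 = math.exp(-0.5 * (zx[i + 1] * zx[i + 1] - x * x))
            s0, s1, w = _u01_s(s0, s1)
            if f1 + w * (f0 - f1) < 1.0:
                return s0, s1, x
        x = s0
        y = s1
        s0 = y
        x ^= x << _U64_23
        s1 = x ^ y ^ (x >> _U64_17) ^ (y >> _U64_26)
        bits = s1 + y
        i = int(bits & np.uint64(0x7F))
        u = 2.0 * (float(bits >> _U64_11) * _INV_2_53) - 1.0
        if abs(u) < zratio[i]:
            return s0, s1, u * zx[i]


@njit(cache=True, inline="always")
def _normal_s(s0, s1, zx, zratio):
    """Standard normal deviate (Doornik-style ziggurat), scalar state."""
    x = s0
    y = s1
    s0 = y
    x ^= x << _U64_23
    s1 = x ^ y ^ (x >> _U64_17) ^ (y >> _U64_26)
    bits = s1 + y
    i = int(bits & np.uint64(0x7F))
    u = 2.0 * (float(bits >> _U64_11) * _INV_2_53) - 1.0
    if abs(u) < zratio[i]:
        return s0, s1, u * zx[i]
    return _normal_slow_s(s0, s1, zx, zratio, i, u)


@njit(cache=True)
def normal01(rng, zx, zratio):
    """Standard normal deviate drawn from an array-state stream (testing
    surface over the scalar-state sampler)."""
    s0, s1, v = _normal_s(rng[0], rng[1], zx, zratio)
    rng[0] = s0
    rng[1] = s1
    return v


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def wrap_coordinate(v, L):
    """Periodic wrap of a coordinate into [0, L).

    A displacement never exceeds one box length, so a single fold
    suffices: the distance past one edge is continued from the opposite
    edge.
    """
    if v < 0.0:
        v += L
    elif v >= L:
        v -= L
    return v


@njit(cache=True, inline="always")
def _in_rect(x, y, r):
    # half-open membership: lower edges included
    return r[0] <= x < r[2] and r[1] <= y < r[3]


@njit(cache=True)
def resolve_confinement(x0, y0, dx, dy, rects, idx, n_idx, p_esc, s0, s1):
    """Advance a particle from (x0, y0) by (dx, dy) through the confinement
    rectangles ``rects[idx[:n_idx]]``.

    Entering a rectangle is free.  Each outbound edge crossing takes one
    uniform draw: with probability ``p_esc`` the particle continues across
    unchanged, otherwise the remaining displacement is mirror-reflected
    back inside.  Crossings are resolved sequentially along the path.
    Returns the final (unwrapped) position and the random stream state:
    ``(x, y, s0, s1)``.
    """
    x = x0
    y = y0
    for _ in range(64):
        if dx == 0.0 and dy == 0.0:
            break
        t_best = 2.0
        best_m = -1
        best_axis = 0
        best_exit = False
        xe = x + dx
        ye = y + dy
        bx0 = min(x, xe)
        bx1 = max(x, xe)
        by0 = min(y, ye)
        by1 = max(y, ye)
        for q in range(n_idx):
            mi = idx[q]
            r0 = rects[mi, 0]
            r1 = rects[mi, 1]
            r2 = rects[mi, 2]
            r3 = rects[mi, 3]
            if bx1 < r0 or bx0 > r2 or by1 < r1 or by0 > r3:
                continue
            if r0 <= x < r2 and r1 <= y < r3:
                t_exit = 2.0
                axis = 0
                if dx > 0.0:
                    t = (r2 - x) / dx
                    if t < t_exit:
                        t_exit = t
                        axis = 0
                elif dx < 0.0:
                    t = (r0 - x) / dx
                    if t < t_exit:
                        t_exit = t
                        axis = 0
                if dy > 0.0:
                    t = (r3 - y) / dy
                    if t < t_exit:
                        t_exit = t
                        axis = 1
                elif dy < 0.0:
                    t = (r1 - y) / dy
                    if t < t_exit:
                        t_exit = t
                        axis = 1
                if t_exit <= 1.0 and t_exit < t_best:
                    t_best = t_exit
                    best_m = mi
                    best_axis = axis
                    best_exit = True
            else:
                # slab test for an inbound crossing
                t_enter = 0.0
                t_leave = 1.0
                axis = 0
                ok = True
                if dx != 0.0:
                    inv = 1.0 / dx
                    t1 = (r0 - x) * inv
                    t2 = (r2 - x) * inv
                    if t1 > t2:
                        tmp = t1
                        t1 = t2
                        t2 = tmp
                    if t1 > t_enter:
                        t_enter = t1
                        axis = 0
                    if t2 < t_leave:
                        t_leave = t2
                elif x < r0 or x >= r2:
                    ok = False
                if ok and dy != 0.0:
                    inv = 1.0 / dy
                    t1 = (r1 - y) * inv
                    t2 = (r3 - y) * inv
                    if t1 > t2:
                        tmp = t1
                        t1 = t2
                        t2 = tmp
                    if t1 > t_enter:
                        t_enter = t1
                        axis = 1
                    if t2 < t_leave:
                        t_leave = t2
                elif ok and (y < r1 or y >= r3):
                    ok = False
                if ok and 0.0 < t_enter <= 1.0 and t_enter < t_leave and t_enter < t_best:
                    t_best = t_enter
                    best_m = mi
                    best_axis = axis
                    best_exit = False
        if best_m < 0:
            x += dx
            y += dy
            break
        # advance to the event point (direction signs before rescaling)
        fwd_x = dx > 0.0
        fwd_y = dy > 0.0
        x += t_best * dx
        y += t_best * dy
        dx *= 1.0 - t_best
        dy *= 1.0 - t_best
        r0 = rects[best_m, 0]
        r1 = rects[best_m, 1]
        r2 = rects[best_m, 2]
        r3 = rects[best_m, 3]
        if best_exit:
            s0, s1, w = _u01_s(s0, s1)
            if w < p_esc:
                # escapes: nudge across so membership flips
                if best_axis == 0:
                    x = r2 + _EPS if fwd_x else r0 - _EPS
                else:
                    y = r3 + _EPS if fwd_y else r1 - _EPS
            else:
                # reflected: flip the crossed component, nudge back inside
                if best_axis == 0:
                    x = r2 - _EPS if fwd_x else r0 + _EPS
                    dx = -dx
                else:
                    y = r3 - _EPS if fwd_y else r1 + _EPS
                    dy = -dy
        else:
            # free entry: nudge inside
            if best_axis == 0:
                x = r0 + _EPS if fwd_x else r2 - _EPS
            else:
                y = r1 + _EPS if fwd_y else r3 - _EPS
    return x, y, s0, s1


@njit(cache=True, inline="always")
def _membership(x, y, rects, sp_idx, n_sp):
    """Index of the (unique, same-species rects are disjoint) rectangle of
    one species containing the point, or -1."""
    for q in range(n_sp):
        mi = sp_idx[q]
        if (
            rects[mi, 0] <= x < rects[mi, 2]
            and rects[mi, 1] <= y < rects[mi, 3]
        ):
            return mi
    return -1


# ---------------------------------------------------------------------------
# observation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _record(out, row, t, n, species, liganded, open_, phos, partner,
            pos, cur_own, states, record_states):
    mono2 = 0
    mono3 = 0
    d23 = 0
    d33 = 0
    d22 = 0
    p2 = 0
    p3 = 0
    p3s = 0
    in2 = 0
    in3 = 0
    open3 = 0
    for i in range(n):
        s = species[i]
        j = partner[i]
        if j < 0:
            if s == 0:
                mono2 += 1
            else:
                mono3 += 1
                if open_[i]:
                    open3 += 1
        elif j > i:
            k = s + species[j]
            if k == 0:
                d22 += 1
            elif k == 1:
                d23 += 1
            else:
                d33 += 1
        if s == 0:
            if phos[i, 0]:
                p2 += 1
            if cur_own[i] >= 0:
                in2 += 1
        else:
            ns = 0
            if phos[i, 0]:
                ns += 1
            if phos[i, 1]:
                ns += 1
            p3s += ns
            if ns > 0:
                p3 += 1
            if cur_own[i] >= 0:
                in3 += 1
        if record_states:
            code = 0
            if j >= 0:
                code = 1 if s + species[j] == 1 else 2
            if phos[i, 0] or phos[i, 1]:
                code += 3
            states[row, i] = code
    out[row, CH_TIME] = t
    out[row, CH_MONO2] = mono2
    out[row, CH_MONO3] = mono3
    out[row, CH_D23] = d23
    out[row, CH_D33] = d33
    out[row, CH_D22] = d22
    out[row, CH_P2] = p2
    out[row, CH_P3] = p3
    out[row, CH_P3_SITES] = p3s
    out[row, CH_IN2] = in2
    out[row, CH_IN3] = in3
    out[row, CH_OPEN3] = open3


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def run(seed, n_steps, obs_every, t0, dt,
        pos, species, liganded, open_, phos, partner, role,
        rects, rect_species, Lx, Ly,
        D_mono, D_dim, r_b, p_off, p_phos, p_basal, p_deph,
        p_open_step, esc, p22_mult, unbind_factor,
        out, states, record_states):
    """Advance the state ``n_steps`` timesteps, recording every
    ``obs_every`` steps into ``out`` (row 0 is the state on entry).

    All probability tables are per-step probabilities; ``esc`` is indexed
    by particle kind [mono ErbB2, mono ErbB3, 2/2, 2/3, 3/3] and already
    scaled.  Returns the number of rows written.
    """
    rng = seed_rng(seed)
    s0 = rng[0]
    s1 = rng[1]
    zx = _ZIG_X
    zratio = _ZIG_RATIO
    n = pos.shape[0]
    m = rects.shape[0]

    # per-species rect index lists
    sp2_idx = np.empty(m, dtype=np.int64)
    sp3_idx = np.empty(m, dtype=np.int64)
    n_sp2 = 0
    n_sp3 = 0
    for mi in range(m):
        if rect_species[mi] == 0:
            sp2_idx[n_sp2] = mi
            n_sp2 += 1
        else:
            sp3_idx[n_sp3] = mi
            n_sp3 += 1

    # current confining rect per particle and species (-1: none)
    curA = np.empty(n, dtype=np.int64)  # ErbB2-species rect containing pos
    curB = np.empty(n, dtype=np.int64)  # ErbB3-species rect containing pos
    for i in range(n):
        curA[i] = _membership(pos[i, 0], pos[i, 1], rects, sp2_idx, n_sp2)
        curB[i] = _membership(pos[i, 0], pos[i, 1], rects, sp3_idx, n_sp3)
    cur_own = np.empty(n, dtype=np.int64)
    for i in range(n):
        cur_own[i] = curA[i] if species[i] == 0 else curB[i]

    # precomputed per-axis step widths
    sd_mono = np.sqrt(2.0 * D_mono * dt)
    sd_dim = np.sqrt(2.0 * D_dim * dt)

    rb_max = max(r_b[0], max(r_b[1], r_b[2]))

    # x-binning for the pair search; bins must be wider than any r_b
    nb = 64
    bw = Lx / nb
    while bw <= rb_max and nb > 1:
        nb //= 2
        bw = Lx / nb
    if nb == 2:  # adjacent-bin scan would double-count with two bins
        nb = 1
        bw = Lx
    bin_count = np.zeros(nb, dtype=np.int64)
    bin_start = np.zeros(nb + 1, dtype=np.int64)
    bin_items = np.zeros(n, dtype=np.int64)
    open_idx = np.zeros(n, dtype=np.int64)

    cap = 256
    cand_i = np.zeros(cap, dtype=np.int64)
    cand_j = np.zeros(cap, dtype=np.int64)
    cand_d2 = np.zeros(cap)
    cur_idx = np.empty(2, dtype=np.int64)

    row = 0
    _record(out, row, t0, n, species, liganded, open_, phos, partner,
            pos, cur_own, states, record_states)
    row += 1

    for step in range(1, n_steps + 1):
        # --- 1. conformational gating (monomers only) ---
        for i in range(n):
            if partner[i] < 0 and species[i] == 1 and not liganded[i]:
                s0, s1, w = _u01_s(s0, s1)
                open_[i] = w < p_open_step

        # --- 2. diffusion with boundary handling ---
        for i in range(n):
            j = partner[i]
            if j >= 0 and j < i:
                continue  # moved together with its partner
            s = species[i]
            n_cur = 0
            if j < 0:
                kidx = s
                sd = sd_mono[s]
                if s == 0:
                    if curA[i] >= 0:
                        cur_idx[0] = curA[i]
                        n_cur = 1
                else:
                    if curB[i] >= 0:
                        cur_idx[0] = curB[i]
                        n_cur = 1
            else:
                k = s + species[j]
                anyph = phos[i, 0] or phos[i, 1] or phos[j, 0] or phos[j, 1]
                sd = sd_dim[k, 1] if anyph else sd_dim[k, 0]
                kidx = 2 + k
                if k == 0:
                    if curA[i] >= 0:
                        cur_idx[0] = curA[i]
                        n_cur = 1
                elif k == 2:
                    if curB[i] >= 0:
                        cur_idx[0] = curB[i]
                        n_cur = 1
                else:
                    if curA[i] >= 0:
                        cur_idx[n_cur] = curA[i]
                        n_cur += 1
                    if curB[i] >= 0:
                        cur_idx[n_cur] = curB[i]
                        n_cur += 1
            s0, s1, g = _normal_s(s0, s1, zx, zratio)
            dx = g * sd
            s0, s1, g = _normal_s(s0, s1, zx, zratio)
            dy = g * sd
            if n_cur > 0:
                x, y, s0, s1 = resolve_confinement(
                    pos[i, 0], pos[i, 1], dx, dy,
                    rects, cur_idx, n_cur, esc[kidx], s0, s1,
                )
            else:
                x = pos[i, 0] + dx
                y = pos[i, 1] + dy
            x = wrap_coordinate(x, Lx)
            y = wrap_coordinate(y, Ly)
            pos[i, 0] = x
            pos[i, 1] = y
            # membership update (own species for monomers/homodimers,
            # both species for heterodimers)
            if j < 0:
                if s == 0:
                    curA[i] = _membership(x, y, rects, sp2_idx, n_sp2)
                    cur_own[i] = curA[i]
                else:
                    curB[i] = _membership(x, y, rects, sp3_idx, n_sp3)
                    cur_own[i] = curB[i]
            else:
                k = s + species[j]
                if k != 2:
                    curA[i] = _membership(x, y, rects, sp2_idx, n_sp2)
                if k != 0:
                    curB[i] = _membership(x, y, rects, sp3_idx, n_sp3)
                curA[j] = curA[i]
                curB[j] = curB[i]
                cur_own[i] = curA[i] if s == 0 else curB[i]
                cur_own[j] = curA[j] if species[j] == 0 else curB[j]
                pos[j, 0] = x
                pos[j, 1] = y

        # --- 3. dissociation ---
        for i in range(n):
            j = partner[i]
            if j <= i:
                continue
            k = species[i] + species[j]
            nl = (1 if liganded[i] else 0) + (1 if liganded[j] else 0)
            s0, s1, w = _u01_s(s0, s1)
            if w < p_off[k, nl]:
                s0, s1, w = _u01_s(s0, s1)
                theta = 2.0 * math.pi * w
                rr = 0.5 * unbind_factor * r_b[k]
                cx = pos[i, 0]
                cy = pos[i, 1]
                ox = rr * math.cos(theta)
                oy = rr * math.sin(theta)
                for which in range(2):
                    w = i if which == 0 else j
                    x = wrap_coordinate(cx + ox if which == 0 else cx - ox, Lx)
                    y = wrap_coordinate(cy + oy if which == 0 else cy - oy, Ly)
                    pos[w, 0] = x
                    pos[w, 1] = y
                    if species[w] == 0:
                        curA[w] = _membership(x, y, rects, sp2_idx, n_sp2)
                        cur_own[w] = curA[w]
                    else:
                        curB[w] = _membership(x, y, rects, sp3_idx, n_sp3)
                        cur_own[w] = curB[w]
                partner[i] = -1
                partner[j] = -1
                role[i] = 0
                role[j] = 0
                open_[i] = species[i] == 0 or liganded[i]
                open_[j] = species[j] == 0 or liganded[j]

        # --- 4. dimerization (closest pair first) ---
        n_open = 0
        for i in range(n):
            if partner[i] < 0 and open_[i]:
                open_idx[n_open] = i
                n_open += 1
        n_cand = 0
        if n_open > 1:
            for b in range(nb):
                bin_count[b] = 0
            for u in range(n_open):
                b = int(pos[open_idx[u], 0] / bw)
                if b >= nb:
                    b = nb - 1
                bin_count[b] += 1
            bin_start[0] = 0
            for b in range(nb):
                bin_start[b + 1] = bin_start[b] + bin_count[b]
                bin_count[b] = 0
            for u in range(n_open):
                i = open_idx[u]
                b = int(pos[i, 0] / bw)
                if b >= nb:
                    b = nb - 1
                bin_items[bin_start[b] + bin_count[b]] = i
                bin_count[b] += 1
            for b in range(nb):
                q0 = bin_start[b]
                e0 = bin_start[b + 1]
                b1 = b + 1 if b + 1 < nb else 0
                q1 = bin_start[b1]
                e1 = bin_start[b1 + 1]
                for u in range(q0, e0):
                    i = bin_items[u]
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    for v in range(u + 1, e0):
                        jj = bin_items[v]
                        n_cand = _try_candidate(i, jj, xi, yi, pos, species, r_b,
                                                Lx, Ly, cand_i, cand_j, cand_d2,
                                                n_cand, cap)
                    if nb > 1:
                        for v in range(q1, e1):
                            jj = bin_items[v]
                            n_cand = _try_candidate(i, jj, xi, yi, pos, species, r_b,
                                                    Lx, Ly, cand_i, cand_j, cand_d2,
                                                    n_cand, cap)
        if n_cand > 1:
            # selection sort by (distance, lower id)
            for a in range(n_cand - 1):
                best = a
                for c in range(a + 1, n_cand):
                    if cand_d2[c] < cand_d2[best] or (
                        cand_d2[c] == cand_d2[best]
                        and min(cand_i[c], cand_j[c]) < min(cand_i[best], cand_j[best])
                    ):
                        best = c
                if best != a:
                    cand_d2[a], cand_d2[best] = cand_d2[best], cand_d2[a]
                    cand_i[a], cand_i[best] = cand_i[best], cand_i[a]
                    cand_j[a], cand_j[best] = cand_j[best], cand_j[a]
        for c in range(n_cand):
            i = cand_i[c]
            jj = cand_j[c]
            if partner[i] >= 0 or partner[jj] >= 0:
                continue
            k = species[i] + species[jj]
            if k == 0 and p22_mult < 1.0:
                s0, s1, w = _u01_s(s0, s1)
                if w >= p22_mult:
                    continue
            partner[i] = jj
            partner[jj] = i
            s0, s1, w = _u01_s(s0, s1)
            if w < 0.5:
                role[i] = 1
                role[jj] = 2
            else:
                role[i] = 2
                role[jj] = 1
            ddx = pos[jj, 0] - pos[i, 0]
            ddx -= Lx * round(ddx / Lx)
            ddy = pos[jj, 1] - pos[i, 1]
            ddy -= Ly * round(ddy / Ly)
            mx = wrap_coordinate(pos[i, 0] + 0.5 * ddx, Lx)
            my = wrap_coordinate(pos[i, 1] + 0.5 * ddy, Ly)
            pos[i, 0] = mx
            pos[i, 1] = my
            pos[jj, 0] = mx
            pos[jj, 1] = my
            curA[i] = _membership(mx, my, rects, sp2_idx, n_sp2)
            curB[i] = _membership(mx, my, rects, sp3_idx, n_sp3)
            curA[jj] = curA[i]
            curB[jj] = curB[i]
            cur_own[i] = curA[i] if species[i] == 0 else curB[i]
            cur_own[jj] = curA[jj] if species[jj] == 0 else curB[jj]

        # --- 5. phosphorylation / dephosphorylation ---
        for i in range(n):
            j = partner[i]
            if j >= 0 and role[i] == 1:
                # i is the activator; j phosphorylates it when competent
                if species[j] == 0 or phos[j, 0] or phos[j, 1]:
                    kp = p_phos[species[i]]
                else:
                    kp = p_basal[species[i]]
                nsite = 1 if species[i] == 0 else 2
                for st in range(nsite):
                    if not phos[i, st]:
                        s0, s1, w = _u01_s(s0, s1)
                        if w < kp:
                            phos[i, st] = True
        for i in range(n):
            nsite = 1 if species[i] == 0 else 2
            for st in range(nsite):
                if phos[i, st]:
                    s0, s1, w = _u01_s(s0, s1)
                    if w < p_deph[species[i], st]:
                        phos[i, st] = False

        # --- 6. observation ---
        if step % obs_every == 0:
            _record(out, row, t0 + step * dt, n, species, liganded, open_, phos,
                    partner, pos, cur_own, states, record_states)
            row += 1
    return row


@njit(cache=True, inline="always")
def _try_candidate(i, jj, xi, yi, pos, species, r_b, Lx, Ly,
                   cand_i, cand_j, cand_d2, n_cand, cap):
    k = species[i] + species[jj]
    rb = r_b[k]
    dx = pos[jj, 0] - xi
    if dx > 0.5 * Lx:
        dx -= Lx
    elif dx < -0.5 * Lx:
        dx += Lx
    if dx > rb or dx < -rb:
        return n_cand
    dy = pos[jj, 1] - yi
    if dy > 0.5 * Ly:
        dy -= Ly
    elif dy < -0.5 * Ly:
        dy += Ly
    if dy > rb or dy < -rb:
        return n_cand
    d2 = dx * dx + dy * dy
    if d2 < rb * rb and n_cand < cap:
        cand_i[n_cand] = i
        cand_j[n_cand] = jj
        cand_d2[n_cand] = d2
        return n_cand + 1
    return n_cand
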