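"""Numba kernels for the lattice Monte Carlo engine.

State layout (flat arrays, shared with :mod:`condmix.lattice`):

``pos``          (N, 3) int64   bead coordinates in [0, L)
``typ``          (N,)   int64   sticker class index (0 protein, 1/2 RNA)
``chain_of``     (N,)   int64   molecule index of each bead
``chain_start``  (M,)   int64   first bead index of each molecule
``chain_len``    (M,)   int64   bead count of each molecule
``bond``         (N,)   int64   anisotropic bond partner, -1 if unbonded
``occ``          (L^3,) int64   site -> bead index, -1 if empty

Geometry: simple cubic lattice, periodic.  Contact neighborhood = the 26
surrounding sites (squared distance <= 3); implicit linkers allow squared
distances 1..4 between consecutive beads.  Anisotropic sticker energies are
carried by explicit mutually exclusive bonds; isotropic contact energies are
summed over all occupied neighbor pairs.  Metropolis acceptance uses
exp(-dE/T); the bond make/break move carries the Metropolis-Hastings
proposal-ratio correction required because candidate counts differ between
the make and break directions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 26-site contact neighborhood (1 <= d^2 <= 3)
_nb = [(dx, dy, dz)
       for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
       if (dx, dy, dz) != (0, 0, 0)]
NB26 = np.array(_nb, dtype=np.int64)

# legal linker placements (1 <= d^2 <= 4), 32 offsets
_ball = [(dx, dy, dz)
         for dx in range(-2, 3) for dy in range(-2, 3) for dz in range(-2, 3)
         if 0 < dx * dx + dy * dy + dz * dz <= 4]
BALL32 = np.array(_ball, dtype=np.int64)

LINKER_D2 = 4   # squared linker reach
CONTACT_D2 = 3  # squared contact radius

# move indices, matching condmix.config.MOVE_ORDER
M_LOCAL, M_PIVOT, M_REPT, M_CHAIN, M_CLUSTER, M_BOND = 0, 1, 2, 3, 4, 5

# constraint modes
C_OFF, C_HEAVISIDE, C_DELTA = 0, 1, 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _site(x, y, z, L):
    return (x * L + y) * L + z


@njit(cache=True, inline="always")
def _wrap(c, L):
    if c >= L:
        return c - L
    if c < 0:
        return c + L
    return c


@njit(cache=True, inline="always")
def _mind(d, L):
    # minimum-image component difference
    d = d % L
    if 2 * d > L:
        d -= L
    return d


@njit(cache=True, inline="always")
def _d2(ax, ay, az, bx, by, bz, L):
    dx = _mind(ax - bx, L)
    dy = _mind(ay - by, L)
    dz = _mind(az - bz, L)
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _iso_at(pos, typ, occ, L, iso, ti, px, py, pz, skip_i, skip_j):
    """Isotropic contact energy of a bead of type ti at (px,py,pz).

    ``skip_i``/``skip_j`` are bead indices to ignore (the bead itself, and
    optionally a second bead treated as absent); pass -1 to ignore nothing.
    """
    e = 0.0
    for k in range(26):
        x = _wrap(px + NB26[k, 0], L)
        y = _wrap(py + NB26[k, 1], L)
        z = _wrap(pz + NB26[k, 2], L)
        j = occ[_site(x, y, z, L)]
        if j >= 0 and j != skip_i and j != skip_j:
            e += iso[ti, typ[j]]
    return e


@njit(cache=True, inline="always")
def _constraint(px, py, pz, L, cmode, T, T0, RB):
    if cmode == C_OFF:
        return 0.0
    cx = L / 2.0
    r2 = (px - cx) ** 2 + (py - cx) ** 2 + (pz - cx) ** 2
    if cmode == C_HEAVISIDE:
        if r2 > RB * RB:  # H(0) = 0: inactive exactly at r = RB
            return T * r2
        return 0.0
    return (T - T0) * r2


@njit(cache=True)
def _n_bond_candidates(pos, typ, bond, occ, L, aniso, i, free_a, free_b):
    """Number of eligible bond partners of bead i in its 26-neighborhood.

    A neighbor j is eligible if it is unbonded (beads ``free_a``/``free_b``
    are treated as unbonded regardless) and the anisotropic energy between
    the two sticker classes is nonzero.
    """
    n = 0
    px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
    for k in range(26):
        x = _wrap(px + NB26[k, 0], L)
        y = _wrap(py + NB26[k, 1], L)
        z = _wrap(pz + NB26[k, 2], L)
        j = occ[_site(x, y, z, L)]
        if j >= 0 and j != i and aniso[typ[i], typ[j]] != 0.0:
            if bond[j] == -1 or j == free_a or j == free_b:
                n += 1
    return n


@njit(cache=True)
def _kth_bond_candidate(pos, typ, bond, occ, L, aniso, i, k_pick):
    n = 0
    px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
    for k in range(26):
        x = _wrap(px + NB26[k, 0], L)
        y = _wrap(py + NB26[k, 1], L)
        z = _wrap(pz + NB26[k, 2], L)
        j = occ[_site(x, y, z, L)]
        if j >= 0 and j != i and aniso[typ[i], typ[j]] != 0.0 and bond[j] == -1:
            if n == k_pick:
                return j
            n += 1
    return -1


@njit(cache=True)
def _attempt(pos, typ, chain_of, chain_start, chain_len, bond, occ, L,
             aniso, iso, cum_w, aniso_on, cmode, T, T0, RB,
             scratch_idx, scratch_flag):
    """One elementary move attempt.  Returns the applied interaction-energy
    change (anisotropic + isotropic, excluding the constraint term)."""
    N = pos.shape[0]
    M = chain_start.shape[0]
    u = np.random.random()
    move = 0
    while move < 5 and u > cum_w[move]:
        move += 1

    if move == M_BOND:
        if not aniso_on:
            return 0.0
        i = np.random.randint(N)
        if bond[i] == -1:
            n_i = _n_bond_candidates(pos, typ, bond, occ, L, aniso, i, -1, -1)
            if n_i == 0:
                return 0.0
            j = _kth_bond_candidate(pos, typ, bond, occ, L, aniso, i,
                                    np.random.randint(n_i))
            n_j = _n_bond_candidates(pos, typ, bond, occ, L, aniso, j, -1, -1)
            dE = aniso[typ[i], typ[j]]
            # forward: pick i (or j) then this partner; reverse: pick either
            # bead of the bond and propose the break
            q_ratio = 2.0 / (1.0 / n_i + 1.0 / n_j)
            acc = np.exp(-dE / T) * q_ratio
            if acc >= 1.0 or np.random.random() < acc:
                bond[i] = j
                bond[j] = i
                return dE
            return 0.0
        else:
            j = bond[i]
            dE = -aniso[typ[i], typ[j]]
            # candidate counts in the post-break state (i, j both free)
            n_i = _n_bond_candidates(pos, typ, bond, occ, L, aniso, i, i, j)
            n_j = _n_bond_candidates(pos, typ, bond, occ, L, aniso, j, i, j)
            q_ratio = (1.0 / n_i + 1.0 / n_j) / 2.0
            acc = np.exp(-dE / T) * q_ratio
            if acc >= 1.0 or np.random.random() < acc:
                bond[i] = -1
                bond[j] = -1
                return dE
            return 0.0

    if move == M_LOCAL:
        i = np.random.randint(N)
        k = np.random.randint(26)
        nx = _wrap(pos[i, 0] + NB26[k, 0], L)
        ny = _wrap(pos[i, 1] + NB26[k, 1], L)
        nz = _wrap(pos[i, 2] + NB26[k, 2], L)
        if occ[_site(nx, ny, nz, L)] != -1:
            return 0.0
        c = chain_of[i]
        s = chain_start[c]
        ln = chain_len[c]
        if i > s:  # previous bead in chain
            p = i - 1
            if _d2(nx, ny, nz, pos[p, 0], pos[p, 1], pos[p, 2], L) > LINKER_D2:
                return 0.0
        if i < s + ln - 1:
            p = i + 1
            if _d2(nx, ny, nz, pos[p, 0], pos[p, 1], pos[p, 2], L) > LINKER_D2:
                return 0.0
        if bond[i] != -1:
            p = bond[i]
            if _d2(nx, ny, nz, pos[p, 0], pos[p, 1], pos[p, 2], L) > CONTACT_D2:
                return 0.0
        ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
        e_old = _iso_at(pos, typ, occ, L, iso, typ[i], ox, oy, oz, i, -1)
        e_new = _iso_at(pos, typ, occ, L, iso, typ[i], nx, ny, nz, i, -1)
        dE = e_new - e_old
        dV = (_constraint(nx, ny, nz, L, cmode, T, T0, RB)
              - _constraint(ox, oy, oz, L, cmode, T, T0, RB))
        acc_arg = -(dE + dV) / T
        if acc_arg >= 0.0 or np.random.random() < np.exp(acc_arg):
            occ[_site(ox, oy, oz, L)] = -1
            occ[_site(nx, ny, nz, L)] = i
            pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
            return dE
        return 0.0

    if move == M_PIVOT:
        c = np.random.randint(M)
        ln = chain_len[c]
        if ln < 2:
            return 0.0
        s = chain_start[c]
        if np.random.random() < 0.5:
            i, anchor = s, s + 1
        else:
            i, anchor = s + ln - 1, s + ln - 2
        k = np.random.randint(32)
        nx = _wrap(pos[anchor, 0] + BALL32[k, 0], L)
        ny = _wrap(pos[anchor, 1] + BALL32[k, 1], L)
        nz = _wrap(pos[anchor, 2] + BALL32[k, 2], L)
        ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
        tgt = occ[_site(nx, ny, nz, L)]
        if tgt != -1 and tgt != i:
            return 0.0
        if bond[i] != -1:
            p = bond[i]
            if _d2(nx, ny, nz, pos[p, 0], pos[p, 1], pos[p, 2], L) > CONTACT_D2:
                return 0.0
        if tgt == i:  # proposed its own site: no-op accept
            return 0.0
        e_old = _iso_at(pos, typ, occ, L, iso, typ[i], ox, oy, oz, i, -1)
        e_new = _iso_at(pos, typ, occ, L, iso, typ[i], nx, ny, nz, i, -1)
        dE = e_new - e_old
        dV = (_constraint(nx, ny, nz, L, cmode, T, T0, RB)
              - _constraint(ox, oy, oz, L, cmode, T, T0, RB))
        acc_arg = -(dE + dV) / T
        if acc_arg >= 0.0 or np.random.random() < np.exp(acc_arg):
            occ[_site(ox, oy, oz, L)] = -1
            occ[_site(nx, ny, nz, L)] = i
            pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
            return dE
        return 0.0

    if move == M_REPT:
        c = np.random.randint(M)
        ln = chain_len[c]
        if ln < 2:
            return 0.0
        s = chain_start[c]
        for b in range(s, s + ln):
            if bond[b] != -1:
                return 0.0
        head_first = np.random.random() < 0.5
        if head_first:
            head, tail = s + ln - 1, s
        else:
            head, tail = s, s + ln - 1
        k = np.random.randint(32)
        nx = _wrap(pos[head, 0] + BALL32[k, 0], L)
        ny = _wrap(pos[head, 1] + BALL32[k, 1], L)
        nz = _wrap(pos[head, 2] + BALL32[k, 2], L)
        tx, ty, tz = pos[tail, 0], pos[tail, 1], pos[tail, 2]
        tgt = occ[_site(nx, ny, nz, L)]
        if tgt != -1 and tgt != tail:
            return 0.0
        ti = typ[head]
        # energy change equals: remove the tail site, add the new head site
        e_old = _iso_at(pos, typ, occ, L, iso, ti, tx, ty, tz, tail, -1)
        e_new = _iso_at(pos, typ, occ, L, iso, ti, nx, ny, nz, tail, -1)
        dE = e_new - e_old
        dV = (_constraint(nx, ny, nz, L, cmode, T, T0, RB)
              - _constraint(tx, ty, tz, L, cmode, T, T0, RB))
        acc_arg = -(dE + dV) / T
        if acc_arg >= 0.0 or np.random.random() < np.exp(acc_arg):
            occ[_site(tx, ty, tz, L)] = -1
            if head_first:
                for b in range(s, s + ln - 1):
                    pos[b, 0] = pos[b + 1, 0]
                    pos[b, 1] = pos[b + 1, 1]
                    pos[b, 2] = pos[b + 1, 2]
            else:
                for b in range(s + ln - 1, s, -1):
                    pos[b, 0] = pos[b - 1, 0]
                    pos[b, 1] = pos[b - 1, 1]
                    pos[b, 2] = pos[b - 1, 2]
            pos[head, 0], pos[head, 1], pos[head, 2] = nx, ny, nz
            for b in range(s, s + ln):
                occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = b
            return dE
        return 0.0

    if move == M_CHAIN:
        c = np.random.randint(M)
        s = chain_start[c]
        ln = chain_len[c]
        k = np.random.randint(26)
        dx, dy, dz = NB26[k, 0], NB26[k, 1], NB26[k, 2]
        for b in range(s, s + ln):
            nx = _wrap(pos[b, 0] + dx, L)
            ny = _wrap(pos[b, 1] + dy, L)
            nz = _wrap(pos[b, 2] + dz, L)
            tgt = occ[_site(nx, ny, nz, L)]
            if tgt != -1 and chain_of[tgt] != c:
                return 0.0
            if bond[b] != -1 and chain_of[bond[b]] != c:
                p = bond[b]
                if _d2(nx, ny, nz, pos[p, 0], pos[p, 1], pos[p, 2],
                       L) > CONTACT_D2:
                    return 0.0
        # clear chain occupancy, then compare external iso energy
        for b in range(s, s + ln):
            occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = -1
        dE = 0.0
        for b in range(s, s + ln):
            dE -= _iso_at(pos, typ, occ, L, iso, typ[b],
                          pos[b, 0], pos[b, 1], pos[b, 2], -1, -1)
        dV = 0.0
        for b in range(s, s + ln):
            nx = _wrap(pos[b, 0] + dx, L)
            ny = _wrap(pos[b, 1] + dy, L)
            nz = _wrap(pos[b, 2] + dz, L)
            dE += _iso_at(pos, typ, occ, L, iso, typ[b], nx, ny, nz, -1, -1)
            dV += (_constraint(nx, ny, nz, L, cmode, T, T0, RB)
                   - _constraint(pos[b, 0], pos[b, 1], pos[b, 2],
                                 L, cmode, T, T0, RB))
        acc_arg = -(dE + dV) / T
        if acc_arg >= 0.0 or np.random.random() < np.exp(acc_arg):
            for b in range(s, s + ln):
                pos[b, 0] = _wrap(pos[b, 0] + dx, L)
                pos[b, 1] = _wrap(pos[b, 1] + dy, L)
                pos[b, 2] = _wrap(pos[b, 2] + dz, L)
                occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = b
            return dE
        # restore occupancy
        for b in range(s, s + ln):
            occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = b
        return 0.0

    # M_CLUSTER: translate a bond-connected cluster of molecules.  Accepted
    # only when the cluster has no isotropic contacts with external beads
    # before or after the move, so the interaction energy is unchanged and
    # the proposal stays symmetric (the cluster composition is identical in
    # the reverse move).
    i0 = np.random.randint(N)
    for q in range(M):
        scratch_flag[q] = 0
    n_stack = 0
    c0 = chain_of[i0]
    scratch_flag[c0] = 1
    scratch_idx[n_stack] = c0
    n_stack += 1
    ptr = 0
    while ptr < n_stack:
        c = scratch_idx[ptr]
        ptr += 1
        s = chain_start[c]
        for b in range(s, s + chain_len[c]):
            p = bond[b]
            if p != -1 and scratch_flag[chain_of[p]] == 0:
                cc = chain_of[p]
                scratch_flag[cc] = 1
                scratch_idx[n_stack] = cc
                n_stack += 1
    k = np.random.randint(26)
    dx, dy, dz = NB26[k, 0], NB26[k, 1], NB26[k, 2]
    dV = 0.0
    for q in range(n_stack):
        c = scratch_idx[q]
        s = chain_start[c]
        for b in range(s, s + chain_len[c]):
            px, py, pz = pos[b, 0], pos[b, 1], pos[b, 2]
            nx = _wrap(px + dx, L)
            ny = _wrap(py + dy, L)
            nz = _wrap(pz + dz, L)
            tgt = occ[_site(nx, ny, nz, L)]
            if tgt != -1 and scratch_flag[chain_of[tgt]] == 0:
                return 0.0
            # external contacts before/after forbid the move
            for kk in range(26):
                x = _wrap(px + NB26[kk, 0], L)
                y = _wrap(py + NB26[kk, 1], L)
                z = _wrap(pz + NB26[kk, 2], L)
                j = occ[_site(x, y, z, L)]
                if j >= 0 and scratch_flag[chain_of[j]] == 0:
                    return 0.0
                x = _wrap(nx + NB26[kk, 0], L)
                y = _wrap(ny + NB26[kk, 1], L)
                z = _wrap(nz + NB26[kk, 2], L)
                j = occ[_site(x, y, z, L)]
                if j >= 0 and scratch_flag[chain_of[j]] == 0:
                    return 0.0
            dV += (_constraint(nx, ny, nz, L, cmode, T, T0, RB)
                   - _constraint(px, py, pz, L, cmode, T, T0, RB))
    acc_arg = -dV / T
    if acc_arg >= 0.0 or np.random.random() < np.exp(acc_arg):
        for q in range(n_stack):
            c = scratch_idx[q]
            s = chain_start[c]
            for b in range(s, s + chain_len[c]):
                occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = -1
        for q in range(n_stack):
            c = scratch_idx[q]
            s = chain_start[c]
            for b in range(s, s + chain_len[c]):
                pos[b, 0] = _wrap(pos[b, 0] + dx, L)
                pos[b, 1] = _wrap(pos[b, 1] + dy, L)
                pos[b, 2] = _wrap(pos[b, 2] + dz, L)
                occ[_site(pos[b, 0], pos[b, 1], pos[b, 2], L)] = b
    return 0.0


@njit(cache=True)
def run_steps(pos, typ, chain_of, chain_start, chain_len, bond, occ, L,
              aniso, iso, cum_w, aniso_on, cmode, RB,
              T_fixed, anneal_on, T0, TEQ, tEQ, t_clamp,
              t_begin, n_steps, E_int):
    """Advance n_steps move attempts starting at phase step t_begin.

    During annealing (anneal_on) the temperature follows
    T0 + TEQ*exp(-4 t / tEQ) until t_clamp, after which T = T0 and the
    constraint is off.  Returns the updated running interaction energy.
    """
    scratch_idx = np.empty(chain_start.shape[0], dtype=np.int64)
    scratch_flag = np.zeros(chain_start.shape[0], dtype=np.int64)
    for step in range(n_steps):
        t = t_begin + step
        if anneal_on:
            if t >= t_clamp:
                T = T0
                cm = C_OFF
            else:
                T = T0 + TEQ * np.exp(-4.0 * t / tEQ)
                cm = cmode
        else:
            T = T_fixed
            cm = cmode
        E_int += _attempt(pos, typ, chain_of, chain_start, chain_len, bond,
                          occ, L, aniso, iso, cum_w, aniso_on, cm, T, T0, RB,
                          scratch_idx, scratch_flag)
    return E_int


@njit(cache=True)
def interaction_energy(pos, typ, bond, occ, L, aniso, iso):
    """From-scratch anisotropic + isotropic interaction energy."""
    N = pos.shape[0]
    e = 0.0
    for i in range(N):
        if bond[i] > i:
            e += aniso[typ[i], typ[bond[i]]]
        e += 0.5 * _iso_at(pos, typ, occ, L, iso, typ[i],
                           pos[i, 0], pos[i, 1], pos[i, 2], i, -1)
    return e


@njit(cache=True)
def constraint_energy(pos, L, cmode, T, T0, RB):
    e = 0.0
    for i in range(pos.shape[0]):
        e += _constraint(pos[i, 0], pos[i, 1], pos[i, 2], L, cmode, T, T0, RB)
    return e
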