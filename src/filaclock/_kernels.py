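"""Numba kernels for exact stochastic simulation (Gillespie direct method).

Counts are (n_T, n_D, n_S) with n_U = N_tot - n_T - n_D - n_S.  Transition
order and stoichiometry mirror :mod:`filaclock.params`.  Each kernel seeds
numba's own RNG, so a fixed seed gives a bit-reproducible trajectory.
"""

import numpy as np
from numba import njit

# form ids for the KaiA activity function
FORM_SOFTPLUS, FORM_LOGISTIC, FORM_SHARP = 0, 1, 2

# stoichiometry on (T, D, S) and source-species index in (U, T, D, S) order,
# duplicated here as plain arrays for numba
_STOICH = np.array([
    [1, 0, 0], [-1, 0, 0], [-1, 1, 0], [1, -1, 0],
    [0, -1, 1], [0, 1, -1], [0, 0, -1], [0, 0, 1]], dtype=np.int64)
_SOURCE = np.array([0, 1, 1, 2, 2, 3, 3, 0], dtype=np.int64)


@njit(cache=True)
def _activity(phi_S, gamma, kaiA, form):
    if kaiA <= 0.0:
        return 0.0
    if form == FORM_SHARP:
        a = kaiA - 2.0 * phi_S
        return a if a > 0.0 else 0.0
    x = gamma * (kaiA - 2.0 * phi_S) / kaiA
    if form == FORM_SOFTPLUS:
        if x > 35.0:
            return (kaiA / gamma) * x
        return (kaiA / gamma) * np.log1p(np.exp(x))
    # logistic
    if x < -500.0:
        return 0.0
    return kaiA / (1.0 + np.exp(-x))


@njit(cache=True)
def _propensities(counts, N_tot, k0, kA, K_half, C_tot, gamma, kaiA, form, out):
    """Fill out[0:8] with reaction propensities (hr^-1); return their sum."""
    nT, nD, nS = counts[0], counts[1], counts[2]
    nU = N_tot - nT - nD - nS
    phi_S = nS * C_tot / N_tot
    A = _activity(phi_S, gamma, kaiA, form)
    f = A / (K_half + A)
    total = 0.0
    ns = (nU, nT, nD, nS)
    for r in range(8):
        k = k0[r] + kA[r] * f
        if k < 0.0:
            k = 0.0
        a = k * ns[_SOURCE[r]]
        out[r] = a
        total += a
    return total


@njit(cache=True)
def ssa_single(k0, kA, K_half, C_tot, gamma, kaiA, form, counts0, N_tot,
               grid, max_steps, seed):
    """Direct-method SSA for one clock, recorded on a uniform grid (ZOH).

    Returns (rec_counts (nt,3), n_events, absorbed, t_final).
    """
    np.random.seed(seed)
    nt = grid.shape[0]
    rec = np.zeros((nt, 3), dtype=np.int64)
    counts = counts0.copy()
    props = np.zeros(8)
    t = 0.0
    ptr = 0
    absorbed = False
    n_events = 0
    t_end = grid[nt - 1]
    for _ in range(max_steps):
        a0 = _propensities(counts, N_tot, k0, kA, K_half, C_tot, gamma, kaiA,
                           form, props)
        if a0 <= 0.0:
            absorbed = True
            break
        dt = -np.log(np.random.random()) / a0
        t_next = t + dt
        while ptr < nt and grid[ptr] < t_next:
            rec[ptr, 0] = counts[0]
            rec[ptr, 1] = counts[1]
            rec[ptr, 2] = counts[2]
            ptr += 1
        if t_next > t_end and ptr >= nt:
            t = t_next
            break
        t = t_next
        u = np.random.random() * a0
        c = 0.0
        r = 7
        for j in range(8):
            c += props[j]
            if u < c:
                r = j
                break
        counts[0] += _STOICH[r, 0]
        counts[1] += _STOICH[r, 1]
        counts[2] += _STOICH[r, 2]
        n_events += 1
    while ptr < nt:
        rec[ptr, 0] = counts[0]
        rec[ptr, 1] = counts[1]
        rec[ptr, 2] = counts[2]
        ptr += 1
    return rec, n_events, absorbed, t


@njit(cache=True)
def ssa_single_events(k0, kA, K_half, C_tot, gamma, kaiA, form, counts0, N_tot,
                      n_events, seed):
    """Event-resolved SSA (for exactness tests); returns (times, counts per event)."""
    np.random.seed(seed)
    times = np.zeros(n_events)
    states = np.zeros((n_events, 3), dtype=np.int64)
    counts = counts0.copy()
    props = np.zeros(8)
    t = 0.0
    for i in range(n_events):
        a0 = _propensities(counts, N_tot, k0, kA, K_half, C_tot, gamma, kaiA,
                           form, props)
        if a0 <= 0.0:
            return times[:i], states[:i]
        t += -np.log(np.random.random()) / a0
        u = np.random.random() * a0
        c = 0.0
        r = 7
        for j in range(8):
            c += props[j]
            if u < c:
                r = j
                break
        counts[0] += _STOICH[r, 0]
        counts[1] += _STOICH[r, 1]
        counts[2] += _STOICH[r, 2]
        times[i] = t
        states[i, 0] = counts[0]
        states[i, 1] = counts[1]
        states[i, 2] = counts[2]
    return times, states


@njit(cache=True)
def ssa_array(k0, kA, K_half, C_tot, gamma, kaiA, form, counts0, N_tot,
              eps, W, grid, max_steps, seed):
    """Direct-method SSA for a 1-D array of clocks with input coupling.

    Cell i's rates are evaluated at A(s_tilde_i) with
    s_tilde_i = (1-eps)*phi_S_i + eps * sum_j W[i,j] * phi_S_j  (W row-normalized,
    zero diagonal).  Recorded on a uniform grid (ZOH).

    Returns (rec (n_cells, nt, 3), n_events, absorbed, t_final).
    """
    np.random.seed(seed)
    n_cells = counts0.shape[0]
    nt = grid.shape[0]
    rec = np.zeros((n_cells, nt, 3), dtype=np.int64)
    counts = counts0.copy()
    conv = C_tot / N_tot

    phi_S = np.zeros(n_cells)
    for i in range(n_cells):
        phi_S[i] = counts[i, 2] * conv
    s_tilde = np.zeros(n_cells)
    for i in range(n_cells):
        acc = 0.0
        for j in range(n_cells):
            acc += W[i, j] * phi_S[j]
        s_tilde[i] = (1.0 - eps) * phi_S[i] + eps * acc

    # neighbour lists: cells whose s_tilde depends on cell i (W[:, i] > 0)
    nbr_count = np.zeros(n_cells, dtype=np.int64)
    for i in range(n_cells):
        c = 0
        for j in range(n_cells):
            if W[j, i] > 0.0:
                c += 1
        nbr_count[i] = c
    max_nbr = 0
    for i in range(n_cells):
        if nbr_count[i] > max_nbr:
            max_nbr = nbr_count[i]
    nbrs = np.zeros((n_cells, max_nbr), dtype=np.int64)
    for i in range(n_cells):
        c = 0
        for j in range(n_cells):
            if W[j, i] > 0.0:
                nbrs[i, c] = j
                c += 1

    props = np.zeros((n_cells, 8))
    cell_sum = np.zeros(n_cells)
    total = 0.0

    def_src = _SOURCE
    for i in range(n_cells):
        A = _activity(s_tilde[i], gamma, kaiA, form)
        f = A / (K_half + A)
        s = 0.0
        nU = N_tot - counts[i, 0] - counts[i, 1] - counts[i, 2]
        ns = (nU, counts[i, 0], counts[i, 1], counts[i, 2])
        for r in range(8):
            k = k0[r] + kA[r] * f
            if k < 0.0:
                k = 0.0
            a = k * ns[def_src[r]]
            props[i, r] = a
            s += a
        cell_sum[i] = s
        total += s

    t = 0.0
    ptr = 0
    absorbed = False
    n_events = 0
    t_end = grid[nt - 1]

    for _ in range(max_steps):
        if total <= 1e-300:
            absorbed = True
            break
        dt = -np.log(np.random.random()) / total
        t_next = t + dt
        while ptr < nt and grid[ptr] < t_next:
            for i in range(n_cells):
                rec[i, ptr, 0] = counts[i, 0]
                rec[i, ptr, 1] = counts[i, 1]
                rec[i, ptr, 2] = counts[i, 2]
            ptr += 1
        if t_next > t_end and ptr >= nt:
            t = t_next
            break
        t = t_next
        # choose cell, then reaction
        u = np.random.random() * total
        c = 0.0
        ci = n_cells - 1
        for i in range(n_cells):
            c += cell_sum[i]
            if u < c:
                ci = i
                break
        u2 = np.random.random() * cell_sum[ci]
        c2 = 0.0
        r = 7
        for j in range(8):
            c2 += props[ci, j]
            if u2 < c2:
                r = j
                break
        counts[ci, 0] += _STOICH[r, 0]
        counts[ci, 1] += _STOICH[r, 1]
        counts[ci, 2] += _STOICH[r, 2]
        n_events += 1

        dS = _STOICH[r, 2]
        if dS != 0:
            dphi = dS * conv
            phi_S[ci] += dphi
            s_tilde[ci] += (1.0 - eps) * dphi
            for m in range(nbr_count[ci]):
                j = nbrs[ci, m]
                s_tilde[j] += eps * W[j, ci] * dphi
            # rates of the affected cells changed: ci plus its out-neighbours
            for m in range(-1, nbr_count[ci]):
                j = ci if m < 0 else nbrs[ci, m]
                if m >= 0 and j == ci:
                    continue
                A = _activity(s_tilde[j], gamma, kaiA, form)
                f = A / (K_half + A)
                s = 0.0
                nU = N_tot - counts[j, 0] - counts[j, 1] - counts[j, 2]
                ns = (nU, counts[j, 0], counts[j, 1], counts[j, 2])
                for rr in range(8):
                    k = k0[rr] + kA[rr] * f
                    if k < 0.0:
                        k = 0.0
                    a = k * ns[def_src[rr]]
                    props[j, rr] = a
                    s += a
                total += s - cell_sum[j]
                cell_sum[j] = s
        else:
            # only cell ci's copy numbers changed; its activity is unchanged
            A = _activity(s_tilde[ci], gamma, kaiA, form)
            f = A / (K_half + A)
            s = 0.0
            nU = N_tot - counts[ci, 0] - counts[ci, 1] - counts[ci, 2]
            ns = (nU, counts[ci, 0], counts[ci, 1], counts[ci, 2])
            for rr in range(8):
                k = k0[rr] + kA[rr] * f
                if k < 0.0:
                    k = 0.0
                a = k * ns[def_src[rr]]
                props[ci, rr] = a
                s += a
            total += s - cell_sum[ci]
            cell_sum[ci] = s
        # periodic exact refresh of the running total to control FP drift
        if n_events % 1048576 == 0:
            total = 0.0
            for i in range(n_cells):
                total += cell_sum[i]

    while ptr < nt:
        for i in range(n_cells):
            rec[i, ptr, 0] = counts[i, 0]
            rec[i, ptr, 1] = counts[i, 1]
            rec[i, ptr, 2] = counts[i, 2]
        ptr += 1
    return rec, n_events, absorbed, t
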