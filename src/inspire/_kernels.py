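"""Numba kernels for the augmented max-KD-tree build and pruned search.

These mirror, with explicit stacks instead of recursion, the pure-Python
reference implementations in :mod:`inspire.fuzzy`; the test-suite asserts
that both paths return identical results.  Node layout: implicit binary
tree in a flat array, root at index 1, children of ``i`` at ``2i``/``2i+1``;
each node stores the maximum membership of its sub-rectangle.
"""

import numpy as np
from numba import njit

_STACK = 512  # > 2 * (1 + sum ceil(log2 N_k)) for any realistic image


@njit(cache=True)
def _split_axis(R, s):
    """argmax_k s_k (R_k - 1); ties broken by the lowest dimension index."""
    best = 0
    bv = s[0] * (R[0] - 1)
    for k in range(1, R.shape[0]):
        v = s[k] * (R[k] - 1)
        if v > bv:
            bv = v
            best = k
    return best


@njit(cache=True)
def build_tree(mem, N, s, tree):
    """Fill `tree` (flat, 1-rooted) with sub-rectangle membership maxima."""
    n = N.shape[0]
    strides = np.empty(n, np.int64)
    strides[n - 1] = 1
    for k in range(n - 2, -1, -1):
        strides[k] = strides[k + 1] * N[k + 1]
    st_i = np.empty(_STACK, np.int64)
    st_y = np.empty((_STACK, n), np.int64)
    st_R = np.empty((_STACK, n), np.int64)
    st_state = np.empty(_STACK, np.int8)
    top = 0
    st_i[top] = 1
    for k in range(n):
        st_y[top, k] = 0
        st_R[top, k] = N[k]
    st_state[top] = 0
    top = 1
    while top > 0:
        top -= 1
        i = st_i[top]
        state = st_state[top]
        if state == 1:
            tree[i] = max(tree[2 * i], tree[2 * i + 1])
            continue
        size = 1
        for k in range(n):
            size *= st_R[top, k]
        if size == 1:
            flat = 0
            for k in range(n):
                flat += st_y[top, k] * strides[k]
            tree[i] = mem[flat]
            continue
        k = _split_axis(st_R[top], s)
        half = (st_R[top, k] + 1) // 2
        # re-push this node for the post-order max, then both children
        y0 = st_y[top].copy()
        R0 = st_R[top].copy()
        st_i[top] = i
        st_state[top] = 1
        top += 1
        st_i[top] = 2 * i
        for j in range(n):
            st_y[top, j] = y0[j]
            st_R[top, j] = R0[j]
        st_R[top, k] = half
        st_state[top] = 0
        top += 1
        st_i[top] = 2 * i + 1
        for j in range(n):
            st_y[top, j] = y0[j]
            st_R[top, j] = R0[j]
        st_y[top, k] = y0[k] + half
        st_R[top, k] = R0[k] - half
        st_state[top] = 0
        top += 1


@njit(cache=True)
def search_joint(tree, N, s, corners, alphas, D, d_t, beta):
    """Joint pruned nearest-spel search for several alpha-cuts at once.

    corners : (C, n) int64 grid indices of the query points.
    alphas  : (L,) cut levels.
    D       : (L, C) current best distances, updated in place.
    Pruning uses the relaxed lower bound with threshold `d_t` and factor
    `beta` (beta = 1 gives the exact bound).
    """
    n = N.shape[0]
    C = corners.shape[0]
    L = alphas.shape[0]
    if L == 0:
        return
    st_y = np.empty((_STACK, n), np.int64)
    st_R = np.empty((_STACK, n), np.int64)
    st_i = np.empty(_STACK, np.int64)
    bounds = np.empty(C, np.float64)
    top = 0
    st_i[top] = 1
    for k in range(n):
        st_y[top, k] = 0
        st_R[top, k] = N[k]
    top = 1
    while top > 0:
        top -= 1
        i = st_i[top]
        tau = tree[i]
        y = st_y[top].copy()  # copy: the slot is reused when pushing children
        R = st_R[top].copy()
        # relaxed lower bound per corner (Euclidean, physical units)
        for j in range(C):
            acc = 0.0
            for k in range(n):
                p = corners[j, k] * s[k]
                lo = y[k] * s[k]
                hi = (y[k] + R[k] - 1) * s[k]
                d = lo - p
                if p - hi > d:
                    d = p - hi
                if d > 0.0:
                    acc += d * d
            b = np.sqrt(acc)
            if b > d_t:
                b = d_t + beta * (b - d_t)
            bounds[j] = b
        prune = True
        for l in range(L):
            if alphas[l] <= tau:
                for j in range(C):
                    if D[l, j] > bounds[j]:
                        prune = False
                        break
                if not prune:
                    break
        if prune:
            continue
        size = 1
        for k in range(n):
            size *= R[k]
        if size == 1:
            for j in range(C):
                acc = 0.0
                for k in range(n):
                    dd = (corners[j, k] - y[k]) * s[k]
                    acc += dd * dd
                dj = np.sqrt(acc)
                for l in range(L):
                    if alphas[l] <= tau and dj < D[l, j]:
                        D[l, j] = dj
            continue
        k = _split_axis(R, s)
        half = (R[k] + 1) // 2
        yk = y[k]
        # left child rectangle: [yk, half), right: [yk + half, ...)
        near_left = corners[0, k] * s[k] <= (yk + half) * s[k]
        # push far child first (LIFO -> near child searched first)
        for child in range(2):
            first = child == 0
            take_left = (first and not near_left) or ((not first) and near_left)
            if take_left:
                st_i[top] = 2 * i
                for m in range(n):
                    st_y[top, m] = y[m]
                    st_R[top, m] = R[m]
                st_R[top, k] = half
            else:
                st_i[top] = 2 * i + 1
                for m in range(n):
                    st_y[top, m] = y[m]
                    st_R[top, m] = R[m]
                st_y[top, k] = yk + half
                st_R[top, k] = R[k] - half
            top += 1


@njit(cache=True)
def mc_corner_tables(tree_s, tree_c, N, s, base, heights, alphas, d_max, d_t, beta, out):
    """Average per-corner alpha-cut distances for a batch of fuzzy points.

    base    : (P, n) minimal-corner grid index of each point's cell.
    heights : (P,) fuzzy-point heights h(p).
    alphas  : (L,) sampled cut levels in (0, 1), shared across points.
    out     : (P, C) filled with the per-corner mean of d'(p, S; alpha).

    For alpha <= h the object tree is searched at level alpha; otherwise the
    complement tree is searched at level 1 - alpha.  Distances start at
    d_max, so empty cuts and far spels saturate there.
    """
    P = base.shape[0]
    n = N.shape[0]
    C = 1 << n
    L = alphas.shape[0]
    corners = np.empty((C, n), np.int64)
    a_obj = np.empty(L, np.float64)
    a_cmp = np.empty(L, np.float64)
    D_obj = np.empty((L, C), np.float64)
    D_cmp = np.empty((L, C), np.float64)
    for p in range(P):
        h = heights[p]
        for j in range(C):
            for k in range(n):
                corners[j, k] = base[p, k] + ((j >> k) & 1)
        n_obj = 0
        n_cmp = 0
        for l in range(L):
            if alphas[l] <= h:
                a_obj[n_obj] = alphas[l]
                n_obj += 1
            else:
                a_cmp[n_cmp] = 1.0 - alphas[l]
                n_cmp += 1
        for l in range(n_obj):
            for j in range(C):
                D_obj[l, j] = d_max
        for l in range(n_cmp):
            for j in range(C):
                D_cmp[l, j] = d_max
        if n_obj > 0:
            search_joint(tree_s, N, s, corners, a_obj[:n_obj], D_obj[:n_obj], d_t, beta)
        if n_cmp > 0:
            search_joint(tree_c, N, s, corners, a_cmp[:n_cmp], D_cmp[:n_cmp], d_t, beta)
        for j in range(C):
            acc = 0.0
            for l in range(n_obj):
                acc += D_obj[l, j]
            for l in range(n_cmp):
                acc += D_cmp[l, j]
            out[p, j] = acc / L
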