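"""Brute-force dip oracle: direct sup-norm optimization over unimodal CDFs.

Independent of the package's incremental-hull implementation: for every
candidate mode position (each open slot between consecutive order
statistics, and each tied value with a mode atom) it solves a small linear
program for the minimal half-bandwidth d such that a convex-increasing /
concave-increasing piecewise-linear CDF fits the ECDF bands, and returns
the minimum over modes.  Only suitable for small n (LP per mode).
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(c, A_ub, b_ub, A_eq=None, b_eq=None, bounds=None):
    res = linprog(c, A_ub=A_ub or None, b_ub=b_ub or None,
                  A_eq=A_eq or None, b_eq=b_eq or None,
                  bounds=bounds, method="highs")
    return res.fun if res.status == 0 else np.inf


def _slot_lp(xs, k, gap_variant=None):
    """Mode strictly between xs[k-1] and xs[k] (k = 0..n slots).

    Variables: g_1..g_n, d.  Minimize d subject to band, monotonicity and
    convex-left / concave-right slope chains.  The modal slot itself must be
    traversed with the left chain's final slope or the right chain's initial
    slope (whichever is smaller), i.e. g_k - g_{k-1} >= min(s_L, s_R) * w;
    ``gap_variant`` selects the "L" or "R" branch of that disjunction
    (None = no slope has to be continued across the slot).
    """
    n = len(xs)
    idx_d = n
    A_ub, b_ub, A_eq, b_eq = [], [], [], []

    def row():
        return [0.0] * (n + 1)

    for i in range(n):
        r = row()          # g_i <= (i)/n + d - 1/n  ->  g_i - d <= (i)/n - 1/n
        r[i] = 1.0
        r[idx_d] = -1.0
        A_ub.append(r)
        b_ub.append(i / n)
        r = row()          # g_i >= (i+1)/n - d
        r[i] = -1.0
        r[idx_d] = -1.0
        A_ub.append(r)
        b_ub.append(-(i + 1) / n)
    # monotone
    for i in range(n - 1):
        r = row()
        r[i] = 1.0
        r[i + 1] = -1.0
        A_ub.append(r)
        b_ub.append(0.0)
        if xs[i + 1] == xs[i]:   # coincident points share one G value
            r = row()
            r[i] = 1.0
            r[i + 1] = -1.0
            A_eq.append(r)
            b_eq.append(0.0)
    # convex side: slopes nondecreasing over g_0..g_{k-1}
    for i in range(k - 2):
        dx1 = xs[i + 1] - xs[i]
        dx2 = xs[i + 2] - xs[i + 1]
        # (g_{i+1}-g_i)*dx2 <= (g_{i+2}-g_{i+1})*dx1
        r = row()
        r[i] = -dx2
        r[i + 1] = dx2 + dx1
        r[i + 2] = -dx1
        A_ub.append(r)
        b_ub.append(0.0)
    # concave side: slopes nonincreasing over g_k..g_{n-1}
    for i in range(k, n - 2):
        dx1 = xs[i + 1] - xs[i]
        dx2 = xs[i + 2] - xs[i + 1]
        r = row()
        r[i] = dx2
        r[i + 1] = -(dx2 + dx1)
        r[i + 2] = dx1
        A_ub.append(r)
        b_ub.append(0.0)
    # modal-slot traversal constraint (see docstring)
    if gap_variant == "L":
        # (g_k - g_{k-1}) * dx_L >= (g_{k-1} - g_{k-2}) * w
        w = xs[k] - xs[k - 1]
        dxl = xs[k - 1] - xs[k - 2]
        r = row()
        r[k - 2] += -w
        r[k - 1] += w + dxl
        r[k] += -dxl
        A_ub.append(r)
        b_ub.append(0.0)
    elif gap_variant == "R":
        # (g_k - g_{k-1}) * dx_R >= (g_{k+1} - g_k) * w
        w = xs[k] - xs[k - 1]
        dxr = xs[k + 1] - xs[k]
        r = row()
        r[k - 1] += dxr
        r[k] += -(dxr + w)
        r[k + 1] += w
        A_ub.append(r)
        b_ub.append(0.0)
    c = row()
    c[idx_d] = 1.0
    bounds = [(0.0, 1.0)] * n + [(0.0, 0.5)]
    return _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)


def _slot_best(xs, k):
    n = len(xs)
    if k == 0 or k == n:      # mode outside the data: one-sided fit only
        return _slot_lp(xs, k, None)
    cands = [
        _slot_lp(xs, k, "L") if k >= 2 else _slot_lp(xs, k, None),
        _slot_lp(xs, k, "R") if k <= n - 2 else _slot_lp(xs, k, None),
    ]
    return min(cands)


def _atom_lp(xs, f, l):
    """Mode atom at the tied value xs[f..l]: those points are absorbed by a
    jump; the sides must still extend feasibly to the jump endpoints."""
    n = len(xs)
    # variables: g_0..g_{n-1}, a (left limit), b (value), d
    na, nb, nd = n, n + 1, n + 2
    A_ub, b_ub, A_eq, b_eq = [], [], [], []

    def row():
        return [0.0] * (n + 3)

    left = list(range(0, f))
    right = list(range(l + 1, n))
    for i in left + right:
        r = row()
        r[i] = 1.0
        r[nd] = -1.0
        A_ub.append(r)
        b_ub.append(i / n)
        r = row()
        r[i] = -1.0
        r[nd] = -1.0
        A_ub.append(r)
        b_ub.append(-(i + 1) / n)
    for seq in (left, right):
        for i, j in zip(seq, seq[1:]):
            r = row()
            r[i] = 1.0
            r[j] = -1.0
            A_ub.append(r)
            b_ub.append(0.0)
            if xs[j] == xs[i]:
                r = row()
                r[i] = 1.0
                r[j] = -1.0
                A_eq.append(r)
                b_eq.append(0.0)
    # a within d of F just left of the atom; b within d of F at the atom
    r = row()
    r[na] = 1.0
    r[nd] = -1.0
    A_ub.append(r)
    b_ub.append(f / n)
    r = row()
    r[nb] = -1.0
    r[nd] = -1.0
    A_ub.append(r)
    b_ub.append(-(l + 1) / n)
    r = row()
    r[na] = 1.0
    r[nb] = -1.0
    A_ub.append(r)
    b_ub.append(0.0)
    # convex chain on left side extended to the endpoint a at x = xs[f]
    lseq = left + ["a"]
    lx = [xs[i] for i in left] + [xs[f]]
    lvar = left + [na]
    for t in range(len(lseq) - 2):
        dx1 = lx[t + 1] - lx[t]
        dx2 = lx[t + 2] - lx[t + 1]
        r = row()
        r[lvar[t]] += -dx2
        r[lvar[t + 1]] += dx2 + dx1
        r[lvar[t + 2]] += -dx1
        A_ub.append(r)
        b_ub.append(0.0)
    if left:
        r = row()   # a >= g_{f-1}
        r[left[-1]] = 1.0
        r[na] = -1.0
        A_ub.append(r)
        b_ub.append(0.0)
    # concave chain on right side starting from b at x = xs[l]
    rx = [xs[l]] + [xs[i] for i in right]
    rvar = [nb] + right
    for t in range(len(rx) - 2):
        dx1 = rx[t + 1] - rx[t]
        dx2 = rx[t + 2] - rx[t + 1]
        r = row()
        r[rvar[t]] += dx2
        r[rvar[t + 1]] += -(dx2 + dx1)
        r[rvar[t + 2]] += dx1
        A_ub.append(r)
        b_ub.append(0.0)
    if right:
        r = row()   # b <= g_{l+1}
        r[nb] = 1.0
        r[right[0]] = -1.0
        A_ub.append(r)
        b_ub.append(0.0)
    c = row()
    c[nd] = 1.0
    bounds = [(0.0, 1.0)] * (n + 2) + [(0.0, 0.5)]
    return _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)


def dip_oracle(x) -> float:
    """Dip by explicit minimization over modes (small n only)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    if n < 2 or xs[0] == xs[-1]:
        return 0.0
    best = np.inf
    for k in range(n + 1):
        best = min(best, _slot_best(xs, k))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        best = min(best, _atom_lp(xs, i, j))
        i = j + 1
    return float(best)
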