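"""Dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF.  Computed by the classical iterative scheme
(AS 217): maintain a candidate modal interval [low, high]; fit the greatest
convex minorant (GCM) and least concave majorant (LCM) of the ECDF on it;
the largest GCM-LCM discrepancy either certifies the current dip or
shrinks the modal interval, accumulating the deviations of the ECDF from
the one-sided fits outside the new interval.  All deviations are kept in
jump-count units and divided by 2n at the end.

The hot loop is JIT-compiled when numba is importable and falls back to
pure Python otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_from_sorted"]


def _dip_core(x):
    """x: sorted sample padded with a dummy at index 0 (1-based indexing)."""
    n = x.shape[0] - 1
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    # pointer chains of the convex minorant / concave majorant touch points
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or ((x[j] - x[mnj]) * (mnj - mnmnj)
                            < (x[mnj] - x[mnmnj]) * (j - mnj)):
                break
            mn[j] = mnmnj
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or ((x[k] - x[mjk]) * (mjk - mjmjk)
                            < (x[mjk] - x[mjmjk]) * (k - mjk)):
                break
            mj[k] = mjmjk

    low = 1
    high = n
    dip = 1.0      # count units; final dip = dip / (2n)

    while True:
        # GCM change points from high down to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = i
        ix = ig - 1
        # LCM change points from low up to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = i
        iv = 2

        # largest distance between GCM and LCM on [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = ((lcmiv - gcmi1 + 1)
                          - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1)
                          / (x[gcmix] - x[gcmi1]))
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = ((x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1)
                          / (x[lcmiv] - x[lcmiv1])
                          - (gcmix - 1 - lcmiv1))
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # deviation of the ECDF above the GCM between the old and new low
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # deviation of the ECDF below the LCM between the new and old high
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (je - jj + 1) - (x[je] - x[jj]) * C
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_u if dip_l < dip_u else dip_l
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _dip_core = njit(cache=True, fastmath=False)(_dip_core)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def dip_from_sorted(xs: np.ndarray) -> float:
    """Dip of an already-sorted 1D sample."""
    xs = np.ascontiguousarray(xs, dtype=np.float64)
    n = len(xs)
    if n < 2:
        return 0.0
    if xs[0] == xs[-1]:
        return 0.0
    padded = np.empty(n + 1)
    padded[0] = np.nan
    padded[1:] = xs
    return float(_dip_core(padded))


def dip_statistic(x) -> float:
    """Dip statistic of a 1D sample.

    For a sample with >= 2 distinct values the dip lies in [1/(2n), 1/4];
    a sample of identical values has dip 0.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("dip requires at least 2 observations")
    if not np.isfinite(x).all():
        raise ValueError("dip requires finite values")
    return dip_from_sorted(np.sort(x))
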