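"""Hartigan & Hartigan dip statistic of unimodality.

Computes the maximum difference, over all sample points, between the
empirical CDF and the unimodal CDF closest to it in sup-norm, following the
greatest-convex-minorant / least-concave-majorant algorithm of Hartigan &
Hartigan (1985) as corrected in the widely used C implementation.  The
result lies in [1/(2n), 0.25] and is invariant to increasing affine
transformations of the sample.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(samples, allow_zero: bool = True) -> float:
    """Dip statistic of a one-dimensional sample (n >= 4 finite values).

    With ``allow_zero`` (the modern convention) a perfectly linear empirical
    CDF has dip 0; otherwise the historical floor 1/(2n) applies.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 4:
        raise ValueError(f"dip statistic needs at least 4 samples, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if x[0] == x[-1]:
        return 0.0
    return _dip(x, n, allow_zero)


def _dip(x: np.ndarray, n: int, allow_zero: bool) -> float:
    # 1-indexed working copies to mirror the reference algorithm
    xx = np.empty(n + 1)
    xx[1:] = x
    mn = np.zeros(n + 1, dtype=np.intp)
    mj = np.zeros(n + 1, dtype=np.intp)
    gcm = np.zeros(n + 2, dtype=np.intp)
    lcm = np.zeros(n + 2, dtype=np.intp)

    low, high = 1, n
    dip = 0.0 if allow_zero else 1.0  # count units; divided by 2n at the end

    while True:
        # greatest convex minorant of the ECDF on [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                mnmnj = mn[mnj]
                if mnj == low or (
                    (xx[j] - xx[mnj]) * (mnj - mnmnj)
                    < (xx[mnj] - xx[mnmnj]) * (j - mnj)
                ):
                    break
                mn[j] = mnmnj
        ic = 1
        gcm[1] = high
        while gcm[ic] > low:
            gcm[ic + 1] = mn[gcm[ic]]
            ic += 1
        l_gcm = ic
        ig = ic

        # least concave majorant on [low, high]
        mj[high] = high
        for j in range(high - 1, low - 1, -1):
            mj[j] = j + 1
            while True:
                mjj = mj[j]
                mjmjj = mj[mjj]
                if mjj == high or (
                    (xx[j] - xx[mjj]) * (mjj - mjmjj)
                    < (xx[mjj] - xx[mjmjj]) * (j - mjj)
                ):
                    break
                mj[j] = mjmjj
        ic = 1
        lcm[1] = low
        while lcm[ic] < high:
            lcm[ic + 1] = mj[lcm[ic]]
            ic += 1
        l_lcm = ic
        ih = ic

        # largest separation between the two fitted curves
        if l_gcm != 2 or l_lcm != 2:
            ix = l_gcm - 1
            iv = 2
            d = 0.0
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    gcm1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm1 + 1) - (xx[lcm_iv] - xx[gcm1]) * (
                        gcm_ix - gcm1
                    ) / (xx[gcm_ix] - xx[gcm1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcm1 = lcm[iv - 1]
                    dx = (xx[gcm_ix] - xx[lcm1]) * (lcm_iv - lcm1) / (
                        xx[lcm_iv] - xx[lcm1]
                    ) - (gcm_ix - lcm1 - 1)
                    ix -= 1
                    if dx > d:
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
            d = 0.0 if allow_zero else 1.0

        if d < dip:
            break

        # largest ECDF deviation below the GCM over [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb = gcm[j + 1]
            je = gcm[j]
            max_t = 1.0
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xx[jj] - xx[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # largest ECDF deviation above the LCM over [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb = lcm[j]
            je = lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and xx[je] != xx[jb]:
                c = (je - jb) / (xx[je] - xx[jb])
                for jj in range(jb, je + 1):
                    t = (xx[jj] - xx[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)
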