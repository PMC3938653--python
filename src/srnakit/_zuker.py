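"""Minimum-free-energy secondary structure DP (Zuker-style recursions).

Matrices:
  V[i,j]  -- best energy given (i,j) paired
  WM[i,j] -- best energy of a multiloop segment with >= 1 branch
  W[j]    -- best exterior energy over prefix [0, j]

The kernel is compiled with numba for the O(n^3) fill; traceback is plain
Python and re-derives decisions with a small tolerance, preferring the
5'-most pairing on ties.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._energy import INF, EnergyModel, default_model, encode

_EPS = 1e-7


@njit(cache=True)
def _fill(codes, pidx, stack, hairpin, bulge, internal,
          ml_init, ml_branch, ml_unpaired, max_internal, min_hairpin):
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            pi = pidx[codes[i], codes[j]]
            if pi >= 0 and d - 1 >= min_hairpin:
                best = hairpin[d - 1] if d - 1 < hairpin.shape[0] else INF
                # stack / bulge / internal loop to an inner pair (k, l)
                kmax = min(j - 1, i + max_internal + 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_internal - g1))
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k, l] >= INF:
                            continue
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            e = stack[pi, pidx[codes[k], codes[l]]]
                        elif g1 == 0 or g2 == 0:
                            e = bulge[g1 + g2]
                        else:
                            e = internal[g1 + g2]
                        if e + V[k, l] < best:
                            best = e + V[k, l]
                # multiloop closure: >= 2 branches inside
                m = INF
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        s = WM[i + 1, k] + WM[k + 1, j - 1]
                        if s < m:
                            m = s
                if ml_init + ml_branch + m < best:
                    best = ml_init + ml_branch + m
                V[i, j] = best
            # WM
            w = INF
            if V[i, j] < INF and V[i, j] + ml_branch < w:
                w = V[i, j] + ml_branch
            if WM[i + 1, j] < INF and WM[i + 1, j] + ml_unpaired < w:
                w = WM[i + 1, j] + ml_unpaired
            if WM[i, j - 1] < INF and WM[i, j - 1] + ml_unpaired < w:
                w = WM[i, j - 1] + ml_unpaired
            for k in range(i, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    s = WM[i, k] + WM[k + 1, j]
                    if s < w:
                        w = s
            WM[i, j] = w
    W = np.zeros(n)
    for j in range(n):
        W[j] = W[j - 1] if j > 0 else 0.0
        for i in range(j):
            if V[i, j] < INF:
                prev = W[i - 1] if i > 0 else 0.0
                if prev + V[i, j] < W[j]:
                    W[j] = prev + V[i, j]
    return V, WM, W


def _traceback(codes, V, WM, W, model: EnergyModel) -> list[tuple[int, int]]:
    pidx = model.pidx
    stack, bulge, internal = model.stack, model.bulge, model.internal
    hairpin = model.hairpin
    pairs: list[tuple[int, int]] = []

    def close(a, b):
        return abs(a - b) <= _EPS

    def trace_v(i, j):
        pairs.append((i, j))
        pi = pidx[codes[i], codes[j]]
        target = V[i, j]
        if j - i - 1 < hairpin.shape[0] and close(target, hairpin[j - i - 1]):
            return
        kmax = min(j - 1, i + model.max_internal + 1)
        for k in range(i + 1, kmax + 1):
            g1 = k - i - 1
            lmin = max(k + 1, j - 1 - (model.max_internal - g1))
            for l in range(j - 1, lmin - 1, -1):
                if V[k, l] >= INF:
                    continue
                g2 = j - l - 1
                e = model.loop_penalty(g1, g2, pi, pidx[codes[k], codes[l]])
                if e < INF and close(target, e + V[k, l]):
                    trace_v(k, l)
                    return
        for k in range(i + 1, j - 1):
            if (WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF and
                    close(target, model.ml_init + model.ml_branch
                          + WM[i + 1, k] + WM[k + 1, j - 1])):
                trace_wm(i + 1, k)
                trace_wm(k + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")

    def trace_wm(i, j):
        target = WM[i, j]
        if V[i, j] < INF and close(target, V[i, j] + model.ml_branch):
            trace_v(i, j)
            return
        if i + 1 <= j and WM[i + 1, j] < INF and close(target, WM[i + 1, j] + model.ml_unpaired):
            trace_wm(i + 1, j)
            return
        if i <= j - 1 and WM[i, j - 1] < INF and close(target, WM[i, j - 1] + model.ml_unpaired):
            trace_wm(i, j - 1)
            return
        for k in range(i, j):
            if (WM[i, k] < INF and WM[k + 1, j] < INF and
                    close(target, WM[i, k] + WM[k + 1, j])):
                trace_wm(i, k)
                trace_wm(k + 1, j)
                return
        raise AssertionError("traceback failed in WM")

    def trace_w(j):
        while j >= 0:
            target = W[j]
            if close(target, W[j - 1] if j > 0 else 0.0):
                j -= 1
                continue
            found = False
            for i in range(j):  # ascending: prefer the 5'-most pairing
                if V[i, j] >= INF:
                    continue
                prev = W[i - 1] if i > 0 else 0.0
                if close(target, prev + V[i, j]):
                    trace_v(i, j)
                    j = i - 1
                    found = True
                    break
            if not found:
                raise AssertionError("traceback failed in W")

    n = len(codes)
    if n:
        trace_w(n - 1)
    return sorted(pairs)


def mfe_fold(seq: str, model: EnergyModel | None = None):
    """Return (mfe, pairs) for the minimum-free-energy structure of ``seq``."""
    model = model or default_model()
    codes = encode(seq)
    n = len(codes)
    if n < 2:
        return 0.0, []
    V, WM, W = _fill(codes, model.pidx, model.stack, model.hairpin,
                     model.bulge, model.internal, model.ml_init,
                     model.ml_branch, model.ml_unpaired,
                     model.max_internal, model.min_hairpin)
    mfe = min(0.0, float(W[n - 1]))
    if mfe >= 0.0:
        return 0.0, []
    pairs = _traceback(codes, V, WM, W, model)
    return mfe, pairs


@njit(cache=True)
def _duplex_fill(ca, cb, pidx, stack, bulge, internal, init, cap):
    na, nb = ca.shape[0], cb.shape[0]
    dp = np.full((na, nb), INF)
    back_i = np.full((na, nb), -1, dtype=np.int64)
    back_j = np.full((na, nb), -1, dtype=np.int64)
    for i in range(na):
        for j in range(nb):
            pi = pidx[ca[i], cb[j]]
            if pi < 0:
                continue
            best = init
            bi = -1
            bj = -1
            for ii in range(max(0, i - cap - 1), i):
                g1 = i - ii - 1
                for jj in range(j + 1, min(nb, j + cap - g1 + 2)):
                    if dp[ii, jj] >= INF:
                        continue
                    g2 = jj - j - 1
                    if g1 == 0 and g2 == 0:
                        e = stack[pidx[ca[ii], cb[jj]], pi]
                    elif g1 == 0 or g2 == 0:
                        e = bulge[g1 + g2]
                    else:
                        e = internal[g1 + g2]
                    if dp[ii, jj] + e < best - 1e-12:
                        best = dp[ii, jj] + e
                        bi = ii
                        bj = jj
            dp[i, j] = best
            back_i[i, j] = bi
            back_j[i, j] = bj
    return dp, back_i, back_j
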