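"""Numba-compiled inner loops: the density-statistics sweep and JC69 pruning.

These mirror the readable implementations in :mod:`mscmig.density` and
:mod:`mscmig.likelihood`; the test suite asserts exact agreement between the
two routes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def stats_sweep(ev_time, ev_kind, ev_a, n0, schildren, src, dst, a0, a1,
                c, coal_exp, w, mig_exp):  # pragma: no cover - numba
    """Single backward-in-time sweep accumulating the MSC-M sufficient stats.

    Events are (time, kind, payload) sorted by time with divergences first
    on ties; kind 0 = coalescence (payload population), 1 = migration
    (payload entry index), 2 = species divergence (payload species node).
    Returns False if the event sequence is inconsistent with the model.
    """
    P = n0.shape[0]
    E = src.shape[0]
    n = n0.copy()
    total = 0
    for j in range(P):
        total += n[j]
    t_prev = 0.0
    for idx in range(ev_time.shape[0]):
        if total <= 1:
            break  # the process stops at the MRCA
        t = ev_time[idx]
        kind = ev_kind[idx]
        a = ev_a[idx]
        dt = t - t_prev
        if dt > 0.0:
            for j in range(P):
                if n[j] > 1:
                    coal_exp[j] += n[j] * (n[j] - 1) * dt
            for k in range(E):
                if a0[k] <= t_prev and t <= a1[k]:
                    mig_exp[k] += n[dst[k]] * dt
        if kind == 0:
            if n[a] < 2:
                return False
            c[a] += 1.0
            n[a] -= 1
            total -= 1
        elif kind == 1:
            j = dst[a]
            s = src[a]
            if n[j] < 1:
                return False
            if not (a0[a] <= t and t < a1[a]):
                return False
            w[a] += 1.0
            n[j] -= 1
            n[s] += 1
        else:
            c1 = schildren[a, 0]
            c2 = schildren[a, 1]
            n[a] += n[c1] + n[c2]
            n[c1] = 0
            n[c2] = 0
        t_prev = t
    return True


@njit(cache=True)
def jc_pruning(post, children, time, tipcodes, counts):  # pragma: no cover
    """Felsenstein pruning under JC69 over compressed site patterns.

    ``post``: internal nodes in postorder (root last); ``tipcodes``:
    (n_tips, n_patterns) nucleotide codes with 4 = missing; ``counts``:
    pattern multiplicities.  Per-node rescaling guards against underflow.
    """
    n_nodes = time.shape[0]
    n_tips = tipcodes.shape[0]
    npat = tipcodes.shape[1]
    part = np.empty((n_nodes, npat, 4))
    logscale = np.zeros(npat)
    for tip in range(n_tips):
        for p in range(npat):
            code = tipcodes[tip, p]
            if code < 4:
                for x in range(4):
                    part[tip, p, x] = 0.0
                part[tip, p, code] = 1.0
            else:
                for x in range(4):
                    part[tip, p, x] = 1.0
    for ii in range(post.shape[0]):
        nd = post[ii]
        for p in range(npat):
            for x in range(4):
                part[nd, p, x] = 1.0
        for side in range(2):
            ch = children[nd, side]
            t = time[nd] - time[ch]
            if t < 0.0:
                return np.nan
            e = np.exp(-4.0 * t / 3.0)
            psame = 0.25 + 0.75 * e
            pdiff = 0.25 - 0.25 * e
            for p in range(npat):
                s = (part[ch, p, 0] + part[ch, p, 1]
                     + part[ch, p, 2] + part[ch, p, 3])
                for x in range(4):
                    part[nd, p, x] *= (pdiff * s
                                       + (psame - pdiff) * part[ch, p, x])
        for p in range(npat):
            m = part[nd, p, 0]
            for x in range(1, 4):
                if part[nd, p, x] > m:
                    m = part[nd, p, x]
            if m <= 0.0:
                return -np.inf
            for x in range(4):
                part[nd, p, x] /= m
            logscale[p] += np.log(m)
    root = post[post.shape[0] - 1]
    total = 0.0
    for p in range(npat):
        lik = 0.25 * (part[root, p, 0] + part[root, p, 1]
                      + part[root, p, 2] + part[root, p, 3])
        total += counts[p] * (np.log(lik) + logscale[p])
    return total


@njit(cache=True)
def stats_merge_sweep(gt, gk, ga, div_t, div_a, n0, schildren, src, dst,
                      a0, a1, c, coal_exp, w, mig_exp):  # pragma: no cover
    """Sort the locus' gene events and sweep them merged with the (sorted)
    species divergences.  Same semantics as :func:`stats_sweep`; ties put
    divergences first.  Returns False on inconsistency."""
    ng = gt.shape[0]
    # insertion sort of the gene events (tiny arrays, nearly sorted)
    for i in range(1, ng):
        t = gt[i]
        k = gk[i]
        a = ga[i]
        j = i - 1
        while j >= 0 and gt[j] > t:
            gt[j + 1] = gt[j]
            gk[j + 1] = gk[j]
            ga[j + 1] = ga[j]
            j -= 1
        gt[j + 1] = t
        gk[j + 1] = k
        ga[j + 1] = a
    P = n0.shape[0]
    E = src.shape[0]
    n = n0.copy()
    total = 0
    for j in range(P):
        total += n[j]
    t_prev = 0.0
    gi = 0
    di = 0
    nd = div_t.shape[0]
    while (gi < ng or di < nd) and total > 1:
        if di < nd and (gi >= ng or div_t[di] <= gt[gi]):
            t = div_t[di]
            kind = 2
            a = div_a[di]
            di += 1
        else:
            t = gt[gi]
            kind = gk[gi]
            a = ga[gi]
            gi += 1
        dt = t - t_prev
        if dt > 0.0:
            for j in range(P):
                if n[j] > 1:
                    coal_exp[j] += n[j] * (n[j] - 1) * dt
            for k in range(E):
                if a0[k] <= t_prev and t <= a1[k]:
                    mig_exp[k] += n[dst[k]] * dt
        if kind == 0:
            if n[a] < 2:
                return False
            c[a] += 1.0
            n[a] -= 1
            total -= 1
        elif kind == 1:
            j = dst[a]
            s = src[a]
            if n[j] < 1:
                return False
            if not (a0[a] <= t and t < a1[a]):
                return False
            w[a] += 1.0
            n[j] -= 1
            n[s] += 1
        else:
            c1 = schildren[a, 0]
            c2 = schildren[a, 1]
            n[a] += n[c1] + n[c2]
            n[c1] = 0
            n[c2] = 0
        t_prev = t
    return True


@njit(cache=True)
def dens_rows(c, coal_exp, w, mig_exp, theta, M, dst, h):  # pragma: no cover
    """MSC-M log density of one locus from its sufficient statistics."""
    P = c.shape[0]
    lp = 0.0
    for j in range(P):
        th = theta[j] * h
        if c[j] > 0.0:
            lp += c[j] * np.log(2.0 / th)
        lp -= coal_exp[j] / th
    for k in range(dst.shape[0]):
        th = theta[dst[k]] * h
        rate = 4.0 * M[k] / th
        if w[k] > 0.0:
            if rate <= 0.0:
                return -np.inf
            lp += w[k] * np.log(rate)
        lp -= rate * mig_exp[k]
    return lp
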