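"""Numba kernel for the Wright-Fisher generation loop.

Haplotypes are uint8 ancestry vectors over the marker lattice; gametes are
built by copying parental segments between crossover breakpoints drawn
uniformly in cM (count ~ Poisson(cM/100) per chromosome, independent
assortment via a random start haplotype per chromosome).  Selection is
soft: parents are sampled proportionally to viability.  Randomness uses
the numpy legacy global stream seeded inside the kernel, so runs are
reproducible for a given seed.

Selection encoding: mode 0 = neutral; mode 1 = DMI pairs (arrays pair_a,
pair_b, pair_s, pair_h; the pair penalty is s * f(minor dosage at a) *
f(major dosage at b) with f(0)=0, f(1)=h, f(2)=1); mode 2 = per-site
selection (hybridization load / single-parent: penalty s * f(dosage of
the target parent) per site, multiplicative).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_XO = 128  # crossovers per chromosome per meiosis; Poisson(cM/100) tail guard


@njit(cache=False)
def _dom(d, h):
    if d == 2:
        return 1.0
    if d == 1:
        return h
    return 0.0


@njit(cache=False)
def _fitness_kernel(hap, mode, pair_a, pair_b, pair_s, pair_h,
                    sites, site_s, site_h, target_major, w):
    n = hap.shape[0] // 2
    for i in range(n):
        w[i] = 1.0
    if mode == 0:
        return
    if mode == 1:
        for i in range(n):
            for p in range(pair_a.shape[0]):
                a = hap[2 * i, pair_a[p]] + hap[2 * i + 1, pair_a[p]]
                b = 2 - (hap[2 * i, pair_b[p]] + hap[2 * i + 1, pair_b[p]])
                w[i] *= 1.0 - pair_s[p] * _dom(a, pair_h[p]) * _dom(b, pair_h[p])
    else:
        for i in range(n):
            for p in range(sites.shape[0]):
                d = hap[2 * i, sites[p]] + hap[2 * i + 1, sites[p]]
                if target_major == 1:
                    d = 2 - d
                w[i] *= 1.0 - site_s[p] * _dom(d, site_h[p])
    # guard against an all-inviable generation: fall back to neutral weights
    tot = 0.0
    for i in range(n):
        tot += w[i]
    if tot <= 0.0:
        for i in range(n):
            w[i] = 1.0


@njit(cache=False)
def _bisect_left(arr, lo, hi, x):
    while lo < hi:
        mid = (lo + hi) >> 1
        if arr[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=False)
def _bisect_right(arr, lo, hi, x):
    while lo < hi:
        mid = (lo + hi) >> 1
        if arr[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=False)
def _make_gamete(out, g, hap_a, hap_b, chrom_starts, chrom_cm_len, marker_cm, buf):
    n_chrom = chrom_cm_len.shape[0]
    for c in range(n_chrom):
        cs = chrom_starts[c]
        ce = chrom_starts[c + 1]
        cur = np.random.randint(0, 2)
        k = np.random.poisson(chrom_cm_len[c] / 100.0)
        if k > _MAX_XO:
            k = _MAX_XO
        if k == 0:
            if cur == 0:
                for j in range(cs, ce):
                    out[g, j] = hap_a[j]
            else:
                for j in range(cs, ce):
                    out[g, j] = hap_b[j]
            continue
        for x in range(k):
            v = np.random.uniform(0.0, chrom_cm_len[c])
            y = x  # insertion sort; k is tiny
            while y > 0 and buf[y - 1] > v:
                buf[y] = buf[y - 1]
                y -= 1
            buf[y] = v
        idx0 = cs
        for x in range(k):
            idx1 = _bisect_left(marker_cm, idx0, ce, buf[x])
            if cur == 0:
                for j in range(idx0, idx1):
                    out[g, j] = hap_a[j]
            else:
                for j in range(idx0, idx1):
                    out[g, j] = hap_b[j]
            cur = 1 - cur
            idx0 = idx1
        if cur == 0:
            for j in range(idx0, ce):
                out[g, j] = hap_a[j]
        else:
            for j in range(idx0, ce):
                out[g, j] = hap_b[j]


@njit(cache=False)
def wf_run(hap, generations, mig_minor, mig_major,
           chrom_starts, chrom_cm_len, marker_cm,
           mode, pair_a, pair_b, pair_s, pair_h,
           sites, site_s, site_h, target_major, seed):
    """Run the generation loop in place; returns the final haplotype array."""
    np.random.seed(seed)
    two_n, m = hap.shape
    n = two_n // 2
    nxt = np.empty_like(hap)
    w = np.empty(n)
    cumw = np.empty(n)
    buf = np.empty(_MAX_XO)
    perm = np.arange(n)

    for _ in range(generations):
        # migration: replace distinct random individuals with pure parentals
        k_min = np.random.binomial(n, mig_minor) if mig_minor > 0.0 else 0
        k_maj = np.random.binomial(n, mig_major) if mig_major > 0.0 else 0
        k_tot = min(k_min + k_maj, n)
        if k_tot > 0:
            for i in range(k_tot):  # partial Fisher-Yates
                j = i + np.random.randint(0, n - i)
                tmp = perm[i]
                perm[i] = perm[j]
                perm[j] = tmp
            for i in range(k_tot):
                ind = perm[i]
                val = np.uint8(1) if i < k_min else np.uint8(0)
                for j in range(m):
                    hap[2 * ind, j] = val
                    hap[2 * ind + 1, j] = val

        _fitness_kernel(hap, mode, pair_a, pair_b, pair_s, pair_h,
                        sites, site_s, site_h, target_major, w)
        tot = 0.0
        for i in range(n):
            tot += w[i]
            cumw[i] = tot

        for g in range(two_n):
            u = np.random.uniform(0.0, tot)
            p = _bisect_right(cumw, 0, n, u)
            if p >= n:
                p = n - 1
            _make_gamete(nxt, g, hap[2 * p], hap[2 * p + 1],
                         chrom_starts, chrom_cm_len, marker_cm, buf)
        hap, nxt = nxt, hap
    return hap
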