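"""Independent brute-force reference implementations used as oracles.

These are deliberately written as plain, slow, loop-based code, separate
from the package's implementations, so that equivalence tests compare two
independently coded readings of the same procedure.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# burst calling: smooth -> threshold scan -> valley split -> >=5-frame filter


def ref_smooth(y, window=10):
    """Local linear regression with tricube weights over a sliding window.

    Window for frame t: the ``window`` consecutive frames starting at
    min(max(t - (window-1)//2, 0), n - window).  Fit via an explicit
    weighted least-squares design matrix (lstsq), not normal equations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = min(window, n)
    if w < 2:
        return y.copy()
    out = np.empty(n)
    for t in range(n):
        lo = t - (w - 1) // 2
        if lo < 0:
            lo = 0
        if lo > n - w:
            lo = n - w
        xs = np.arange(lo, lo + w, dtype=float)
        ys = y[lo:lo + w]
        d = np.abs(xs - t)
        dmax = d.max()
        if dmax == 0:
            weights = np.ones(w)
        else:
            u = d / dmax
            weights = (1 - u ** 3) ** 3
            weights[u >= 1] = 0.0
        sw = np.sqrt(weights)
        design = np.column_stack([np.ones(w), xs])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw,
                                   rcond=None)
        out[t] = coef[0] + coef[1] * t
    return out


def ref_split(run_vals):
    """Valley-split of a run of smoothed values; returns fragment slices."""
    fragments = []
    a = 0
    t = 2
    n = len(run_vals)
    while t <= n - 3:
        s = run_vals
        if s[t - 2] > s[t - 1] > s[t] and s[t] < s[t + 1] < s[t + 2]:
            fragments.append((a, t - 1))
            a = t
            t = a + 2
        else:
            t += 1
    fragments.append((a, n - 1))
    return fragments


def ref_call_bursts(raw, threshold, window=10, min_duration=5):
    """Burst intervals on a raw trace: baseline-zero, smooth, scan, split,
    filter.  Returns a list of (start, end) inclusive frame pairs."""
    raw = np.asarray(raw, dtype=float)
    bz = raw - raw.min()
    s = ref_smooth(bz, window)
    intervals = []
    t = 0
    n = len(s)
    while t < n:
        if s[t] > threshold:
            start = t
            while t < n and s[t] > threshold:
                t += 1
            end = t - 1
            for fa, fb in ref_split(s[start:end + 1]):
                if fb - fa + 1 >= min_duration:
                    intervals.append((start + fa, start + fb))
        else:
            t += 1
    return intervals


# ---------------------------------------------------------------------------
# genomics: quadratic interval oracles


def _overlaps(a_start, a_end, b_start, b_end):
    return a_start < b_end and b_start < a_end


def ref_filter_exonic(reads, exons, margin=50):
    kept = []
    for rd in reads:
        hit = False
        for ex in exons:
            if ex.chrom != rd.chrom:
                continue
            if _overlaps(rd.start, rd.end, max(ex.start - margin, 0),
                         ex.end + margin):
                hit = True
                break
        if not hit:
            kept.append(rd)
    return kept


def ref_count_reads(enhancer, reads):
    n = 0
    for rd in reads:
        if rd.chrom == enhancer.chrom and _overlaps(
                rd.start, rd.end, enhancer.start, enhancer.end):
            n += 1
    return n


def ref_classify(enhancer, tf_sites, tss_peaks, window=500):
    has_in = has_out = False
    for site in tf_sites:
        if site.chrom != enhancer.chrom or not _overlaps(
                site.start, site.end, enhancer.start, enhancer.end):
            continue
        m = (site.start + site.end) // 2
        for pk in tss_peaks:
            if pk.strand not in ("+", "-") or pk.chrom != site.chrom:
                continue
            p = (pk.start + pk.end) // 2
            if abs(p - m) > window:
                continue
            if _overlaps(pk.start, pk.end, site.start, site.end):
                inward = True
            elif pk.strand == "+":
                inward = p < m
            else:
                inward = p > m
            if inward:
                has_in = True
            else:
                has_out = True
    if has_in and has_out:
        return "both"
    if has_in:
        return "inward"
    if has_out:
        return "outward"
    return "none"
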