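"""Independently coded brute-force oracles for the statistics under test.

Everything here works by direct summation / enumeration with explicit
Python loops, deliberately avoiding the vectorized code paths of the
package so that agreement is a genuine cross-check.
"""

import math
from fractions import Fraction
from itertools import combinations


def gene_copies(dataset, site, locus):
    out = []
    for row in dataset.alleles[dataset.site_mask(site), locus, :]:
        for a in row:
            if a != 0:
                out.append(int(a))
    return out


def brute_he(copies):
    """Nei unbiased gene diversity by direct per-allele summation."""
    n = len(copies)
    ss = 0.0
    for a in set(copies):
        p = copies.count(a) / n
        ss += p * p
    return n / (n - 1) * (1.0 - ss)


def brute_ar_enumeration(copies, g):
    """Mean distinct-allele count over ALL g-subsets, exact rational."""
    total = Fraction(0)
    count = 0
    for sub in combinations(range(len(copies)), g):
        total += len({copies[i] for i in sub})
        count += 1
    return total / count


def brute_ar_formula(copies, g):
    """Rarefaction formula evaluated in exact rational arithmetic."""
    N = len(copies)
    denom = math.comb(N, g)
    total = Fraction(0)
    for a in set(copies):
        Na = copies.count(a)
        total += 1 - Fraction(math.comb(N - Na, g), denom)
    return total


def brute_wc(dataset, sites):
    """Weir & Cockerham multilocus (Fst, Fis, Fit) with explicit loops."""
    A = B = C = 0.0
    for l in range(dataset.n_loci):
        genos = []
        for s in sites:
            gn = [tuple(int(x) for x in row)
                  for row in dataset.alleles[dataset.site_mask(s), l, :]
                  if 0 not in row]
            if gn:
                genos.append(gn)
        if len(genos) < 2:
            continue
        alleles = sorted({a for gn in genos for g in gn for a in g})
        if len(alleles) < 2:
            continue
        r = len(genos)
        n_i = [len(gn) for gn in genos]
        nbar = sum(n_i) / r
        nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
        for allele in alleles:
            p_i, h_i = [], []
            for gn in genos:
                cnt = sum((g[0] == allele) + (g[1] == allele) for g in gn)
                het = sum(1 for g in gn if (g[0] == allele) != (g[1] == allele))
                p_i.append(cnt / (2 * len(gn)))
                h_i.append(het / len(gn))
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                               / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            A += a
            B += b
            C += c
    fst = A / (A + B + C)
    fis = 1 - C / (B + C)
    fit = 1 - C / (A + B + C)
    return fst, fis, fit


def brute_hs_ht(dataset, sites, locus):
    """Weighted H_S / H_T with corrections, via explicit loops."""
    per_site = []
    for s in sites:
        copies = gene_copies(dataset, s, locus)
        if len(copies) >= 2:
            per_site.append(copies)
    k = len(per_site)
    if k < 2:
        return None
    total = sum(len(c) for c in per_site)
    hs = 0.0
    for copies in per_site:
        hs += (len(copies) / total) * brute_he(copies)
    alleles = sorted({a for c in per_site for a in c})
    sum_pbar2 = 0.0
    for a in alleles:
        pbar = sum((len(c) / total) * (c.count(a) / len(c)) for c in per_site)
        sum_pbar2 += pbar * pbar
    ch = k / sum(1.0 / len(c) for c in per_site)
    ht = 1.0 - sum_pbar2 + hs / (ch * k)
    return hs, ht, k


def brute_gst_prime(dataset, sites):
    hs_l, ht_l = [], []
    k = None
    for l in range(dataset.n_loci):
        res = brute_hs_ht(dataset, sites, l)
        if res is None:
            continue
        hs_l.append(res[0])
        ht_l.append(res[1])
        k = res[2]
    hs = sum(hs_l) / len(hs_l)
    ht = sum(ht_l) / len(ht_l)
    gst = (ht - hs) / ht
    gst_max = (k - 1) * (1 - hs) / (k - 1 + hs)
    return gst / gst_max


def brute_jost_d(dataset, sites):
    num_l, den_l = [], []
    k = None
    for l in range(dataset.n_loci):
        res = brute_hs_ht(dataset, sites, l)
        if res is None:
            continue
        hs, ht, k = res
        num_l.append(ht - hs)
        den_l.append(1 - hs)
    num = sum(num_l) / len(num_l)
    den = sum(den_l) / len(den_l)
    return k / (k - 1) * num / den


def brute_rst(dataset, sites):
    """Allele-size ANOVA components combined over loci, explicit loops."""
    A = W = 0.0
    for l in range(dataset.n_loci):
        groups = []
        for s in sites:
            copies = gene_copies(dataset, s, l)
            if len(copies) >= 2:
                groups.append([float(x) for x in copies])
        if len(groups) < 2:
            continue
        allv = [v for g in groups for v in g]
        if len(set(allv)) < 2:
            continue
        N = len(allv)
        r = len(groups)
        grand = sum(allv) / N
        ss_w = 0.0
        ss_a = 0.0
        for g in groups:
            m = sum(g) / len(g)
            ss_w += sum((v - m) ** 2 for v in g)
            ss_a += len(g) * (m - grand) ** 2
        ms_w = ss_w / (N - r)
        ms_a = ss_a / (r - 1)
        n0 = (N - sum(len(g) ** 2 for g in groups) / N) / (r - 1)
        A += (ms_a - ms_w) / n0
        W += ms_w
    return A / (A + W)


def brute_shdi(raster_values):
    counts = {}
    for v in raster_values:
        counts[v] = counts.get(v, 0) + 1
    total = sum(counts.values())
    out = 0.0
    for c in counts.values():
        p = c / total
        out -= p * math.log(p)
    return out


def brute_bmq(raster_values, quality):
    num = den = 0.0
    total = len(raster_values)
    counts = {}
    for v in raster_values:
        counts[v] = counts.get(v, 0) + 1
    for code, c in counts.items():
        p = 100.0 * c / total
        num += p * quality[code]
        den += p
    return num / den


def brute_ols_slope(x, y):
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)
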