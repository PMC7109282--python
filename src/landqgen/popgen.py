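"""Microsatellite summary statistics and differentiation measures.

Per-site statistics: Nei's unbiased expected heterozygosity (He), rarefied
allelic richness (AR), the Weir & Cockerham within-population inbreeding
coefficient f with an allele-permutation test, and a molecular-coancestry
effective population size (Ne).  Pairwise statistics: Weir & Cockerham
F-statistics from allele-frequency variance components, Hedrick's G'_ST,
Jost's D, and Slatkin's R_ST from allele-size variance components with a
permutation test of F_ST = R_ST.

Conventions (documented because the literature varies):

* missing calls are dropped per locus (pairwise deletion), so every
  statistic uses the gene copies actually observed;
* multilocus F_ST / R_ST combine loci as ratios of summed variance
  components; G'_ST and D average the heterozygosity components over loci
  before forming the ratio;
* H_S and H_T use sample-size-weighted allele frequencies with
  small-sample corrections, so slightly negative estimates are possible
  for weak differentiation;
* permutation p-values use the add-one correction (b+1)/(n+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .datatypes import GenotypeDataset

__all__ = [
    "expected_heterozygosity",
    "allelic_richness",
    "default_rarefaction_g",
    "inbreeding_with_test",
    "wc_f_statistics",
    "hedrick_gst_prime",
    "jost_d",
    "slatkin_rst_with_test",
    "ne_coancestry",
    "site_diversity",
    "pair_differentiation",
    "SiteDiversity",
    "PairDifferentiation",
]


@dataclass
class SiteDiversity:
    site: object
    He: float
    AR: float
    f: float
    f_pvalue: float
    Ne: float  # inf when coancestry <= 0 (not estimable)


@dataclass
class PairDifferentiation:
    site_a: object
    site_b: object
    Fst: float
    Fis: float
    GstPrime: float
    JostD: float
    Rst: float
    Rst_se: float
    Fst_se: float
    perm_pvalue_Fst_eq_Rst: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _allele_counts(copies: np.ndarray):
    """(sizes, counts) for a flat array of gene copies."""
    return np.unique(copies, return_counts=True)


# ---------------------------------------------------------------------------
# expected heterozygosity
# ---------------------------------------------------------------------------

def expected_heterozygosity(dataset: GenotypeDataset, site, locus=None) -> float:
    """Nei's unbiased gene diversity; mean over loci when ``locus`` is None."""
    if locus is None:
        vals = [expected_heterozygosity(dataset, site, l) for l in range(dataset.n_loci)]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan
    copies = dataset.site_alleles(site, locus)
    n = copies.size
    if n < 2:
        raise ValueError(f"site {site!r} locus {locus}: fewer than 2 gene copies")
    _, counts = _allele_counts(copies)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


# ---------------------------------------------------------------------------
# allelic richness by rarefaction
# ---------------------------------------------------------------------------

def allelic_richness(dataset: GenotypeDataset, site, locus=None, g: int = None) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    AR = sum over alleles of 1 - C(N - N_a, g)/C(N, g); evaluated with exact
    integer binomials.  ``g`` defaults to the smallest gene-copy count over
    all site x locus cells (the usual rarefaction convention).
    """
    if g is None:
        g = default_rarefaction_g(dataset)
    if locus is None:
        return float(np.mean([allelic_richness(dataset, site, l, g)
                              for l in range(dataset.n_loci)]))
    copies = dataset.site_alleles(site, locus)
    N = copies.size
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds N={N} gene copies")
    if g < 1:
        raise ValueError("g must be >= 1")
    _, counts = _allele_counts(copies)
    denom = math.comb(N, g)
    total = 0.0
    for Na in counts:
        total += 1.0 - math.comb(N - Na, g) / denom
    return float(total)


def default_rarefaction_g(dataset: GenotypeDataset) -> int:
    gmin = None
    for site in dataset.sites:
        for l in range(dataset.n_loci):
            n = dataset.site_alleles(site, l).size
            if gmin is None or n < gmin:
                gmin = n
    if not gmin:
        raise ValueError("dataset has a site x locus cell with no data")
    return gmin


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components(dataset: GenotypeDataset, sites, locus):
    """Per-allele W&C (1984) components (a, b, c) at one locus.

    Returns three arrays (one entry per allele) or None when fewer than two
    sites have data or the locus is monomorphic across the sites.
    """
    genos = [dataset.site_genotypes(s, locus) for s in sites]
    genos = [gn for gn in genos if gn.shape[0] > 0]
    r = len(genos)
    if r < 2:
        return None
    all_sizes = np.unique(np.concatenate([gn.ravel() for gn in genos]))
    if all_sizes.size < 2:
        return None
    n_i = np.array([gn.shape[0] for gn in genos], dtype=float)
    nbar = n_i.mean()
    r_ = float(r)
    nc = (r_ * nbar - np.sum(n_i ** 2) / (r_ * nbar)) / (r_ - 1.0)
    # per-site allele frequencies and heterozygote frequencies, vectorized
    # over alleles: eq has shape (n_i, 2, n_alleles)
    P = np.empty((r, all_sizes.size))
    H = np.empty((r, all_sizes.size))
    for i, gn in enumerate(genos):
        eq = gn[:, :, None] == all_sizes[None, None, :]
        P[i] = eq.mean(axis=(0, 1))
        H[i] = (eq.sum(axis=1) == 1).mean(axis=0)
    pbar = (n_i @ P) / (r_ * nbar)
    s2 = (n_i @ (P - pbar) ** 2) / ((r_ - 1.0) * nbar)
    hbar = (n_i @ H) / (r_ * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r_ - 1) / r_ * s2 - hbar / 4.0)
                       / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r_ - 1) / r_ * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def wc_f_statistics(dataset: GenotypeDataset, sites=None, return_locus_components=False):
    """Multilocus Weir & Cockerham (theta, F_IS, F_IT) over ``sites``.

    Loci monomorphic across all sites contribute nothing (skipped).
    Multilocus values are ratios of summed components.
    """
    if sites is None:
        sites = dataset.sites
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    per_locus = []
    for l in range(dataset.n_loci):
        comp = _wc_components(dataset, sites, l)
        if comp is None:
            continue
        a, b, c = comp
        per_locus.append((a.sum(), b.sum(), c.sum()))
    if not per_locus:
        raise ValueError("no polymorphic locus across the requested sites")
    A = sum(x[0] for x in per_locus)
    B = sum(x[1] for x in per_locus)
    C = sum(x[2] for x in per_locus)
    tot = A + B + C
    fst = A / tot if tot != 0 else math.nan
    fis = 1.0 - C / (B + C) if (B + C) != 0 else math.nan
    fit = 1.0 - C / tot if tot != 0 else math.nan
    if return_locus_components:
        return (fst, fis, fit), per_locus
    return fst, fis, fit


def _fst_jackknife_se(per_locus):
    """Delete-one-locus jackknife SE of the ratio-of-sums F_ST."""
    L = len(per_locus)
    if L < 2:
        return math.nan
    A = sum(x[0] for x in per_locus)
    T = sum(sum(x) for x in per_locus)
    pseudo = []
    for a, b, c in per_locus:
        t = a + b + c
        denom = T - t
        pseudo.append((A - a) / denom if denom != 0 else math.nan)
    pseudo = np.array(pseudo, dtype=float)
    pseudo = pseudo[~np.isnan(pseudo)]
    L = pseudo.size
    if L < 2:
        return math.nan
    return float(math.sqrt((L - 1) / L * np.sum((pseudo - pseudo.mean()) ** 2)))


# ---------------------------------------------------------------------------
# within-population inbreeding with permutation test
# ---------------------------------------------------------------------------

def _inbreeding_components(genos: np.ndarray):
    """Single-population W&C (b, c) components summed over alleles."""
    n = genos.shape[0]
    sizes = np.unique(genos)
    if sizes.size < 2:
        return None
    eq = genos[:, :, None] == sizes[None, None, :]
    p = eq.mean(axis=(0, 1))
    h = (eq.sum(axis=1) == 1).mean(axis=0)
    b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
    c = h / 2.0
    return float(b.sum()), float(c.sum())


def _multilocus_f(per_locus_genos):
    B = C = 0.0
    any_poly = False
    for genos in per_locus_genos:
        if genos.shape[0] < 2:
            continue
        comp = _inbreeding_components(genos)
        if comp is None:
            continue
        any_poly = True
        B += comp[0]
        C += comp[1]
    if not any_poly or (B + C) == 0:
        return math.nan
    return 1.0 - C / (B + C)


def inbreeding_with_test(dataset: GenotypeDataset, site, n_perm: int = 999,
                         rng=None, per_locus: bool = False):
    """Weir & Cockerham within-population f with an allele-shuffle test.

    The null of Hardy-Weinberg genotype proportions is simulated by
    permuting gene copies among individuals within the site, per locus;
    p = ((#{|f_perm| >= |f_obs|}) + 1)/(n_perm + 1).  With ``per_locus``,
    also returns a per-locus (f, p) list.
    """
    rng = np.random.default_rng(rng)
    genos = [dataset.site_genotypes(site, l) for l in range(dataset.n_loci)]
    if sum(gn.shape[0] for gn in genos) == 0:
        raise ValueError(f"no genotypes at site {site!r}")
    n_ind = max(gn.shape[0] for gn in genos)
    if n_ind < 5:
        raise ValueError("need at least 5 individuals for the inbreeding test")
    f_obs = _multilocus_f(genos)
    if math.isnan(f_obs):
        raise ValueError(f"site {site!r} monomorphic: f undefined")

    def shuffle_once():
        shuffled = []
        for gn in genos:
            if gn.shape[0] == 0:
                shuffled.append(gn)
                continue
            flat = gn.ravel().copy()
            rng.shuffle(flat)
            shuffled.append(flat.reshape(-1, 2))
        return shuffled

    exceed = 0
    locus_exceed = [0] * dataset.n_loci
    f_locus_obs = []
    for gn in genos:
        comp = _inbreeding_components(gn) if gn.shape[0] >= 2 else None
        if comp is None or (comp[0] + comp[1]) == 0:
            f_locus_obs.append(math.nan)
        else:
            f_locus_obs.append(1.0 - comp[1] / (comp[0] + comp[1]))
    for _ in range(n_perm):
        perm = shuffle_once()
        f_p = _multilocus_f(perm)
        if not math.isnan(f_p) and abs(f_p) >= abs(f_obs):
            exceed += 1
        if per_locus:
            for l, gn in enumerate(perm):
                if math.isnan(f_locus_obs[l]) or gn.shape[0] < 2:
                    continue
                comp = _inbreeding_components(gn)
                if comp is None:
                    continue
                b, c = comp
                if (b + c) != 0 and abs(1.0 - c / (b + c)) >= abs(f_locus_obs[l]):
                    locus_exceed[l] += 1
    p = (exceed + 1) / (n_perm + 1)
    if per_locus:
        locus_results = [
            (f_locus_obs[l],
             (locus_exceed[l] + 1) / (n_perm + 1) if not math.isnan(f_locus_obs[l]) else math.nan)
            for l in range(dataset.n_loci)
        ]
        return f_obs, p, locus_results
    return f_obs, p


# ---------------------------------------------------------------------------
# H_S / H_T based statistics: Hedrick's G'_ST and Jost's D
# ---------------------------------------------------------------------------

def _hs_ht(dataset: GenotypeDataset, sites, locus):
    """Sample-size-weighted, small-sample-corrected (H_S, H_T) at one locus.

    H_S is the gene-copy-weighted mean of per-site unbiased gene
    diversities.  H_T uses the weighted pooled frequencies with the
    Nei-Chesser-style correction H_T = 1 - sum(pbar^2) + H_S/(c_h * k),
    c_h the harmonic-mean gene-copy count.
    """
    copies = [dataset.site_alleles(s, locus) for s in sites]
    copies = [c for c in copies if c.size >= 2]
    k = len(copies)
    if k < 2:
        return None
    sizes = np.unique(np.concatenate(copies))
    n = np.array([c.size for c in copies], dtype=float)
    w = n / n.sum()
    P = np.zeros((k, sizes.size))
    for i, c in enumerate(copies):
        s, cnt = np.unique(c, return_counts=True)
        P[i, np.searchsorted(sizes, s)] = cnt / c.size
    hs_i = n / (n - 1.0) * (1.0 - np.sum(P ** 2, axis=1))
    Hs = float(np.sum(w * hs_i))
    pbar = w @ P
    ch = k / np.sum(1.0 / n)  # harmonic mean gene copies
    Ht = float(1.0 - np.sum(pbar ** 2) + Hs / (ch * k))
    return Hs, Ht, k


def hedrick_gst_prime(dataset: GenotypeDataset, sites) -> float:
    """Hedrick's standardized G'_ST for a pair (or set) of sites.

    Multilocus: H_S and H_T are averaged over polymorphic loci before the
    ratio (summed-component convention).
    """
    sites = list(sites)
    hs_list, ht_list, k = _collect_hs_ht(dataset, sites)
    Hs, Ht = float(np.mean(hs_list)), float(np.mean(ht_list))
    if Ht == 0:
        return math.nan
    if Hs >= 1.0:
        raise ValueError("H_S = 1: G'_ST undefined (degenerate diversity)")
    gst = (Ht - Hs) / Ht
    gst_max = (k - 1.0) * (1.0 - Hs) / (k - 1.0 + Hs)
    gmax_over_ht = gst_max  # note G_ST(max) already on the G_ST scale
    if gmax_over_ht == 0:
        return math.nan
    return float(gst / gmax_over_ht)


def jost_d(dataset: GenotypeDataset, sites) -> float:
    """Jost's differentiation D; multilocus by averaging the (H_T - H_S)
    and (1 - H_S) terms over loci before the ratio."""
    sites = list(sites)
    hs_list, ht_list, k = _collect_hs_ht(dataset, sites)
    num = float(np.mean(np.array(ht_list) - np.array(hs_list)))
    den = float(np.mean(1.0 - np.array(hs_list)))
    if den == 0:
        return math.nan
    return float(k / (k - 1.0) * num / den)


def _collect_hs_ht(dataset, sites):
    hs_list, ht_list, kk = [], [], None
    for l in range(dataset.n_loci):
        res = _hs_ht(dataset, sites, l)
        if res is None:
            continue
        hs, ht, k = res
        hs_list.append(hs)
        ht_list.append(ht)
        kk = k
    if not hs_list:
        raise ValueError("no locus with data in at least two sites")
    return hs_list, ht_list, kk


# ---------------------------------------------------------------------------
# Slatkin's R_ST and the F_ST = R_ST permutation test
# ---------------------------------------------------------------------------

def _rst_components(copies_by_site):
    """One-way ANOVA variance components on allele sizes (gene copies).

    Returns (sigma2_among, sigma2_within) or None without size variation.
    """
    groups = [c.astype(float) for c in copies_by_site if c.size >= 2]
    r = len(groups)
    if r < 2:
        return None
    allv = np.concatenate(groups)
    if np.unique(allv).size < 2:
        return None
    n_i = np.array([g.size for g in groups], dtype=float)
    N = n_i.sum()
    grand = allv.mean()
    means = np.array([g.mean() for g in groups])
    ss_within = sum(np.sum((g - m) ** 2) for g, m in zip(groups, means))
    ss_among = np.sum(n_i * (means - grand) ** 2)
    ms_within = ss_within / (N - r)
    ms_among = ss_among / (r - 1)
    n0 = (N - np.sum(n_i ** 2) / N) / (r - 1)
    s2_within = ms_within
    s2_among = (ms_among - ms_within) / n0
    return s2_among, s2_within


def _rst_from_locus_components(comps):
    A = sum(c[0] for c in comps)
    W = sum(c[1] for c in comps)
    if (A + W) == 0:
        return math.nan
    return A / (A + W)


def slatkin_rst_with_test(dataset: GenotypeDataset, sites=None, n_perm: int = 999,
                          rng=None):
    """Multilocus R_ST, jackknife SE, and a permutation test of F_ST = R_ST.

    R_ST comes from among/within-population variance components of allele
    sizes (ratio of summed components over loci).  The null that stepwise
    size information is irrelevant is simulated by permuting the sizes
    assigned to the distinct allelic states within each locus; p is the
    add-one-corrected proportion of permutations with
    |R_ST_perm - F_ST| >= |R_ST_obs - F_ST|.
    """
    rng = np.random.default_rng(rng)
    if sites is None:
        sites = dataset.sites
    sites = list(sites)
    copies = [[dataset.site_alleles(s, l) for s in sites] for l in range(dataset.n_loci)]
    comps = []
    usable = []
    for l in range(dataset.n_loci):
        c = _rst_components(copies[l])
        if c is not None:
            comps.append(c)
            usable.append(l)
    if not comps:
        raise ValueError("no locus with allele-size variation")
    rst = _rst_from_locus_components(comps)
    rst_se = _ratio_jackknife_se(comps)
    fst, _, _ = wc_f_statistics(dataset, sites)
    obs = abs(rst - fst)
    exceed = 0
    for _ in range(n_perm):
        perm_comps = []
        for l in usable:
            allv = np.concatenate([c for c in copies[l] if c.size])
            states = np.unique(allv)
            perm_states = rng.permutation(states)
            remap = dict(zip(states.tolist(), perm_states.tolist()))
            permed = [np.array([remap[v] for v in c], dtype=np.int64) if c.size else c
                      for c in copies[l]]
            pc = _rst_components(permed)
            if pc is not None:
                perm_comps.append(pc)
        if not perm_comps:
            continue
        rst_p = _rst_from_locus_components(perm_comps)
        if not math.isnan(rst_p) and abs(rst_p - fst) >= obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return rst, rst_se, p


def _ratio_jackknife_se(comps):
    L = len(comps)
    if L < 2:
        return math.nan
    A = sum(c[0] for c in comps)
    T = sum(c[0] + c[1] for c in comps)
    pseudo = []
    for a, w in comps:
        denom = T - (a + w)
        if denom != 0:
            pseudo.append((A - a) / denom)
    pseudo = np.array(pseudo)
    L = pseudo.size
    if L < 2:
        return math.nan
    return float(math.sqrt((L - 1) / L * np.sum((pseudo - pseudo.mean()) ** 2)))


# ---------------------------------------------------------------------------
# effective size from molecular coancestry
# ---------------------------------------------------------------------------

def ne_coancestry(dataset: GenotypeDataset, site) -> tuple:
    """(Ne, mean coancestry) from the molecular-coancestry method.

    Pairwise similarity per locus for genotypes (a,b) and (c,d) is
    S = (I_ac + I_ad + I_bc + I_bd)/4; coancestry fhat averages S over
    loci within a pair, then over all pairs.  Ne = 1/(2 fhat); when
    fhat <= 0 the size is not estimable and Ne is returned as ``inf``.
    """
    idx = np.flatnonzero(dataset.site_mask(site))
    if idx.size < 2:
        raise ValueError("need at least 2 individuals")
    G = dataset.alleles[idx]  # (n, L, 2)
    n = idx.size
    vals = []
    for i, j in combinations(range(n), 2):
        per_locus = []
        for l in range(dataset.n_loci):
            a, b = G[i, l]
            c, d = G[j, l]
            if 0 in (a, b, c, d):
                continue
            s = (int(a == c) + int(a == d) + int(b == c) + int(b == d)) / 4.0
            per_locus.append(s)
        if per_locus:
            vals.append(float(np.mean(per_locus)))
    if not vals:
        raise ValueError("no pair with shared typed loci")
    fhat = float(np.mean(vals))
    ne = math.inf if fhat <= 0 else 1.0 / (2.0 * fhat)
    return ne, fhat


# ---------------------------------------------------------------------------
# convenience wrappers producing tidy results
# ---------------------------------------------------------------------------

def site_diversity(dataset: GenotypeDataset, site, g: int = None,
                   n_perm: int = 999, rng=None) -> SiteDiversity:
    he = expected_heterozygosity(dataset, site)
    ar = allelic_richness(dataset, site, g=g)
    f, p = inbreeding_with_test(dataset, site, n_perm=n_perm, rng=rng)
    ne, _ = ne_coancestry(dataset, site)
    return SiteDiversity(site=site, He=he, AR=ar, f=f, f_pvalue=p, Ne=ne)


def pair_differentiation(dataset: GenotypeDataset, site_a, site_b,
                         n_perm: int = 999, rng=None) -> PairDifferentiation:
    pair = [site_a, site_b]
    (fst, fis, _), per_locus = wc_f_statistics(dataset, pair, return_locus_components=True)
    gstp = hedrick_gst_prime(dataset, pair)
    d = jost_d(dataset, pair)
    rst, rst_se, p = slatkin_rst_with_test(dataset, pair, n_perm=n_perm, rng=rng)
    return PairDifferentiation(
        site_a=site_a, site_b=site_b, Fst=fst, Fis=fis, GstPrime=gstp,
        JostD=d, Rst=rst, Rst_se=rst_se, Fst_se=_fst_jackknife_se(per_locus),
        perm_pvalue_Fst_eq_Rst=p,
    )
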