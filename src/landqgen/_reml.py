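"""Restricted maximum likelihood for one-way and nested random-effects models.

Both models have a single fixed intercept and block-diagonal covariance, so
the REML criterion is profiled over the residual variance and optimized over
variance ratios gamma = sigma2_effect / sigma2_res with non-negativity
enforced by bound constraints.  Balanced designs use exact eigenvalue
decompositions (sums of squares); unbalanced ones fall back to per-block
dense Cholesky factorizations, which stay small because blocks are families
or populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class OnewayFit:
    sigma2_group: float
    sigma2_res: float
    mu: float
    loglik: float
    method: str  # "reml" or "anova"
    converged: bool


@dataclass
class NestedFit:
    sigma2_pop: float
    sigma2_fam: float
    sigma2_res: float
    mu: float
    loglik: float
    converged: bool


# ---------------------------------------------------------------------------
# one-way model: y_ij = mu + a_i + e_ij
# ---------------------------------------------------------------------------

def _oneway_profile(gamma, y, groups_idx, n_i):
    """(-2) profiled REML criterion (up to a constant) for ratio gamma."""
    N = y.size
    d = 1.0 + gamma * n_i
    # GLS with W_i^{-1} = I - gamma/(1+gamma n_i) J
    sums = np.array([y[g].sum() for g in groups_idx])
    # X = 1: X'W^-1 X = sum(n_i - gamma n_i^2/d) = sum(n_i/d)
    xwx = np.sum(n_i / d)
    xwy = np.sum(sums / d)
    mu = xwy / xwx
    q = 0.0
    for g, s, di, ni in zip(groups_idx, sums, d, n_i):
        r = y[g] - mu
        rs = s - ni * mu
        q += r @ r - gamma / di * rs * rs
    sigma2 = q / (N - 1)
    crit = ((N - 1) * math.log(max(sigma2, 1e-300))
            + float(np.sum(np.log(d)))
            + math.log(xwx))
    return crit, mu, sigma2


def reml_oneway(y, groups) -> OnewayFit:
    """REML fit of a single random grouping factor plus residual."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    groups_idx = [np.flatnonzero(inv == i) for i in range(labels.size)]
    n_i = np.array([g.size for g in groups_idx], dtype=float)
    N = y.size

    def crit(g):
        return _oneway_profile(g, y, groups_idx, n_i)[0]

    res = optimize.minimize_scalar(crit, bounds=(0.0, 1e6), method="bounded",
                                   options={"xatol": 1e-10})
    gamma = float(res.x)
    # the bounded minimizer never lands exactly on 0; prefer the boundary
    # when it is at least as good
    if crit(0.0) <= res.fun + 1e-9:
        gamma = 0.0
    c, mu, sigma2 = _oneway_profile(gamma, y, groups_idx, n_i)
    ll = -0.5 * (c + (N - 1) * (1.0 + _LOG2PI))
    return OnewayFit(sigma2_group=gamma * sigma2, sigma2_res=sigma2, mu=mu,
                     loglik=ll, method="reml", converged=bool(res.success))


def anova_oneway(y, groups) -> OnewayFit:
    """Method-of-moments (ANOVA) estimator with Searle's n0 coefficient."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    k = labels.size
    n_i = np.bincount(inv).astype(float)
    N = y.size
    means = np.array([y[inv == i].mean() for i in range(k)])
    grand = y.mean()
    ss_res = sum(float(np.sum((y[inv == i] - means[i]) ** 2)) for i in range(k))
    ss_grp = float(np.sum(n_i * (means - grand) ** 2))
    ms_res = ss_res / (N - k)
    ms_grp = ss_grp / (k - 1)
    n0 = (N - np.sum(n_i ** 2) / N) / (k - 1)
    s2g = max((ms_grp - ms_res) / n0, 0.0)
    return OnewayFit(sigma2_group=s2g, sigma2_res=ms_res, mu=float(grand),
                     loglik=math.nan, method="anova", converged=True)


# ---------------------------------------------------------------------------
# nested model: y_ijk = mu + p_i + f_ij + e_ijk
# ---------------------------------------------------------------------------

def _nested_sums_of_squares(y, pop_inv, fam_inv, k, F):
    fam_sum = np.bincount(fam_inv, weights=y, minlength=F)
    fam_n = np.bincount(fam_inv, minlength=F).astype(float)
    fam_mean = fam_sum / fam_n
    fam_pop = np.empty(F, dtype=int)
    for j in range(F):
        fam_pop[j] = pop_inv[np.flatnonzero(fam_inv == j)[0]]
    pop_sum = np.bincount(pop_inv, weights=y, minlength=k)
    pop_n = np.bincount(pop_inv, minlength=k).astype(float)
    pop_mean = pop_sum / pop_n
    grand = y.mean()
    ss_e = float(np.sum((y - fam_mean[fam_inv]) ** 2))
    ss_f = float(np.sum(fam_n * (fam_mean - pop_mean[fam_pop]) ** 2))
    ss_p = float(np.sum(pop_n * (pop_mean - grand) ** 2))
    return ss_e, ss_f, ss_p, fam_n, pop_n


def _nested_balanced_crit(params, ss, dims):
    gf, gp = params
    ss_e, ss_f, ss_p = ss
    k, f, m, N = dims
    d1 = 1.0
    d2 = 1.0 + m * gf
    d3 = 1.0 + m * gf + f * m * gp
    q = ss_e / d1 + ss_f / d2 + ss_p / d3
    sigma2 = q / (N - 1)
    # log|V| counts d3 with multiplicity k (k-1 among-pop contrasts plus the
    # grand mean); the REML term log|X'V^-1 X| = log(N/d3) cancels one of them
    crit = ((N - 1) * math.log(max(sigma2, 1e-300))
            + k * (f - 1) * math.log(d2) + (k - 1) * math.log(d3)
            + math.log(N))
    return crit, sigma2


def _nested_dense_crit(params, y, pop_blocks):
    """General path: per-population dense Cholesky of W = I + gf Jfam + gp J."""
    gf, gp = params
    logdet = 0.0
    xwx = 0.0
    xwy = 0.0
    solves = []
    for yb, fam_codes in pop_blocks:
        n = yb.size
        W = np.full((n, n), gp)
        same_fam = fam_codes[:, None] == fam_codes[None, :]
        W[same_fam] += gf
        W[np.diag_indices(n)] += 1.0
        L = np.linalg.cholesky(W)
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        ones = np.ones(n)
        Wiy = np.linalg.solve(W, yb)
        Wi1 = np.linalg.solve(W, ones)
        xwx += ones @ Wi1
        xwy += ones @ Wiy
        solves.append((yb, Wiy, Wi1))
    mu = xwy / xwx
    q = 0.0
    for yb, Wiy, Wi1 in solves:
        q += (yb @ Wiy) - 2 * mu * (np.ones_like(yb) @ Wiy) + mu ** 2 * np.sum(Wi1)
    N = sum(yb.size for yb, _ in pop_blocks)
    sigma2 = q / (N - 1)
    crit = (N - 1) * math.log(max(sigma2, 1e-300)) + logdet + math.log(xwx)
    return crit, sigma2, mu


def reml_nested(y, pop, fam) -> NestedFit:
    """REML for population + family(population) random effects."""
    y = np.asarray(y, dtype=float)
    pop = np.asarray(pop)
    fam_full = np.char.add(np.char.add(pop.astype(str), "::"), np.asarray(fam).astype(str))
    pop_labels, pop_inv = np.unique(pop, return_inverse=True)
    fam_labels, fam_inv = np.unique(fam_full, return_inverse=True)
    k, F, N = pop_labels.size, fam_labels.size, y.size
    if k < 2:
        raise ValueError("need at least 2 populations")
    ss_e, ss_f, ss_p, fam_n, pop_n = _nested_sums_of_squares(y, pop_inv, fam_inv, k, F)

    balanced = (np.unique(fam_n).size == 1 and np.unique(pop_n).size == 1
                and F % k == 0)
    if balanced:
        m = int(fam_n[0])
        f = F // k
        dims = (k, f, m, N)
        ss = (ss_e, ss_f, ss_p)

        def crit(params):
            return _nested_balanced_crit(params, ss, dims)[0]
    else:
        blocks = []
        for i in range(k):
            sel = np.flatnonzero(pop_inv == i)
            blocks.append((y[sel], fam_inv[sel]))

        def crit(params):
            return _nested_dense_crit(params, y, blocks)[0]

    best = None
    for x0 in ([0.1, 0.1], [1.0, 0.01], [0.01, 1.0]):
        res = optimize.minimize(crit, x0=np.array(x0), method="L-BFGS-B",
                                bounds=[(0.0, 1e6), (0.0, 1e6)])
        if best is None or res.fun < best.fun:
            best = res
    gf, gp = best.x
    # consider the boundary corners explicitly (variance components at 0)
    candidates = [(gf, gp), (0.0, gp), (gf, 0.0), (0.0, 0.0)]
    gf, gp = min(candidates, key=crit)
    if balanced:
        c, sigma2 = _nested_balanced_crit((gf, gp), ss, dims)
        mu = float(y.mean())  # GLS intercept equals the grand mean when balanced
    else:
        c, sigma2, mu = _nested_dense_crit((gf, gp), y, blocks)
    ll = -0.5 * (c + (N - 1) * (1.0 + _LOG2PI))
    return NestedFit(sigma2_pop=gp * sigma2, sigma2_fam=gf * sigma2,
                     sigma2_res=sigma2, mu=float(mu), loglik=ll,
                     converged=bool(best.success))
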