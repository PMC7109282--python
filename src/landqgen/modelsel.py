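"""Gaussian GLM fits with AICc ranking and Akaike weights.

Node-level responses (one observation per site) are confronted with three
single-predictor candidates - habitat amount, compositional heterogeneity,
and effective population size - ranked by the small-sample Akaike
criterion AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1) with k = 3 (intercept,
slope, residual variance).  Link-level responses (one observation per
landscape) are too few for information-theoretic ranking, so only the
slope significance is reported, with predictors log10-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GaussianFit",
    "fit_gaussian_glm",
    "aicc_rank",
    "node_level_selection",
    "link_level_selection",
]


@dataclass
class GaussianFit:
    name: str
    beta: float
    intercept: float
    pvalue: float
    loglik: float
    n: int
    k: int = 3  # intercept, slope, residual variance


def fit_gaussian_glm(y, x, name: str = "model", log10_x: bool = False) -> GaussianFit:
    """Maximum-likelihood Gaussian regression of y on a single predictor.

    Equivalent to OLS; the log-likelihood uses the ML variance (divisor n)
    so it is comparable across models in information criteria.  The slope
    p-value is the usual two-sided t-test.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if log10_x:
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive predictor values")
        x = np.log10(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("predictor has zero variance")
    beta = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - beta * x.mean())
    resid = y - intercept - beta * x
    rss = float(resid @ resid)
    df = n - 2
    if rss == 0:
        pvalue = 0.0
    else:
        se = math.sqrt(rss / df / sxx)
        t = beta / se
        pvalue = float(2.0 * stats.t.sf(abs(t), df))
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2_ml) + 1.0)
    return GaussianFit(name=name, beta=beta, intercept=intercept,
                       pvalue=pvalue, loglik=loglik, n=n)


def aicc(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _significance_tier(p: float) -> str:
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def aicc_rank(fits, n: int = None) -> pd.DataFrame:
    """Rank candidate fits of the same response by AICc.

    Returns a table with AICc, delta AICc, Akaike weights (summing to 1),
    the plausible-set flag (delta < 2) and the significance tier
    annotation (** p<0.05, * p<0.10).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if n is None:
        if len(ns) != 1:
            raise ValueError("fits use different observation counts")
        n = ns.pop()
    rows = []
    for f in fits:
        rows.append({
            "model": f.name, "beta": f.beta, "intercept": f.intercept,
            "p": f.pvalue, "df": float(f.k), "logLik": f.loglik,
            "AICc": aicc(f.loglik, f.k, n),
        })
    df = pd.DataFrame(rows)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    rel = np.exp(-0.5 * df["dAICc"])
    df["wAICc"] = rel / rel.sum()
    df["plausible"] = df["dAICc"] < 2.0
    df["signif"] = df["p"].map(_significance_tier)
    df = df.sort_values("AICc", kind="stable").reset_index(drop=True)
    return df[["model", "beta", "intercept", "AICc", "dAICc", "df",
               "wAICc", "p", "signif", "plausible", "logLik"]]


def node_level_selection(responses: pd.DataFrame, predictors: pd.DataFrame,
                         log10_x: bool = False) -> dict:
    """AICc rankings per node-level response over the predictor candidates.

    ``responses`` and ``predictors`` are aligned per site (same index).
    Missing response values are dropped listwise per response.  Returns
    ``{response name: ranking DataFrame}``.
    """
    out = {}
    for resp in responses.columns:
        y = responses[resp].to_numpy(float)
        fits = []
        for pred in predictors.columns:
            x = predictors[pred].to_numpy(float)
            fits.append(fit_gaussian_glm(y, x, name=pred, log10_x=log10_x))
        ns = {f.n for f in fits}
        out[resp] = aicc_rank(fits, n=min(ns))
    return out


def link_level_selection(responses: pd.DataFrame, predictor,
                         log10_x: bool = True) -> pd.DataFrame:
    """Significance-based report (beta, p) per link-level response.

    With only one observation per landscape the candidate sets are too
    small for AICc, so the slope test carries the inference; predictors
    are log10-transformed by default.
    """
    x = np.asarray(predictor, dtype=float)
    rows = []
    for resp in responses.columns:
        try:
            fit = fit_gaussian_glm(responses[resp].to_numpy(float), x,
                                   name=resp, log10_x=log10_x)
        except ValueError:  # too few usable observations for this response
            rows.append({"response": resp, "beta": math.nan,
                         "intercept": math.nan, "p": math.nan,
                         "signif": "", "n": 0})
            continue
        rows.append({"response": resp, "beta": fit.beta,
                     "intercept": fit.intercept, "p": fit.pvalue,
                     "signif": _significance_tier(fit.pvalue), "n": fit.n})
    return pd.DataFrame(rows)
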