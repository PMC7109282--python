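"""Quantitative genetics for open-pollinated families under mixed mating.

Open-pollinated ("half-sib") progeny of a partially selfing tree are more
related than true half-sibs, so the textbook Va = 4 sigma2_fam overstates
nothing only when selfing is absent.  Under mixed mating with population
inbreeding f, the selfing rate is s = 2f/(1+f), the within-family
coancestry theta = (1+3f)^2 / (8(1+f)), and the additive variance is
recovered from the among-family variance component as

    Va = sigma2_fam / (2 theta),    with  2 theta = (1+s)^2 / (2 (2-s)).

From Va we derive the evolvability CVa% = 100 sqrt(Va)/mean and the
narrow-sense heritability h2 = Va / (sigma2_fam + sigma2_res) (within-
population phenotypic variance).  Q_ST between paired sites uses a nested
population + family(population) model:

    Q_ST = sigma2_pop / (sigma2_pop + 2 sigma2_A),

and the phenotypic analogue P_ST replaces sigma2_A with total
within-population variance (scaled by an assumed additive proportion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._reml import anova_oneway, reml_nested, reml_oneway
from .datatypes import DEFAULT_KEEP_TRAITS, MEASUREMENT_DAYS, ProgenyTrialTable

__all__ = [
    "MatingSystemConstants",
    "VarianceDecomposition",
    "mating_constants",
    "growth_rate",
    "derive_growth_traits",
    "germination_summaries",
    "prune_correlated_traits",
    "fit_family_model",
    "qst",
    "pst",
]


@dataclass
class MatingSystemConstants:
    f: float
    s: float
    theta: float
    c: float

    def __post_init__(self):
        alt = (1.0 + self.s) ** 2 / (2.0 * (2.0 - self.s))
        if abs(self.c - alt) > 1e-12:
            raise AssertionError("the two routes to c = 2*theta disagree")


@dataclass
class VarianceDecomposition:
    trait: str
    site: object
    sigma2_pop: float
    sigma2_fam: float
    sigma2_res: float
    Va: float
    CVa_pct: float
    h2: float
    h2_raw: float
    h2_capped: bool
    trait_mean: float
    constants: MatingSystemConstants
    method: str


def mating_constants(f: float) -> MatingSystemConstants:
    """Selfing rate, within-family coancestry and correction c from f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("inbreeding coefficient f must be in [0, 1]")
    s = 2.0 * f / (1.0 + f)
    theta = (1.0 + 3.0 * f) ** 2 / (8.0 * (1.0 + f))
    return MatingSystemConstants(f=f, s=s, theta=theta, c=2.0 * theta)


def growth_rate(days, values) -> float:
    """OLS slope of a measurement series on day (growth per day)."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < 2:
        raise ValueError("growth rate needs at least 2 time points")
    d = days - days.mean()
    denom = d @ d
    if denom == 0:
        raise ValueError("all measurement days identical")
    return float(d @ (values - values.mean()) / denom)


def derive_growth_traits(table: ProgenyTrialTable,
                         days=MEASUREMENT_DAYS) -> ProgenyTrialTable:
    """Expand repeated ``H@day`` / ``D@day`` records into derived traits.

    Adds, per individual: HGR and DGR (regression slopes, cm/day and
    mm/day) and the initial/final heights and diameters IH, FH, ID, FD.
    """
    df = table.data
    derived = []
    for prefix, slope_name, init_name, final_name in (
        ("H@", "HGR", "IH", "FH"),
        ("D@", "DGR", "ID", "FD"),
    ):
        sub = df[df["trait"].str.startswith(prefix)]
        if sub.empty:
            continue
        sub = sub.assign(day=sub["trait"].str.slice(len(prefix)).astype(int))
        for (lsc, site, fam, ind), grp in sub.groupby(
                ["landscape", "site", "family", "individual"], sort=False):
            grp = grp.sort_values("day")
            if grp.shape[0] < 2:
                continue
            base = dict(landscape=lsc, site=site, family=fam, individual=ind)
            derived.append({**base, "trait": slope_name,
                            "value": growth_rate(grp["day"], grp["value"])})
            derived.append({**base, "trait": init_name,
                            "value": grp["value"].iloc[0]})
            derived.append({**base, "trait": final_name,
                            "value": grp["value"].iloc[-1]})
    if not derived:
        return table
    out = pd.concat([df, pd.DataFrame(derived)], ignore_index=True)
    return ProgenyTrialTable(out)


def germination_summaries(table: ProgenyTrialTable):
    """(TG per germinant, PG per site x family) from the germination block.

    PG = germinated/sown within each site x family; TG rows are kept only
    for individuals that germinated.
    """
    df = table.data
    germ = df[df["trait"] == "germinated"]
    if germ.empty:
        raise ValueError("no germination records ('germinated' trait)")
    pg = (germ.groupby(["landscape", "site", "family"])["value"]
          .agg(sown="count", germinated="sum").reset_index())
    if (pg["sown"] == 0).any():
        raise ValueError("a family with zero sown seeds")
    pg["PG"] = pg["germinated"] / pg["sown"]
    germinants = set(germ.loc[germ["value"] > 0, "individual"])
    tg = df[(df["trait"] == "TG") & df["individual"].isin(germinants)].copy()
    return tg.reset_index(drop=True), pg


def prune_correlated_traits(wide: pd.DataFrame, traits=None, threshold: float = 0.5,
                            keep=DEFAULT_KEEP_TRAITS) -> list:
    """Greedy removal of traits until no pairwise |r| exceeds ``threshold``.

    At each step the trait with the most offending partners is dropped
    (ties: larger mean |r|); traits on the keep-list are never dropped.
    Constant traits cannot enter the correlation matrix and are retained
    with a warning.
    """
    if traits is None:
        traits = [c for c in wide.columns
                  if c not in ("landscape", "site", "family", "individual")]
    traits = list(traits)
    keep = set(keep or ())
    X = wide[traits]
    constant = [t for t in traits if X[t].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"constant traits excluded from correlation screen: {constant}")
    active = [t for t in traits if t not in constant]
    while True:
        corr = X[active].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        over = (corr > threshold)
        counts = over.sum(axis=1)
        droppable = [t for t in active if t not in keep and counts[t] > 0]
        if not droppable:
            break
        worst = max(droppable,
                    key=lambda t: (counts[t], corr.loc[t, over.loc[t]].mean()))
        active.remove(worst)
    return active + constant


def _site_oneway(table: ProgenyTrialTable, trait: str, site, method: str):
    sub = table.trait_frame(trait)
    sub = sub[sub["site"] == site]
    if sub.empty:
        raise ValueError(f"no {trait!r} data at site {site!r}")
    if sub["family"].nunique() < 2:
        raise ValueError(f"site {site!r} has fewer than 2 families for {trait!r}")
    y = sub["value"].to_numpy(float)
    fams = sub["family"].to_numpy()
    if method == "anova":
        return anova_oneway(y, fams), y
    fit = reml_oneway(y, fams)
    if not fit.converged:
        warnings.warn(f"REML did not converge for {trait!r} at {site!r}; "
                      "falling back to the ANOVA estimator")
        return anova_oneway(y, fams), y
    return fit, y


def fit_family_model(table: ProgenyTrialTable, trait: str, f: float,
                     site=None, method: str = "reml") -> VarianceDecomposition:
    """Va, CVa% and h2 for one trait at one site (or pooled across sites).

    The among-family variance component from a REML fit of
    y = mu + family + residual is converted to additive variance with the
    mixed-mating correction Va = sigma2_fam/(2 theta).  h2 above 1 (possible
    for small theta) is reported raw and capped with a warning flag.
    """
    const = mating_constants(f)
    if site is None:
        sites = table.sites
        if len(sites) == 1:
            site = sites[0]
        else:
            return _pooled_family_model(table, trait, const, method)
    fit, y = _site_oneway(table, trait, site, method)
    return _decomposition(trait, site, 0.0, fit.sigma2_group, fit.sigma2_res,
                          float(np.mean(y)), const, fit.method)


def _pooled_family_model(table, trait, const, method):
    sub = table.trait_frame(trait)
    y = sub["value"].to_numpy(float)
    fit = reml_nested(y, sub["site"].to_numpy(), sub["family"].to_numpy())
    return _decomposition(trait, None, fit.sigma2_pop, fit.sigma2_fam,
                          fit.sigma2_res, float(np.mean(y)), const, "reml")


def _decomposition(trait, site, s2p, s2f, s2e, mean, const, method):
    va = s2f / const.c
    vp_within = s2f + s2e
    h2_raw = va / vp_within if vp_within > 0 else math.nan
    capped = h2_raw > 1.0
    if capped:
        warnings.warn(f"h2 for {trait!r} exceeds 1 ({h2_raw:.3f}); "
                      "reporting the raw value and a capped copy")
    cva = 100.0 * math.sqrt(max(va, 0.0)) / mean if mean > 0 else math.nan
    return VarianceDecomposition(
        trait=trait, site=site, sigma2_pop=s2p, sigma2_fam=s2f, sigma2_res=s2e,
        Va=va, CVa_pct=cva, h2=min(h2_raw, 1.0) if not math.isnan(h2_raw) else h2_raw,
        h2_raw=h2_raw, h2_capped=capped, trait_mean=mean, constants=const,
        method=method,
    )


def qst(table: ProgenyTrialTable, trait: str, f: float, sites=None) -> float:
    """Q_ST between two sites from the nested population/family model."""
    sub = table.trait_frame(trait)
    if sites is not None:
        sub = sub[sub["site"].isin(list(sites))]
    if sub["site"].nunique() < 2:
        raise ValueError("Q_ST needs at least 2 sites")
    fit = reml_nested(sub["value"].to_numpy(float), sub["site"].to_numpy(),
                      sub["family"].to_numpy())
    const = mating_constants(f)
    sigma2_a = fit.sigma2_fam / const.c
    denom = fit.sigma2_pop + 2.0 * sigma2_a
    if denom == 0:
        raise ValueError("zero total genetic variance: Q_ST undefined")
    return float(fit.sigma2_pop / denom)


def pst(table: ProgenyTrialTable, trait: str, sites=None,
        additive_proportion: float = 1.0) -> float:
    """P_ST between two sites from phenotypic variance partitioning.

    additive_proportion is the assumed c/h2 ratio scaling the
    between-population component (default 1, exposed for sensitivity
    analysis).
    """
    sub = table.trait_frame(trait)
    if sites is not None:
        sub = sub[sub["site"].isin(list(sites))]
    if sub["site"].nunique() < 2:
        raise ValueError("P_ST needs at least 2 sites")
    fit = reml_oneway(sub["value"].to_numpy(float), sub["site"].to_numpy())
    num = additive_proportion * fit.sigma2_group
    denom = num + 2.0 * fit.sigma2_res
    if denom == 0:
        raise ValueError("zero total variance: P_ST undefined")
    return float(num / denom)


def site_pairs_within_landscapes(table: ProgenyTrialTable):
    """(landscape, site_a, site_b) tuples for all within-landscape pairs."""
    df = table.data[["landscape", "site"]].drop_duplicates()
    out = []
    for lsc, grp in df.groupby("landscape", sort=False):
        for a, b in combinations(grp["site"].tolist(), 2):
            out.append((lsc, a, b))
    return out
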