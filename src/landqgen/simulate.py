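"""Synthetic genotypes, progeny trials and land-cover scenes with known truth.

Every downstream stage of the pipeline is exercised on data whose
generating parameters are known, so parameter recovery can be tested:

* genotypes: per-site allele frequencies follow the Balding-Nichols
  divergence model - Dirichlet with concentration (1-F)/F times the
  ancestral frequencies - whose expected F_ST equals the divergence
  parameter F; within sites, inbreeding is realized as an
  identical-by-descent draw mixture with weight f;
* progeny trials: trait = mean + population effect + family effect +
  residual, with the family variance set to 2*theta*Va so the
  mixed-mating correction recovers the target additive variance exactly
  in expectation;
* scenes: autocorrelated class-coded rasters built from smoothed noise
  fields thresholded at the target habitat percentage, with sites placed
  inside habitat patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import GenotypeDataset, LandscapeScene, ProgenyTrialTable
from .quantgen import mating_constants

__all__ = [
    "GenotypeSimSpec",
    "TraitSimSpec",
    "SceneSimSpec",
    "simulate_genotypes",
    "simulate_progeny_trial",
    "simulate_scene",
    "default_class_table",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSimSpec:
    n_landscapes: int = 5
    sites_per_landscape: int = 2
    n_individuals_per_site: int = 60
    n_loci: int = 10
    alleles_per_locus: int = 15
    ancestral_freqs: np.ndarray = None  # (n_loci, alleles_per_locus); uniform if None
    target_Fst: float = 0.05
    inbreeding_f: float = 0.0
    allele_size_step: int = 2
    allele_size_base: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_landscapes", "sites_per_landscape",
                     "n_individuals_per_site", "n_loci", "alleles_per_locus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.target_Fst < 1.0:
            raise ValueError("target_Fst must be in [0, 1)")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")
        if self.ancestral_freqs is None:
            self.ancestral_freqs = np.full(
                (self.n_loci, self.alleles_per_locus), 1.0 / self.alleles_per_locus)
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if self.ancestral_freqs.shape != (self.n_loci, self.alleles_per_locus):
            raise ValueError("ancestral_freqs must be (n_loci, alleles_per_locus)")
        if np.any(np.abs(self.ancestral_freqs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each ancestral frequency vector must sum to 1")


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeDataset:
    """Draw a site-structured microsatellite dataset.

    Allele k at a locus is reported as size base + k*step so stepwise
    (R_ST) statistics are computable.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_sites = spec.n_landscapes * spec.sites_per_landscape
    n_ind = n_sites * spec.n_individuals_per_site
    F = spec.target_Fst
    sizes = spec.allele_size_base + spec.allele_size_step * np.arange(spec.alleles_per_locus)
    alleles = np.empty((n_ind, spec.n_loci, 2), dtype=np.int64)
    site_labels = []
    landscape_of = {}
    row = 0
    for lsc in range(spec.n_landscapes):
        for s in range(spec.sites_per_landscape):
            site = f"L{lsc + 1}S{s + 1}"
            landscape_of[site] = f"L{lsc + 1}"
            for l in range(spec.n_loci):
                anc = spec.ancestral_freqs[l]
                if F == 0.0:
                    p = anc
                else:
                    conc = anc * (1.0 - F) / F
                    p = rng.dirichlet(np.maximum(conc, 1e-12))
                n = spec.n_individuals_per_site
                first = rng.choice(spec.alleles_per_locus, size=n, p=p)
                second = rng.choice(spec.alleles_per_locus, size=n, p=p)
                ibd = rng.random(n) < spec.inbreeding_f
                second = np.where(ibd, first, second)
                alleles[row:row + n, l, 0] = sizes[first]
                alleles[row:row + n, l, 1] = sizes[second]
            site_labels.extend([site] * spec.n_individuals_per_site)
            row += spec.n_individuals_per_site
    return GenotypeDataset(alleles=alleles, site_of=np.array(site_labels),
                           landscape_of=landscape_of,
                           locus_names=[f"loc{l + 1}" for l in range(spec.n_loci)])


# ---------------------------------------------------------------------------
# progeny trials
# ---------------------------------------------------------------------------

@dataclass
class TraitSimSpec:
    n_sites: int = 2
    families_per_site: int = 30
    offspring_per_family: int = 12
    trait_mean: float = 10.0
    var_between_pops: float = 0.0
    target_Va: float = 4.0
    var_residual: float = 6.0
    inbreeding_f: float = 0.0
    rng_seed: int = 0
    family_sizes: list = None  # optional unbalanced sizes (per family, recycled)

    def __post_init__(self):
        if self.offspring_per_family < 2:
            raise ValueError("offspring_per_family must be >= 2")
        for name in ("var_between_pops", "target_Va", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")

    @property
    def sigma2_family(self) -> float:
        """Implied among-family variance: 2*theta*Va."""
        return mating_constants(self.inbreeding_f).c * self.target_Va


def simulate_progeny_trial(spec: TraitSimSpec, trait_name: str = "trait",
                           landscape_of=None, site_names=None,
                           rng=None) -> ProgenyTrialTable:
    """One quantitative trait over open-pollinated families in sites."""
    rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    s2f = spec.sigma2_family
    rows = []
    if site_names is None:
        site_names = [f"S{i + 1}" for i in range(spec.n_sites)]
    for si, site in enumerate(site_names):
        lsc = landscape_of[site] if landscape_of else "L1"
        pop_eff = rng.normal(0.0, math.sqrt(spec.var_between_pops))
        for fj in range(spec.families_per_site):
            fam = f"{site}F{fj + 1}"
            fam_eff = rng.normal(0.0, math.sqrt(s2f))
            if spec.family_sizes is not None:
                m = spec.family_sizes[fj % len(spec.family_sizes)]
            else:
                m = spec.offspring_per_family
            resid = rng.normal(0.0, math.sqrt(spec.var_residual), size=m)
            for oi in range(m):
                rows.append((lsc, site, fam, f"{fam}O{oi + 1}", trait_name,
                             spec.trait_mean + pop_eff + fam_eff + resid[oi]))
    return ProgenyTrialTable(pd.DataFrame(
        rows, columns=["landscape", "site", "family", "individual",
                       "trait", "value"]))


# ---------------------------------------------------------------------------
# land-cover scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneSimSpec:
    grid_shape: tuple = (600, 600)
    cell_size: float = 10.0
    n_classes: int = 11
    target_habitat_pct: float = 40.0
    habitat_class_id: int = 2
    smoothing_iterations: int = 3
    n_sites: int = 2
    landscape_id: str = "L1"
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_habitat_pct <= 100.0:
            raise ValueError("target_habitat_pct must be in [0, 100]")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 1 <= self.habitat_class_id <= self.n_classes:
            raise ValueError("habitat_class_id must be one of the class codes")


def default_class_table(n_classes: int = 11, habitat_class_id: int = 2) -> pd.DataFrame:
    """Class codes 1..n with quality scores spanning 0.2-1.0.

    The habitat class scores 1.0; the others are spread evenly down to 0.2
    (placeholder scores for synthetic runs, fully user-overridable).
    Composite groups mirror the open-vegetation and pollinator-habitat
    groupings used at link level.
    """
    names = ["water", "savanna", "riparian_forest", "seasonal_forest",
             "wetland", "pasture", "agriculture", "rural_building",
             "urban", "road", "eucalyptus"]
    rows = []
    others = [c for c in range(1, n_classes + 1) if c != habitat_class_id]
    for c in range(1, n_classes + 1):
        if c == habitat_class_id:
            q = 1.0
        else:
            rank = others.index(c)
            q = 0.2 + 0.7 * (1.0 - rank / max(len(others) - 1, 1))
        name = names[c - 1] if c <= len(names) else f"class{c}"
        groups = []
        if name in ("savanna", "pasture", "wetland"):
            groups.append("open_vegetation")
        if name in ("savanna", "pasture", "wetland", "seasonal_forest",
                    "riparian_forest"):
            groups.append("pollinator_habitat")
        rows.append({"code": c, "name": name, "quality": round(q, 3),
                     "groups": ";".join(groups)})
    return pd.DataFrame(rows)


def simulate_scene(spec: SceneSimSpec, class_table: pd.DataFrame = None) -> LandscapeScene:
    """Autocorrelated class raster hitting the target habitat percentage.

    A smoothed Gaussian noise field is thresholded at the habitat-target
    quantile (realized percentage within rounding of the target); the
    remaining cells are partitioned among the other classes along a second
    smoothed field, giving contiguous patches of every class.  Sites are
    placed inside the largest habitat patches (grid center when there is
    no habitat).
    """
    rng = np.random.default_rng(spec.rng_seed)
    nrow, ncol = spec.grid_shape
    sigma = 2.0 * max(spec.smoothing_iterations, 1)
    habitat_field = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), sigma)
    frac = spec.target_habitat_pct / 100.0
    if frac >= 1.0:
        habitat = np.ones((nrow, ncol), dtype=bool)
    elif frac <= 0.0:
        habitat = np.zeros((nrow, ncol), dtype=bool)
    else:
        cut = np.quantile(habitat_field, 1.0 - frac)
        habitat = habitat_field > cut
        realized = 100.0 * habitat.mean()
        if abs(realized - spec.target_habitat_pct) > 2.0:
            raise ValueError(
                f"habitat target {spec.target_habitat_pct}% unreachable on this "
                f"grid (realized {realized:.1f}%)")
    raster = np.full((nrow, ncol), spec.habitat_class_id, dtype=np.int64)
    others = [c for c in range(1, spec.n_classes + 1) if c != spec.habitat_class_id]
    if others and not habitat.all():
        matrix_field = ndimage.gaussian_filter(rng.standard_normal((nrow, ncol)), sigma)
        vals = matrix_field[~habitat]
        qs = np.quantile(vals, np.linspace(0, 1, len(others) + 1)[1:-1]) if len(others) > 1 else []
        codes = np.searchsorted(qs, vals)
        raster[~habitat] = np.array(others)[codes]
    if class_table is None:
        class_table = default_class_table(spec.n_classes, spec.habitat_class_id)
    sites = _place_sites(habitat, spec, rng)
    return LandscapeScene(raster=raster, cell_size=spec.cell_size,
                          class_table=class_table, sites=sites)


def _place_sites(habitat, spec: SceneSimSpec, rng) -> pd.DataFrame:
    nrow, ncol = habitat.shape
    cs = spec.cell_size
    rows = []
    if habitat.any():
        labels, n = ndimage.label(habitat, structure=np.ones((3, 3), bool))
        sizes = np.bincount(labels.ravel())[1:]
        order = np.argsort(sizes)[::-1] + 1
        cells_by_patch = [np.argwhere(labels == pid) for pid in order[:max(spec.n_sites, 1)]]
        for i in range(spec.n_sites):
            cells = cells_by_patch[i % len(cells_by_patch)]
            r, c = cells[rng.integers(cells.shape[0])]
            x = (c + 0.5) * cs
            y = (nrow - 1 - r + 0.5) * cs
            rows.append({"site": f"{spec.landscape_id}S{i + 1}", "x": x, "y": y,
                         "landscape": spec.landscape_id})
    else:
        for i in range(spec.n_sites):
            rows.append({"site": f"{spec.landscape_id}S{i + 1}",
                         "x": ncol * cs / 2.0, "y": nrow * cs / 2.0,
                         "landscape": spec.landscape_id})
    return pd.DataFrame(rows)
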