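"""Study-design presets: the reference sampling layout on synthetic data.

The reference design is five 6 x 6 km landscapes, each holding two savanna
sites: ~60 genotyped adults per site at 10 microsatellite loci, balanced
open-pollinated seed families per site grown in a nursery (the field
totals imply roughly a hundred seeds per site; family sizes are balanced
here because the per-family counts are not published), and an 11-class
land-cover raster per landscape with habitat percentage varying across
landscapes.  All numeric choices are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datatypes import ProgenyTrialTable
from .quantgen import mating_constants
from .simulate import GenotypeSimSpec, SceneSimSpec, TraitSimSpec

#: per-landscape habitat-amount targets (%) spanning the fragmentation gradient
HABITAT_TARGETS = (15.0, 25.0, 35.0, 45.0, 60.0)

#: generating values per trait: (mean, sigma2_pop, Va, sigma2_res, unit)
TRAIT_PARAMS = {
    "SLD": (22.0, 0.30, 2.0, 3.0, "mm"),
    "STD": (8.0, 0.05, 0.4, 0.6, "mm"),
    "SM": (150.0, 40.0, 300.0, 500.0, "mg"),
    "NL": (8.0, 0.20, 1.2, 2.0, "count"),
    "LW": (25.0, 0.50, 8.0, 12.0, "mm"),
    "RL": (25.0, 1.00, 6.0, 9.0, "cm"),
    "RDM": (0.5, 0.002, 0.03, 0.05, "g"),
    "ASL": (15.0, 0.50, 3.0, 5.0, "cm"),
    "TG": (12.0, 0.30, 2.0, 4.0, "days"),
}

#: inbreeding level used when generating traits (within the 0.12-0.23 band
#: typical of a mixed-mating savanna tree)
PRESET_F = 0.15


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every stochastic step is seeded."""

    seed: int = 1
    n_landscapes: int = 5
    sites_per_landscape: int = 2
    n_individuals_per_site: int = 60
    n_loci: int = 10
    alleles_per_locus: int = 15
    target_Fst: float = 0.05
    inbreeding_f: float = PRESET_F
    families_per_site: int = 15
    offspring_per_family: int = 7
    grid_shape: tuple = (600, 600)
    cell_size: float = 10.0
    n_classes: int = 11
    habitat_class: int = 2
    habitat_targets: tuple = HABITAT_TARGETS
    node_radius: float = 500.0
    link_radii: tuple = (2000.0, 4000.0, 6000.0)
    dispersal_radius: float = 500.0
    rarefaction_g: int = None
    n_perm: int = 199
    trait_params: dict = field(default_factory=lambda: dict(TRAIT_PARAMS))

    def genotype_spec(self) -> GenotypeSimSpec:
        return GenotypeSimSpec(
            n_landscapes=self.n_landscapes,
            sites_per_landscape=self.sites_per_landscape,
            n_individuals_per_site=self.n_individuals_per_site,
            n_loci=self.n_loci, alleles_per_locus=self.alleles_per_locus,
            target_Fst=self.target_Fst, inbreeding_f=self.inbreeding_f,
            rng_seed=self.seed,
        )

    def scene_specs(self) -> list:
        specs = []
        for i in range(self.n_landscapes):
            target = self.habitat_targets[i % len(self.habitat_targets)]
            specs.append(SceneSimSpec(
                grid_shape=self.grid_shape, cell_size=self.cell_size,
                n_classes=self.n_classes, target_habitat_pct=target,
                habitat_class_id=self.habitat_class,
                n_sites=self.sites_per_landscape,
                landscape_id=f"L{i + 1}", rng_seed=self.seed * 1000 + i,
            ))
        return specs

    def to_yaml(self, path):
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        d["trait_params"] = {k: list(v) for k, v in self.trait_params.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("grid_shape", "habitat_targets", "link_radii"):
            if k in d:
                d[k] = tuple(d[k])
        if "trait_params" in d:
            d["trait_params"] = {k: tuple(v) for k, v in d["trait_params"].items()}
        return cls(**d)


def paper_like_config(seed: int = 1) -> RunConfig:
    return RunConfig(seed=seed)


def simulate_design_traits(config: RunConfig) -> ProgenyTrialTable:
    """Full multi-trait progeny table for the reference design.

    Core traits are generated independently from the family model (so each
    one's Va is recoverable); redundant companions (LL from LW, AGM/ADM
    from ASL, RGM from RDM) and the repeated height/diameter series are
    derived with strong correlations so the pruning and growth-rate stages
    have realistic work to do.  A germination block (sown seeds with
    germinated flags and TG for germinants) is included per family.
    """
    rng = np.random.default_rng(config.seed + 7919)
    sites, landscape_of = [], {}
    for i in range(config.n_landscapes):
        for j in range(config.sites_per_landscape):
            s = f"L{i + 1}S{j + 1}"
            sites.append(s)
            landscape_of[s] = f"L{i + 1}"
    c = mating_constants(config.inbreeding_f).c
    nf, m = config.families_per_site, config.offspring_per_family
    rows = []
    for site in sites:
        lsc = landscape_of[site]
        core = {}
        for trait, (mean, s2p, va, s2e, _unit) in config.trait_params.items():
            s2f = c * va
            pop_eff = rng.normal(0.0, np.sqrt(s2p))
            fam_eff = np.repeat(rng.normal(0.0, np.sqrt(s2f), nf), m)
            resid = rng.normal(0.0, np.sqrt(s2e), nf * m)
            core[trait] = mean + pop_eff + fam_eff + resid
        inds = [f"{site}F{fj + 1}O{oi + 1}" for fj in range(nf) for oi in range(m)]
        fams = [f"{site}F{fj + 1}" for fj in range(nf) for oi in range(m)]
        n = nf * m
        # redundant companions (induce |r| > 0.5 clusters for the pruning)
        derived = {
            "LL": 2.2 * core["LW"] + rng.normal(0, 3.0, n),
            "AGM": 0.12 * core["ASL"] + rng.normal(0, 0.05, n),
            "RGM": 2.5 * core["RDM"] + rng.normal(0, 0.05, n),
        }
        derived["ADM"] = 0.45 * derived["AGM"] + rng.normal(0, 0.01, n)
        # repeated growth series: height (cm) and diameter (mm)
        h0 = 8.0 + 0.5 * rng.standard_normal(n)
        hslope = 0.05 + 0.01 * rng.standard_normal(n)
        d0 = 2.0 + 0.2 * rng.standard_normal(n)
        dslope = 0.010 + 0.002 * rng.standard_normal(n)
        series = {}
        for day in (76, 116, 133, 145):
            series[f"H@{day}"] = h0 + hslope * (day - 76) + rng.normal(0, 0.2, n)
            series[f"D@{day}"] = d0 + dslope * (day - 76) + rng.normal(0, 0.05, n)
        for name, vals in {**core, **derived, **series}.items():
            for ind, fam, v in zip(inds, fams, vals):
                rows.append((lsc, site, fam, ind, name, float(v)))
        # germination block: every trial individual germinated by definition;
        # a few extra sown seeds per family carry stochastic failures so the
        # realized PG sits near 0.8
        for ind, fam in zip(inds, fams):
            rows.append((lsc, site, fam, ind, "germinated", 1.0))
        for fj in range(nf):
            fam = f"{site}F{fj + 1}"
            for si_, g in enumerate(rng.binomial(1, 0.3, 3)):
                rows.append((lsc, site, fam, f"{fam}seed{si_ + 1}",
                             "germinated", float(g)))
    table = ProgenyTrialTable(pd.DataFrame(
        rows, columns=["landscape", "site", "family", "individual", "trait", "value"]))
    return table
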