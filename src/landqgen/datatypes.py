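"""Core in-memory containers shared across the analysis stages.

The pipeline moves three kinds of data around: diploid microsatellite
genotypes grouped into sites nested in landscapes, progeny-trial trait
tables (seedlings nested in open-pollinated maternal families nested in
sites), and class-coded land-cover rasters with site coordinates.  Each
container is a thin dataclass over numpy/pandas structures so that every
stage can also be driven from plain CSV / GenePop / ASCII-grid files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing allele call (GenePop "000")
MISSING = 0


@dataclass
class GenotypeDataset:
    """Diploid allele-size calls for individuals grouped by site.

    Parameters
    ----------
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding allele
        sizes (repeat-ladder integers).  ``0`` marks a missing call; an
        individual is missing at a locus only when both copies are ``0``.
    site_of
        Site label per individual, length ``n_individuals``.
    landscape_of
        Mapping from site label to landscape label.
    locus_names
        Labels for the loci, length ``n_loci``.
    individual_ids
        Optional individual labels; generated if omitted.
    """

    alleles: np.ndarray
    site_of: np.ndarray
    landscape_of: dict
    locus_names: list
    individual_ids: list = field(default=None)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_ind, n_loci, 2)")
        if np.any(self.alleles < 0):
            raise ValueError("allele sizes must be non-negative integers")
        self.site_of = np.asarray(self.site_of)
        if self.site_of.shape[0] != self.alleles.shape[0]:
            raise ValueError("site_of length must match number of individuals")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i:04d}" for i in range(self.n_individuals)]
        missing = set(self.site_of) - set(self.landscape_of)
        if missing:
            raise ValueError(f"sites without landscape assignment: {sorted(missing)}")
        for s in self.sites:
            if not np.any(self.site_of == s):
                raise ValueError(f"empty site {s!r}")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def sites(self) -> list:
        seen = dict.fromkeys(self.site_of.tolist())
        return list(seen)

    @property
    def landscapes(self) -> list:
        seen = dict.fromkeys(self.landscape_of[s] for s in self.sites)
        return list(seen)

    def sites_of_landscape(self, landscape) -> list:
        return [s for s in self.sites if self.landscape_of[s] == landscape]

    def site_mask(self, site) -> np.ndarray:
        return self.site_of == site

    def site_alleles(self, site, locus: int) -> np.ndarray:
        """Non-missing gene copies (flat array of allele sizes) at one locus."""
        a = self.alleles[self.site_mask(site), locus, :].ravel()
        return a[a != MISSING]

    def site_genotypes(self, site, locus: int) -> np.ndarray:
        """Genotype rows ``(n, 2)`` with both alleles called."""
        a = self.alleles[self.site_mask(site), locus, :]
        ok = np.all(a != MISSING, axis=1)
        return a[ok]

    def subset_sites(self, sites) -> "GenotypeDataset":
        sites = list(sites)
        mask = np.isin(self.site_of, sites)
        return GenotypeDataset(
            alleles=self.alleles[mask],
            site_of=self.site_of[mask],
            landscape_of={s: self.landscape_of[s] for s in sites},
            locus_names=list(self.locus_names),
            individual_ids=[i for i, m in zip(self.individual_ids, mask) if m],
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_individuals):
            site = self.site_of[i]
            for l, locus in enumerate(self.locus_names):
                rows.append(
                    (
                        self.individual_ids[i],
                        site,
                        self.landscape_of[site],
                        locus,
                        self.alleles[i, l, 0],
                        self.alleles[i, l, 1],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["individual", "site", "landscape", "locus", "allele1", "allele2"],
        )


#: measurement days (after germination) for repeated height/diameter records
MEASUREMENT_DAYS = (76, 116, 133, 145)

#: seed traits measured in the field (phenotypic differentiation only)
SEED_TRAITS = ("SLD", "STD", "SM")

#: trait set retained after correlation pruning in the reference design
DEFAULT_KEEP_TRAITS = ("SLD", "STD", "SM", "NL", "LW", "RL", "RDM", "ASL")


@dataclass
class ProgenyTrialTable:
    """Long-format progeny-trial data.

    ``data`` columns: landscape, site, family, individual, trait, value.
    Repeated height/diameter measurements use trait names ``H@<day>`` /
    ``D@<day>``; germination uses ``germinated`` (0/1) and ``TG`` (days,
    germinants only).
    """

    data: pd.DataFrame

    REQUIRED = ("landscape", "site", "family", "individual", "trait", "value")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        fam_sites = self.data.groupby("family")["site"].nunique()
        if (fam_sites > 1).any():
            bad = fam_sites[fam_sites > 1].index.tolist()
            raise ValueError(f"families spanning multiple sites: {bad}")

    @property
    def sites(self) -> list:
        return list(dict.fromkeys(self.data["site"]))

    @property
    def traits(self) -> list:
        return list(dict.fromkeys(self.data["trait"]))

    def landscape_of(self, site):
        sub = self.data.loc[self.data["site"] == site, "landscape"]
        return sub.iloc[0]

    def wide(self, traits=None) -> pd.DataFrame:
        """One row per individual, one column per trait."""
        df = self.data
        if traits is not None:
            df = df[df["trait"].isin(traits)]
        idx = ["landscape", "site", "family", "individual"]
        return df.pivot_table(index=idx, columns="trait", values="value",
                              aggfunc="mean").reset_index()

    def trait_frame(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        return sub.dropna(subset=["value"]).reset_index(drop=True)


@dataclass
class LandscapeScene:
    """A class-coded land-cover raster plus site coordinates.

    ``raster`` holds integer class codes; the geographic frame is the usual
    north-up grid (row 0 is the top edge), ``cell_size`` in meters, origin
    ``(xll, yll)`` at the lower-left corner.  ``class_table`` is a DataFrame
    with columns code, name, quality and optional comma-separated composite
    group labels; ``sites`` has columns site, x, y, landscape.
    """

    raster: np.ndarray
    cell_size: float
    class_table: pd.DataFrame
    sites: pd.DataFrame
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=np.int64)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        known = set(self.class_table["code"].astype(int))
        present = set(np.unique(self.raster).tolist())
        if not present <= known:
            raise ValueError(f"raster codes missing from class table: {sorted(present - known)}")

    @property
    def shape(self):
        return self.raster.shape

    def cell_centers(self):
        """(x, y) coordinate arrays of every cell center, same shape as raster."""
        nrow, ncol = self.raster.shape
        x = self.xll + (np.arange(ncol) + 0.5) * self.cell_size
        y = self.yll + (nrow - 1 - np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def quality_of(self, code: int) -> float:
        row = self.class_table.loc[self.class_table["code"] == code]
        if row.empty or row["quality"].isna().all():
            raise KeyError(f"no quality score for class code {code}")
        return float(row["quality"].iloc[0])

    def composite_members(self, group: str) -> list:
        out = []
        for _, row in self.class_table.iterrows():
            groups = str(row.get("groups", "") or "")
            if group in [g.strip() for g in groups.split(";") if g.strip()]:
                out.append(int(row["code"]))
        return out

    def site_xy(self, site) -> tuple:
        row = self.sites.loc[self.sites["site"] == site]
        if row.empty:
            raise KeyError(f"unknown site {site!r}")
        return float(row["x"].iloc[0]), float(row["y"].iloc[0])
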