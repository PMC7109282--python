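import numpy as np
import pandas as pd
import pytest

from landqgen.datatypes import GenotypeDataset, LandscapeScene, ProgenyTrialTable


def dataset_from_sites(site_genos, locus_names=None, landscape_of=None):
    """Build a GenotypeDataset from {site: array (n, L, 2)}."""
    sites = list(site_genos)
    arrays = [np.asarray(site_genos[s], dtype=np.int64) for s in sites]
    n_loci = arrays[0].shape[1]
    alleles = np.concatenate(arrays, axis=0)
    site_of = np.concatenate([[s] * a.shape[0] for s, a in zip(sites, arrays)])
    if landscape_of is None:
        landscape_of = {s: "L1" for s in sites}
    if locus_names is None:
        locus_names = [f"loc{i + 1}" for i in range(n_loci)]
    return GenotypeDataset(alleles=alleles, site_of=site_of,
                           landscape_of=landscape_of, locus_names=locus_names)


def random_dataset(rng, max_ind=20, n_sites=2, n_loci=2, n_alleles=4, step=2):
    """Small random ladder-allele dataset for oracle comparisons."""
    sizes = 100 + step * np.arange(n_alleles)
    site_genos = {}
    for s in range(n_sites):
        n = rng.integers(4, max_ind + 1)
        g = rng.choice(sizes, size=(n, n_loci, 2))
        site_genos[f"S{s + 1}"] = g
    return dataset_from_sites(site_genos)


def scene_from_raster(raster, cell_size=10.0, class_table=None, sites=None):
    raster = np.asarray(raster, dtype=np.int64)
    if class_table is None:
        codes = np.unique(raster)
        class_table = pd.DataFrame({
            "code": codes, "name": [f"c{c}" for c in codes],
            "quality": np.linspace(0.2, 1.0, codes.size),
            "groups": [""] * codes.size,
        })
    if sites is None:
        nrow, ncol = raster.shape
        sites = pd.DataFrame([{"site": "S1", "x": ncol * cell_size / 2,
                               "y": nrow * cell_size / 2, "landscape": "L1"}])
    return LandscapeScene(raster=raster, cell_size=cell_size,
                          class_table=class_table, sites=sites)


def progeny_from_values(values_by_site_family, trait="trait"):
    """Build a ProgenyTrialTable from {site: {family: [values]}}."""
    rows = []
    for site, fams in values_by_site_family.items():
        for fam, vals in fams.items():
            for i, v in enumerate(vals):
                rows.append(("L1", site, f"{site}{fam}", f"{site}{fam}o{i}",
                             trait, float(v)))
    return ProgenyTrialTable(pd.DataFrame(
        rows, columns=["landscape", "site", "family", "individual",
                       "trait", "value"]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
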