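"""File formats: GenePop, long genotype CSV, progeny CSV, ESRI ASCII grid.

All formats are plain text.  GenePop files use 2- or 3-digit allele codes
with ``pop``-delimited site blocks; rasters travel as ESRI ASCII grids
(6-line header + whitespace-separated integers) so no GIS stack is needed.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, LandscapeScene, ProgenyTrialTable, MISSING


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def write_genepop(dataset: GenotypeDataset, path, digits: int = 3, title: str = "landqgen export"):
    """Write a GenePop file; site labels are encoded in individual names."""
    if digits not in (2, 3):
        raise ValueError("GenePop allele codes are 2 or 3 digits")
    if dataset.alleles.max() >= 10 ** digits:
        raise ValueError(f"allele size too large for {digits}-digit codes")
    lines = [title]
    lines.extend(str(l) for l in dataset.locus_names)
    for site in dataset.sites:
        lines.append("pop")
        idx = np.flatnonzero(dataset.site_mask(site))
        for i in idx:
            geno = " ".join(
                f"{dataset.alleles[i, l, 0]:0{digits}d}{dataset.alleles[i, l, 1]:0{digits}d}"
                for l in range(dataset.n_loci)
            )
            lines.append(f"{site}_{dataset.individual_ids[i]} ,  {geno}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path, landscape_of=None) -> GenotypeDataset:
    """Read a GenePop file.

    Site labels are taken from the prefix before the last ``_`` in each
    individual name when present, else ``pop<k>``.  ``landscape_of`` maps
    site label to landscape; defaults to one landscape per site.
    """
    text = Path(path).read_text()
    lines = [l.rstrip() for l in text.splitlines() if l.strip()]
    if len(lines) < 3:
        raise ValueError("not a GenePop file: too short")
    body = lines[1:]
    # locus names: either one per line or a single comma-separated line
    loci = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if i == len(body):
        raise ValueError("no 'pop' delimiter found")
    rows, site_labels, ids = [], [], []
    pop_idx = 0
    for line in body[i:]:
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ValueError(f"malformed genotype line: {line!r}")
        name, geno = line.split(",", 1)
        name = name.strip()
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(f"{name}: expected {len(loci)} loci, got {len(codes)}")
        digits = len(codes[0]) // 2
        if any(len(c) != 2 * digits for c in codes):
            raise ValueError(f"{name}: inconsistent allele code width")
        pair_rows = [(int(c[:digits]), int(c[digits:])) for c in codes]
        rows.append(pair_rows)
        m = re.match(r"(.+)_([^_]+)$", name)
        site_labels.append(m.group(1) if m else f"pop{pop_idx}")
        ids.append(m.group(2) if m else name)
    alleles = np.array(rows, dtype=np.int64)
    site_of = np.array(site_labels)
    if landscape_of is None:
        landscape_of = {s: s for s in dict.fromkeys(site_labels)}
    return GenotypeDataset(alleles=alleles, site_of=site_of,
                           landscape_of=landscape_of, locus_names=loci,
                           individual_ids=ids)


# ---------------------------------------------------------------------------
# Long CSV genotype table
# ---------------------------------------------------------------------------

def write_genotypes_csv(dataset: GenotypeDataset, path):
    dataset.to_long_frame().to_csv(path, index=False)


def read_genotypes_csv(path) -> GenotypeDataset:
    df = pd.read_csv(path)
    need = {"individual", "site", "landscape", "locus", "allele1", "allele2"}
    if not need <= set(df.columns):
        raise ValueError(f"long genotype CSV must have columns {sorted(need)}")
    loci = list(dict.fromkeys(df["locus"]))
    inds = list(dict.fromkeys(df["individual"]))
    l_idx = {l: j for j, l in enumerate(loci)}
    i_idx = {ind: j for j, ind in enumerate(inds)}
    alleles = np.full((len(inds), len(loci), 2), MISSING, dtype=np.int64)
    site_of = np.empty(len(inds), dtype=object)
    landscape_of = {}
    for row in df.itertuples(index=False):
        i, l = i_idx[row.individual], l_idx[row.locus]
        alleles[i, l, 0] = row.allele1
        alleles[i, l, 1] = row.allele2
        site_of[i] = row.site
        landscape_of[row.site] = row.landscape
    return GenotypeDataset(alleles=alleles, site_of=np.array(site_of.tolist()),
                           landscape_of=landscape_of, locus_names=loci,
                           individual_ids=inds)


# ---------------------------------------------------------------------------
# Progeny trial CSV
# ---------------------------------------------------------------------------

def write_progeny_csv(table: ProgenyTrialTable, path):
    table.data.to_csv(path, index=False)


def read_progeny_csv(path) -> ProgenyTrialTable:
    return ProgenyTrialTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# ESRI ASCII grid + scene side tables
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: np.ndarray, cell_size: float, path,
                     xll: float = 0.0, yll: float = 0.0, nodata: int = -9999):
    r = np.asarray(raster)
    header = (
        f"ncols {r.shape[1]}\n"
        f"nrows {r.shape[0]}\n"
        f"xllcorner {xll}\n"
        f"yllcorner {yll}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, r, fmt="%d")


def read_ascii_grid(path):
    """Return ``(raster, cell_size, xll, yll)`` from an ESRI ASCII grid."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            parts = fh.readline().split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    raster = np.asarray(data, dtype=np.int64).reshape(nrows, ncols)
    return (raster, header["cellsize"],
            header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_scene(scene: LandscapeScene, grid_path, sites_path, classes_path):
    write_ascii_grid(scene.raster, scene.cell_size, grid_path,
                     xll=scene.xll, yll=scene.yll)
    scene.sites.to_csv(sites_path, index=False)
    scene.class_table.to_csv(classes_path, index=False)


def read_scene(grid_path, sites_path, classes_path) -> LandscapeScene:
    raster, cell_size, xll, yll = read_ascii_grid(grid_path)
    sites = pd.read_csv(sites_path)
    classes = pd.read_csv(classes_path)
    return LandscapeScene(raster=raster, cell_size=cell_size,
                          class_table=classes, sites=sites, xll=xll, yll=yll)
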