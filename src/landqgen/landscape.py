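"""Raster landscape metrics at node (site) and link (site-pair) levels.

All geometry is raster-only: a buffer is the set of cells whose centers lie
within the radius of the focal point, so discretization error shrinks with
cell size (the connectivity tests verify convergence to closed-form areas).
Node buffers default to 0.5 km around each site; link buffers to 2/4/6 km
around the midpoint of a site pair.  Metrics: per-class percentage (with
composite class groups), multi-scale donut subtraction, Shannon
heterogeneity (SHDI), buffer matrix quality (BMQ = sum P_i Q_i / sum P_i),
and functional connectivity (habitat patches dilated by a pollinator
foraging radius, area in hectares).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import LandscapeScene

__all__ = [
    "BufferSpec",
    "buffer_mask",
    "class_percentages",
    "donut_metric",
    "shannon_heterogeneity",
    "buffer_matrix_quality",
    "functional_connectivity",
    "scale_of_effect_screen",
    "node_metrics",
    "link_metrics",
]

NODE_RADIUS = 500.0
LINK_RADII = (2000.0, 4000.0, 6000.0)


@dataclass
class BufferSpec:
    """A circular analysis window around a site or a pair midpoint."""
    center: tuple
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("buffer radius must be positive")

    @classmethod
    def node(cls, scene: LandscapeScene, site, radius: float = NODE_RADIUS):
        return cls(center=scene.site_xy(site), radius=radius)

    @classmethod
    def link(cls, scene: LandscapeScene, site_a, site_b, radius: float):
        xa, ya = scene.site_xy(site_a)
        xb, yb = scene.site_xy(site_b)
        return cls(center=((xa + xb) / 2.0, (ya + yb) / 2.0), radius=radius)


def buffer_mask(scene: LandscapeScene, buf: BufferSpec) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the buffer."""
    X, Y = scene.cell_centers()
    cx, cy = buf.center
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= buf.radius ** 2
    if not mask.any():
        raise ValueError("buffer does not intersect the raster")
    return mask


def class_percentages(scene: LandscapeScene, buf: BufferSpec,
                      composites: dict = None) -> dict:
    """Percentage of buffer cells per class code; composite groups are the
    sums of their members' percentages (keys are the group names)."""
    mask = buffer_mask(scene, buf)
    vals = scene.raster[mask]
    total = vals.size
    codes, counts = np.unique(vals, return_counts=True)
    pct = {int(c): 100.0 * n / total for c, n in zip(codes, counts)}
    out = dict(pct)
    if composites:
        for name, members in composites.items():
            out[name] = sum(pct.get(int(m), 0.0) for m in members)
    return out


def donut_metric(scene: LandscapeScene, center, r_inner: float, r_outer: float,
                 class_set) -> float:
    """pct(class_set, r_outer) - pct(class_set, r_inner).

    This is the multi-scale decorrelation subtraction; it can be negative
    when the class is concentrated inside the inner radius.
    """
    if r_outer <= r_inner:
        raise ValueError("r_outer must exceed r_inner")
    outer = class_percentages(scene, BufferSpec(center, r_outer))
    inner = class_percentages(scene, BufferSpec(center, r_inner))
    cs = [int(c) for c in np.atleast_1d(class_set)]
    return (sum(outer.get(c, 0.0) for c in cs)
            - sum(inner.get(c, 0.0) for c in cs))


def shannon_heterogeneity(scene: LandscapeScene, buf: BufferSpec) -> float:
    """SHDI = -sum p_i ln p_i over classes present in the buffer."""
    mask = buffer_mask(scene, buf)
    vals = scene.raster[mask]
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def buffer_matrix_quality(scene: LandscapeScene, buf: BufferSpec) -> float:
    """Area-weighted mean class quality: BMQ = sum P_i Q_i / sum P_i."""
    pct = class_percentages(scene, buf)
    num = den = 0.0
    for code, p in pct.items():
        q = scene.quality_of(int(code))
        num += p * q
        den += p
    return num / den


def functional_connectivity(scene: LandscapeScene, buf: BufferSpec,
                            habitat_classes, link_radius: float = 500.0,
                            variant: str = "dilated_union"):
    """Habitat area functionally linked by a dispersal radius, in hectares.

    The habitat cells inside the buffer are labeled into 8-neighbor
    patches, then dilated by ``link_radius`` (Euclidean distance
    transform).  ``dilated_union`` (default) returns the area of the
    dilated union - patch area plus everything the dispersal buffers
    reach.  ``patches_plus_corridors`` instead adds to the raw patch area
    only the dilated zone shared by two or more patches (the corridors).
    Also returns the number of connected components after dilation.
    """
    if scene.cell_size > link_radius / 5.0:
        warnings.warn("cell size is coarse relative to link_radius; "
                      "dilated areas may be inaccurate")
    mask = buffer_mask(scene, buf)
    cs = {int(c) for c in np.atleast_1d(habitat_classes)}
    habitat = np.isin(scene.raster, list(cs)) & mask
    if not habitat.any():
        return 0.0, 0
    structure = np.ones((3, 3), dtype=bool)  # 8-neighbor connectivity
    labels, n_patches = ndimage.label(habitat, structure=structure)
    dist = ndimage.distance_transform_edt(~habitat, sampling=scene.cell_size)
    dilated = dist <= link_radius
    _, n_components = ndimage.label(dilated, structure=structure)
    cell_area = scene.cell_size ** 2
    if variant == "dilated_union":
        area_m2 = float(dilated.sum()) * cell_area
    elif variant == "patches_plus_corridors":
        # nearest-patch partition of the dilated halo; corridor cells are
        # those within link_radius of >= 2 distinct patches
        corridors = _corridor_mask(habitat, labels, n_patches, dilated,
                                   scene.cell_size, link_radius)
        area_m2 = (float(habitat.sum()) + float(corridors.sum())) * cell_area
    else:
        raise ValueError(f"unknown connectivity variant {variant!r}")
    return area_m2 / 1e4, int(n_components)


def _corridor_mask(habitat, labels, n_patches, dilated, cell_size, link_radius):
    halo = dilated & ~habitat
    if n_patches < 2 or not halo.any():
        return np.zeros_like(habitat)
    reached = np.zeros(habitat.shape, dtype=np.int16)
    for pid in range(1, n_patches + 1):
        dist = ndimage.distance_transform_edt(labels != pid, sampling=cell_size)
        reached += (dist <= link_radius)
    return (reached >= 2) & halo


def scale_of_effect_screen(metrics: pd.DataFrame, scale_col: str = "radius",
                           value_cols=None, id_cols=("landscape",),
                           r_scale_threshold: float = 0.90,
                           r_cross_threshold: float = 0.5,
                           keep=()) -> list:
    """Two-stage Pearson screen over link-level metric tables.

    Stage 1 (scale of effect): for each metric, when all inter-scale
    correlations exceed ``r_scale_threshold`` only the smallest scale is
    kept, otherwise every scale survives as a separate metric named
    ``metric@radius``.  Stage 2: greedy cross-metric pruning at
    |r| > ``r_cross_threshold`` (most offending partners dropped first,
    ties by larger mean |r|); ``keep`` names are never dropped.
    Returns the retained metric names.
    """
    if value_cols is None:
        value_cols = [c for c in metrics.columns
                      if c not in (scale_col, *id_cols)]
    wide = metrics.pivot_table(index=list(id_cols), columns=scale_col,
                               values=list(value_cols))
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 observations per metric")
    survivors = {}
    for metric in value_cols:
        sub = wide[metric]
        radii = sorted(sub.columns)
        if sub[radii[0]].nunique() <= 1:
            warnings.warn(f"constant metric {metric!r} flagged")
        corr = sub.corr().abs()
        offdiag = corr.values[np.triu_indices(len(radii), 1)]
        if len(radii) == 1 or (offdiag > r_scale_threshold).all():
            survivors[metric] = sub[radii[0]]
        else:
            for r in radii:
                survivors[f"{metric}@{int(r)}"] = sub[r]
    surv = pd.DataFrame(survivors)
    active = list(surv.columns)
    keep = set(keep)
    while True:
        corr = surv[active].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        over = corr > r_cross_threshold
        counts = over.sum(axis=1)
        droppable = [m for m in active if m not in keep and counts[m] > 0]
        if not droppable:
            break
        worst = max(droppable,
                    key=lambda m: (counts[m], corr.loc[m, over.loc[m]].mean()))
        active.remove(worst)
    return active


# ---------------------------------------------------------------------------
# tidy per-site / per-pair tables
# ---------------------------------------------------------------------------

def node_metrics(scene: LandscapeScene, habitat_classes, radius: float = NODE_RADIUS,
                 composites: dict = None, link_radius: float = 500.0,
                 shared_protected: dict = None) -> pd.DataFrame:
    """One row per site: habitat %, SHDI, BMQ, functional connectivity.

    ``shared_protected`` maps a site to a partner site whose buffer values
    it shares (sites inside the same protected area use identical node
    metrics)."""
    rows = []
    cache = {}
    for _, srow in scene.sites.iterrows():
        site = srow["site"]
        key = site
        if shared_protected and site in shared_protected:
            key = shared_protected[site]
        if key not in cache:
            buf = BufferSpec.node(scene, key, radius)
            pct = class_percentages(scene, buf, composites)
            habitat_pct = sum(pct.get(int(c), 0.0)
                              for c in np.atleast_1d(habitat_classes))
            conn, _ = functional_connectivity(scene, buf, habitat_classes,
                                              link_radius)
            cache[key] = dict(
                habitat_pct=habitat_pct,
                shdi=shannon_heterogeneity(scene, buf),
                bmq=buffer_matrix_quality(scene, buf),
                connectivity_ha=conn,
            )
        rows.append({"site": site, "landscape": srow["landscape"],
                     "radius": radius, **cache[key]})
    return pd.DataFrame(rows)


def link_metrics(scene: LandscapeScene, habitat_classes,
                 radii=LINK_RADII, composites: dict = None,
                 link_radius: float = 500.0) -> pd.DataFrame:
    """One row per within-landscape site pair and scale radius."""
    rows = []
    sites = scene.sites
    for lsc, grp in sites.groupby("landscape", sort=False):
        slist = grp["site"].tolist()
        for i in range(len(slist)):
            for j in range(i + 1, len(slist)):
                a, b = slist[i], slist[j]
                for r in radii:
                    buf = BufferSpec.link(scene, a, b, r)
                    pct = class_percentages(scene, buf, composites)
                    habitat_pct = sum(pct.get(int(c), 0.0)
                                      for c in np.atleast_1d(habitat_classes))
                    conn, _ = functional_connectivity(scene, buf, habitat_classes,
                                                      link_radius)
                    row = {
                        "landscape": lsc, "site_a": a, "site_b": b, "radius": r,
                        "habitat_pct": habitat_pct,
                        "shdi": shannon_heterogeneity(scene, buf),
                        "bmq": buffer_matrix_quality(scene, buf),
                        "connectivity_ha": conn,
                    }
                    if composites:
                        for name in composites:
                            row[name] = pct[name]
                    rows.append(row)
    df = pd.DataFrame(rows)
    # donut subtractions between successive scales, e.g. habitat_pct@4-2
    radii = sorted(radii)
    extra = []
    for (lsc, a, b), grp in df.groupby(["landscape", "site_a", "site_b"], sort=False):
        grp = grp.set_index("radius")
        for r_in, r_out in zip(radii[:-1], radii[1:]):
            extra.append({
                "landscape": lsc, "site_a": a, "site_b": b,
                "metric": f"habitat_pct@{int(r_out / 1000)}_{int(r_in / 1000)}km",
                "value": grp.loc[r_out, "habitat_pct"] - grp.loc[r_in, "habitat_pct"],
            })
    donuts = pd.DataFrame(extra)
    return df, donuts
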