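#!/usr/bin/env python
"""Mixed-mating quantitative genetics from the progeny trial.

Reads the progeny CSV from 01 and the per-site inbreeding estimates from
02, expands the repeated height/diameter series into growth traits,
prunes traits at |r| > 0.5, and fits the REML family model per site and
trait: Va = sigma2_fam/(2 theta) with theta from the site's neutral-locus
f, CVa% and h2, then Q_ST (seedling traits) and P_ST (seed traits) per
within-landscape site pair.  Writes tidy CSVs under results/tables/.
"""

import argparse
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from landqgen import io, quantgen
from landqgen.datatypes import SEED_TRAITS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--tables", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    table = quantgen.derive_growth_traits(
        io.read_progeny_csv(args.inputs / "progeny.csv"))
    div = pd.read_csv(args.tables / "site_diversity.csv")
    f_of_site = dict(zip(div["site"], div["f"]))

    tg, pg = quantgen.germination_summaries(table)
    pg.to_csv(args.tables / "germination.csv", index=False)
    print(f"germination: PG {pg['PG'].min():.2f}-{pg['PG'].max():.2f} "
          f"over {len(pg)} families")

    wide = table.wide()
    measurable = [c for c in wide.columns
                  if c not in ("landscape", "site", "family", "individual",
                               "germinated")]
    retained = quantgen.prune_correlated_traits(wide, traits=measurable)
    print(f"traits retained after |r|>0.5 pruning: {sorted(retained)}")
    seedling = [t for t in retained if t in ("NL", "LW", "RL", "RDM", "ASL")]

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for site in table.sites:
            f = max(f_of_site.get(site, 0.0), 0.0)
            for trait in seedling:
                vd = quantgen.fit_family_model(table, trait, f=f, site=site)
                rows.append({"site": site,
                             "landscape": table.landscape_of(site),
                             "trait": trait, "Va": vd.Va,
                             "CVa_pct": vd.CVa_pct, "h2": vd.h2,
                             "h2_raw": vd.h2_raw, "h2_capped": vd.h2_capped,
                             "mean": vd.trait_mean, "f_used": f})
    dec = pd.DataFrame(rows)
    dec.to_csv(args.tables / "variance_decomposition.csv", index=False)
    print(f"Va range {dec['Va'].min():.4f}-{dec['Va'].max():.4f}; "
          f"{int(dec['h2_capped'].sum())} fits with h2 > 1 (capped)")

    rows = []
    for lsc, a, b in quantgen.site_pairs_within_landscapes(table):
        f_pair = max(np.mean([f_of_site.get(a, 0.0), f_of_site.get(b, 0.0)]), 0.0)
        for trait in seedling:
            try:
                v = quantgen.qst(table, trait, f=f_pair, sites=[a, b])
            except ValueError:
                v = np.nan
            rows.append({"landscape": lsc, "site_a": a, "site_b": b,
                         "trait": trait, "statistic": "Qst", "value": v})
        for trait in SEED_TRAITS:
            rows.append({"landscape": lsc, "site_a": a, "site_b": b,
                         "trait": trait, "statistic": "Pst",
                         "value": quantgen.pst(table, trait, sites=[a, b])})
    qp = pd.DataFrame(rows)
    qp.to_csv(args.tables / "qst_pst.csv", index=False)
    qv = qp[qp["statistic"] == "Qst"]["value"].dropna()
    pv = qp[qp["statistic"] == "Pst"]["value"].dropna()
    print(f"Q_ST {qv.min():.3f}-{qv.max():.3f}; P_ST {pv.min():.4f}-{pv.max():.4f}")


if __name__ == "__main__":
    main()
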