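#!/usr/bin/env python
"""Link landscape structure to genetic responses by AICc and significance.

Node level (n = 10 sites): each response (He, AR, f, trait means, CVa%)
is confronted with habitat amount, compositional heterogeneity and Ne;
candidates are ranked by AICc with Akaike weights.  Link level (n = 5
landscapes): slope significance of each differentiation statistic on
log10 habitat amount at the 2 km scale.  Writes the ranking tables and
response-vs-predictor figures under results/.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from landqgen import modelsel


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--tables", type=Path, default=Path("results/tables"))
    ap.add_argument("--figdir", type=Path, default=Path("results/figures"))
    args = ap.parse_args()
    args.figdir.mkdir(parents=True, exist_ok=True)

    div = pd.read_csv(args.tables / "site_diversity.csv").set_index("site")
    node = pd.read_csv(args.tables / "node_metrics.csv").set_index("site")
    dec = pd.read_csv(args.tables / "variance_decomposition.csv")
    sites = [s for s in div.index if s in node.index]

    predictors = pd.DataFrame({
        "habitat_amount": node.loc[sites, "habitat_pct"],
        "compositional_heterogeneity": node.loc[sites, "shdi"],
        "Ne": div.loc[sites, "Ne"],
    })
    responses = {"He": div.loc[sites, "He"], "AR": div.loc[sites, "AR"],
                 "f": div.loc[sites, "f"]}
    for trait, grp in dec.groupby("trait"):
        grp = grp.set_index("site")
        responses[f"mean_{trait}"] = grp.reindex(sites)["mean"]
        responses[f"CVa_{trait}"] = grp.reindex(sites)["CVa_pct"]
    rankings = modelsel.node_level_selection(pd.DataFrame(responses), predictors)
    combined = pd.concat([df.assign(response=r) for r, df in rankings.items()],
                         ignore_index=True)
    combined.to_csv(args.tables / "node_rankings.csv", index=False)
    print("best node-level model per response:")
    for resp, df in rankings.items():
        best = df.iloc[0]
        print(f"  {resp:12s} {best['model']:28s} wAICc={best['wAICc']:.2f} "
              f"p={best['p']:.3f}{best['signif']}")

    link = pd.read_csv(args.tables / "link_metrics.csv")
    diff = pd.read_csv(args.tables / "pair_differentiation.csv")
    qp = pd.read_csv(args.tables / "qst_pst.csv")
    hab2 = (link[link["radius"] == link["radius"].min()]
            .groupby("landscape")["habitat_pct"].mean())
    diff_l = diff.groupby("landscape").mean(numeric_only=True)
    lscapes = [l for l in hab2.index if l in diff_l.index]
    link_resp = diff_l.loc[lscapes, ["Fst", "GstPrime", "JostD", "Fis"]].copy()
    for (stat, trait), grp in qp.groupby(["statistic", "trait"]):
        link_resp[f"{stat}_{trait}"] = (grp.groupby("landscape")["value"]
                                        .mean().reindex(lscapes))
    fits = modelsel.link_level_selection(link_resp, hab2.loc[lscapes],
                                         log10_x=True)
    fits.to_csv(args.tables / "link_fits.csv", index=False)
    print("link-level slopes on log10 habitat amount (2 km):")
    for _, row in fits.iterrows():
        print(f"  {row['response']:10s} beta={row['beta']: .3f} "
              f"p={row['p']:.3f}{row['signif']}")

    for resp, ylab in (("He", "Expected heterozygosity"),
                       ("AR", "Allelic richness")):
        _fig(node.loc[sites, "habitat_pct"], div.loc[sites, resp],
             "Habitat amount (%)", ylab, args.figdir / f"node_{resp}.png")
    _fig(np.log10(hab2.loc[lscapes]), diff_l.loc[lscapes, "Fst"],
         "log10 habitat amount at 2 km (%)", "F_ST",
         args.figdir / "link_Fst.png")


def _fig(x, y, xlabel, ylabel, path):
    x, y = np.asarray(x, float), np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, color="black", s=25)
    if np.ptp(x) > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, color="black")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    main()
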