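#!/usr/bin/env python
"""Generate the reference-design synthetic inputs.

Five 6x6 km landscapes spanning a habitat-amount gradient, two savanna
sites each: 60 genotyped adults/site at 10 microsatellite loci
(divergence 0.05, inbreeding 0.15), balanced open-pollinated seed
families (15 x 7 per site) with the full multi-trait nursery protocol,
and an 11-class land-cover raster per landscape.  Writes GenePop + CSV
genotypes, the progeny CSV and ASCII-grid scenes under results/inputs/.
"""

import argparse
from pathlib import Path

from landqgen import io
from landqgen.presets import paper_like_config, simulate_design_traits
from landqgen.simulate import simulate_genotypes, simulate_scene


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    config = paper_like_config(args.seed)
    config.to_yaml(out / "config.yaml")

    genotypes = simulate_genotypes(config.genotype_spec())
    io.write_genepop(genotypes, out / "genotypes.gen")
    io.write_genotypes_csv(genotypes, out / "genotypes.csv")
    print(f"genotypes: {genotypes.n_individuals} individuals, "
          f"{genotypes.n_loci} loci, {len(genotypes.sites)} sites")

    traits = simulate_design_traits(config)
    io.write_progeny_csv(traits, out / "progeny.csv")
    n_ind = traits.data["individual"].nunique()
    print(f"progeny trial: {n_ind} individuals, {len(traits.traits)} trait columns")

    for spec in config.scene_specs():
        scene = simulate_scene(spec)
        io.write_scene(scene, out / f"scene_{spec.landscape_id}.asc",
                       out / f"sites_{spec.landscape_id}.csv",
                       out / "classes.csv")
        pct = 100.0 * (scene.raster == spec.habitat_class_id).mean()
        print(f"scene {spec.landscape_id}: habitat {pct:.1f}% "
              f"(target {spec.target_habitat_pct}%)")


if __name__ == "__main__":
    main()
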