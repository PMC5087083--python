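#!/usr/bin/env python
"""Intersect called candidate regions with the simulated gene models and run
a demonstration over-representation test (genes inside planted sweeps as the
gene set). Writes results/annotate/{region_genes_*.tsv, enrichment.tsv}.
"""

from pathlib import Path

import pandas as pd

from sweepscan.annotate import GeneSetMap, enrich, read_annotation, regions_to_genes

SIM = Path("results/sim")
SCAN = Path("results/scan")
OUT = Path("results/annotate")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = read_annotation(SIM / "genes.bed")
    truth = pd.read_csv(SIM / "truth.bed", sep="\t", header=None,
                        names=["chrom", "start", "end", "target_pop", "dr", "f"])
    _, swept_genes = regions_to_genes(truth, genes)
    genesets = GeneSetMap({"SWEPT": ("genes inside planted sweeps",
                                     frozenset(swept_genes))})

    for key in ("joint_popA", "joint_popB", "zfst"):
        regions = pd.read_csv(SCAN / f"regions_{key}.tsv", sep="\t")
        per_region, union = regions_to_genes(regions, genes)
        per_region.to_csv(OUT / f"region_genes_{key}.tsv", sep="\t", index=False)
        print(f"{key}: {len(union)} candidate genes in {len(regions)} regions")
        if key == "joint_popA":
            all_joint = union

    union_both = set(all_joint)
    for key in ("joint_popB",):
        regions = pd.read_csv(SCAN / f"regions_{key}.tsv", sep="\t")
        _, u = regions_to_genes(regions, genes)
        union_both |= set(u)
    table = enrich(union_both, set(genes["gene_id"]), genesets)
    table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    row = table.iloc[0]
    print(f"enrichment of planted-sweep genes among joint candidates: "
          f"{row['n_overlap']}/{row['n_background']} overlap, p = {row['p']:.3g}")


if __name__ == "__main__":
    main()
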