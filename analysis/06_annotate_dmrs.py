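#!/usr/bin/env python
"""Annotate called DMRs with genomic context.

Builds promoters (-1000/+500 around the TSS), gene bodies, exons/introns,
3' ends (+/-1000 around the TES), and the CpG island/shore/shelf partition
(2 kb flanks); flags >= 1 bp overlaps per category and computes signed
distances to the nearest TSS.
"""

import json

import pandas as pd

from methylome import io as mio
from methylome.annotation import (
    annotate_regions,
    build_features,
    category_percentages,
    tss_distance_table,
)
from methylome.intervals import GenomicInterval

genes = mio.read_gene_models("results/sim/gene_models.tsv")
islands = mio.read_bed("results/sim/cpg_islands.bed")
features = build_features(genes, islands)

dmrs: list[GenomicInterval] = []
directions: list[str] = []
for direction in ("hypo", "hyper"):
    table = pd.read_csv(f"results/dmrs.{direction}.tsv", sep="\t")
    for row in table.itertuples(index=False):
        dmrs.append(GenomicInterval(row.chrom, row.start, row.end, ".",
                                    f"{direction}_{len(dmrs)}"))
        directions.append(direction)

annot = annotate_regions(dmrs, features)
annot["direction"] = directions
annot.to_csv("results/dmr_annotation.tsv", sep="\t", index=False)
dist = tss_distance_table(dmrs, features)
dist["direction"] = directions
dist.to_csv("results/dmr_tss_distance.tsv", sep="\t", index=False)

pct = {
    direction: category_percentages(annot.loc[annot["direction"] == direction])
    for direction in ("hypo", "hyper")
}
with open("results/dmr_category_percentages.json", "w") as fh:
    json.dump(pct, fh, indent=2)

for direction in ("hypo", "hyper"):
    row = pct[direction]
    print(f"{direction}: " + ", ".join(
        f"{c} {row[c]:.0f}%" for c in ("promoter", "exon", "intron",
                                       "three_prime", "intergenic", "gene_body")
    ))
print("outputs -> results/dmr_annotation.tsv, dmr_tss_distance.tsv, "
      "dmr_category_percentages.json")
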