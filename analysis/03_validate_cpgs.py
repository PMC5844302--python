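#!/usr/bin/env python
"""Genomic-context validation of reference CpG sites.

Combines the strand-split pileups of all six libraries and applies the
four G-evidence criteria (>= 95% G and >= 5 G reads on each strand's
guanine coordinate). Planted CpG-destroying polymorphisms must fail.
"""

from pathlib import Path

import pandas as pd

from methylome import io as mio
from methylome.intervals import GenomicInterval
from methylome.validation import passed_sites, validate_cpg_sites, validation_table

pileup_files = sorted(Path("results/sim").glob("*_rep*.pileup.tsv"))
combined = (
    pd.concat([mio.read_pileup(p) for p in pileup_files], ignore_index=True)
    .groupby(["chrom", "pos", "strand"], as_index=False)[
        ["nA", "nC", "nG", "nT", "nMeth", "nUnmeth"]].sum()
)

ref_cpgs: dict[str, list[int]] = {}
for iv in mio.read_bed("results/sim/reference_cpgs.bed"):
    ref_cpgs.setdefault(iv.chrom, []).append(iv.start)

results = validate_cpg_sites(combined, ref_cpgs)
validation_table(results).to_csv("results/validation.tsv", sep="\t", index=False)
ok = passed_sites(results)
mio.write_bed(
    [GenomicInterval(c, p, p + 2) for c, p in sorted(ok)],
    "results/validated_cpgs.bed", bed6=False,
)

snps = {(iv.chrom, iv.start) for iv in mio.read_bed("results/sim/truth_snp_sites.bed")}
print(f"combined pileup over {len(pileup_files)} libraries")
print(f"validated: {len(ok)}/{len(results)} CpGs "
      f"({100 * len(ok) / len(results):.1f}%)")
print(f"planted polymorphic sites rejected: {len(snps - ok)}/{len(snps)}")
print("outputs -> results/validation.tsv, results/validated_cpgs.bed")
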