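"""Feature construction and DMR annotation.

Feature windows (all 0-based half-open, clipped to chromosome bounds):

* promoter: 1000 bp upstream through 500 bp downstream of the TSS,
  strand-mirrored — plus-strand TSS ``t`` gives ``[t-1000, t+500)``,
  minus-strand ``[t-499, t+1001)``;
* gene body: TSS through TES;
* introns: gene body minus exons, per gene;
* 3' end: 1000 bp on each side of the TES, strand-mirrored;
* CpG island shores: up to 2 kb flanking each island edge, minus islands;
* shelves: the next 2 kb beyond the shores, minus shores and islands.

Annotation flags are non-exclusive >= 1 bp overlaps per category;
``intergenic`` means no promoter/exon/intron/3'-end overlap. TSS distance
is edge-to-point against the nearest single TSS, signed positive when the
region lies downstream in the TSS's strand orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    clip_to_chrom,
    merge_intervals,
    overlaps_any,
    subtract_intervals,
)

GENE_MODEL_CATEGORIES = ("promoter", "exon", "intron", "three_prime", "intergenic")
ISLAND_CATEGORIES = ("island", "shore", "shelf")
DEFAULT_BIN_EDGES = (5_000, 50_000, 500_000)


@dataclass
class TssPoint:
    chrom: str
    pos: int
    strand: str
    gene_id: str


@dataclass
class FeatureSet:
    promoters: list = field(default_factory=list)
    gene_bodies: list = field(default_factory=list)
    exons: list = field(default_factory=list)
    introns: list = field(default_factory=list)
    three_prime_ends: list = field(default_factory=list)
    cpg_islands: list = field(default_factory=list)
    cpg_shores: list = field(default_factory=list)
    cpg_shelves: list = field(default_factory=list)
    tss_points: list = field(default_factory=list)

    def category(self, name: str) -> list:
        return {
            "promoter": self.promoters,
            "gene_body": self.gene_bodies,
            "exon": self.exons,
            "intron": self.introns,
            "three_prime": self.three_prime_ends,
            "island": self.cpg_islands,
            "shore": self.cpg_shores,
            "shelf": self.cpg_shelves,
        }[name]


def _strand_window(chrom: str, point: int, strand: str, up: int, down: int
                   ) -> GenomicInterval:
    """Window of ``up`` bases upstream and ``down`` bases (including the
    anchor base) downstream of a strand-oriented point."""
    if strand == "+":
        return GenomicInterval(chrom, max(0, point - up), point + down)
    return GenomicInterval(chrom, max(0, point - down + 1), point + up + 1)


def build_features(
    gene_models: list[GeneModel],
    cpg_islands: list[GenomicInterval],
    chrom_lengths: dict | None = None,
    promoter_up: int = 1_000,
    promoter_down: int = 500,
    three_prime_flank: int = 1_000,
    shore_width: int = 2_000,
    shelf_width: int = 2_000,
) -> FeatureSet:
    """Derive the full feature set from gene models and CpG islands."""
    chrom_lengths = chrom_lengths or {}

    def clipped(ivs):
        out = []
        for iv in ivs:
            iv = GenomicInterval(iv.chrom, max(0, iv.start), iv.end, iv.strand, iv.name)
            c = clip_to_chrom(iv, chrom_lengths)
            if c is not None:
                out.append(c)
        return out

    promoters, bodies, exons, introns, tprime, tss_points = [], [], [], [], [], []
    for g in gene_models:
        promoters.append(
            _strand_window(g.chrom, g.tss, g.strand, promoter_up, promoter_down)
        )
        tprime.append(
            _strand_window(g.chrom, g.tes, g.strand, three_prime_flank,
                           three_prime_flank)
        )
        body = g.body_interval()
        bodies.append(body)
        exons.extend(g.exons)
        introns.extend(subtract_intervals([body], list(g.exons)))
        tss_points.append(TssPoint(g.chrom, g.tss, g.strand, g.gene_id))

    islands = merge_intervals(cpg_islands)
    shore_cand = [
        GenomicInterval(iv.chrom, max(0, iv.start - shore_width), iv.end + shore_width)
        for iv in islands
    ]
    shores = subtract_intervals(shore_cand, islands)
    shelf_cand = [
        GenomicInterval(
            iv.chrom,
            max(0, iv.start - shore_width - shelf_width),
            iv.end + shore_width + shelf_width,
        )
        for iv in islands
    ]
    shelves = subtract_intervals(shelf_cand, islands + shores)

    return FeatureSet(
        promoters=clipped(promoters),
        gene_bodies=clipped(bodies),
        exons=clipped(exons),
        introns=clipped(introns),
        three_prime_ends=clipped(tprime),
        cpg_islands=clipped(islands),
        cpg_shores=clipped(shores),
        cpg_shelves=clipped(shelves),
        tss_points=tss_points,
    )


def annotate_regions(
    regions: list[GenomicInterval], features: FeatureSet
) -> pd.DataFrame:
    """Non-exclusive overlap flags per region and category.

    ``intergenic`` is derived: no overlap with promoter, exon, intron, or
    3'-end. Regions on chromosomes absent from the feature set simply get
    all-false gene-model flags (counted as intergenic).
    """
    cats = ("promoter", "exon", "intron", "three_prime", "island", "shore", "shelf")
    rows = []
    for i, region in enumerate(regions):
        flags = {c: overlaps_any(region, features.category(c)) for c in cats}
        flags["gene_body"] = overlaps_any(region, features.gene_bodies)
        flags["intergenic"] = not (
            flags["promoter"] or flags["exon"] or flags["intron"]
            or flags["three_prime"]
        )
        rows.append({
            "region_id": region.name or f"region{i:05d}",
            "chrom": region.chrom, "start": region.start, "end": region.end,
            **flags,
        })
    return pd.DataFrame(rows)


def category_percentages(annotations: pd.DataFrame) -> dict:
    """Percent of regions overlapping each category (non-exclusive)."""
    cats = GENE_MODEL_CATEGORIES + ISLAND_CATEGORIES + ("gene_body",)
    n = len(annotations)
    if n == 0:
        return {c: float("nan") for c in cats}
    return {c: 100.0 * float(annotations[c].mean()) for c in cats}


def tss_distance(
    region: GenomicInterval, tss_points: list[TssPoint],
    bin_edges: tuple = DEFAULT_BIN_EDGES,
) -> tuple[int, str]:
    """Signed distance to the nearest single TSS, with a bin label.

    Zero when the region contains the TSS; otherwise the gap between the
    nearest region edge and the TSS, positive when the region lies
    downstream of the TSS in the TSS's own strand orientation. The nearest
    TSS is chosen by absolute distance, ties broken toward a downstream
    placement and then toward the lower TSS coordinate.
    """
    same_chrom = [t for t in tss_points if t.chrom == region.chrom]
    if not same_chrom:
        raise ValueError(f"no TSS on chromosome {region.chrom}")

    def signed(t: TssPoint) -> int:
        if region.start <= t.pos < region.end:
            return 0
        if region.start > t.pos:          # region right of the TSS
            gap = region.start - t.pos
            return gap if t.strand == "+" else -gap
        gap = t.pos - (region.end - 1)    # region left of the TSS
        return -gap if t.strand == "+" else gap

    dists = [(abs(signed(t)), -np.sign(signed(t)), t.pos, signed(t)) for t in same_chrom]
    dists.sort(key=lambda x: (x[0], x[1], x[2]))
    d = int(dists[0][3])
    return d, distance_bin(d, bin_edges)


def distance_bin(d: int, bin_edges: tuple = DEFAULT_BIN_EDGES) -> str:
    """Label for a signed TSS distance; 0 falls in the first downstream bin."""
    side = "downstream" if d >= 0 else "upstream"
    mag = abs(d)
    prev = 0
    for edge in bin_edges:
        if mag <= edge:
            return f"{_kb(prev)}-{_kb(edge)}kb_{side}"
        prev = edge
    return f">{_kb(bin_edges[-1])}kb_{side}"


def _kb(bp: int) -> str:
    return f"{bp // 1000}"


def tss_distance_table(
    regions: list[GenomicInterval], features: FeatureSet,
    bin_edges: tuple = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    rows = []
    for i, region in enumerate(regions):
        d, label = tss_distance(region, features.tss_points, bin_edges)
        rows.append({
            "region_id": region.name or f"region{i:05d}",
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "tss_distance": d, "tss_bin": label,
        })
    return pd.DataFrame(rows)
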