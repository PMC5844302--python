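"""Feature window construction, overlap flags, and TSS distances."""

import numpy as np
import pytest

from methylome.annotation import (
    FeatureSet,
    TssPoint,
    build_features,
    category_percentages,
    annotate_regions,
    distance_bin,
    tss_distance,
)
from methylome.intervals import GeneModel, GenomicInterval


def gene(gene_id, chrom, strand, tx_start, tx_end, exon_bounds=None):
    if strand == "+":
        tss, tes = tx_start, tx_end - 1
    else:
        tss, tes = tx_end - 1, tx_start
    exon_bounds = exon_bounds or [(tx_start, tx_end)]
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds)
    return GeneModel(gene_id, chrom, strand, tss, tes, exons)


def span_set(ivs):
    return {(iv.chrom, p) for iv in ivs for p in range(iv.start, iv.end)}


def test_promoter_window_plus_strand():
    fs = build_features([gene("g", "c", "+", 10_000, 20_000)], [])
    (prom,) = fs.promoters
    assert (prom.start, prom.end) == (9_000, 10_500)


def test_promoter_window_minus_strand_is_mirror():
    fs = build_features([gene("g", "c", "-", 5_000, 10_001)], [])   # TSS at 10000
    (prom,) = fs.promoters
    assert (prom.start, prom.end) == (9_501, 11_001)


def test_promoter_strand_mirror_symmetry():
    """Reflecting the genome maps + promoters onto - promoters exactly."""
    L = 100_000
    for tx_start, tx_end in [(10_000, 20_000), (40_000, 47_000)]:
        plus = build_features([gene("g", "c", "+", tx_start, tx_end)], [])
        minus = build_features(
            [gene("g", "c", "-", L - tx_end, L - tx_start)], []
        )
        (p,) = plus.promoters
        (m,) = minus.promoters
        assert (m.start, m.end) == (L - p.end, L - p.start)


def test_three_prime_window_both_strands():
    fs = build_features([gene("g", "c", "+", 10_000, 20_000)], [])
    (tp,) = fs.three_prime_ends
    assert (tp.start, tp.end) == (18_999, 20_999)    # TES at 19999, 1 kb each side
    fs = build_features([gene("g", "c", "-", 10_000, 20_000)], [])
    (tp,) = fs.three_prime_ends
    assert (tp.start, tp.end) == (9_001, 11_001)     # TES at 10000, mirrored


def test_island_shore_shelf_hand_coordinates():
    islands = [GenomicInterval("c", 20_000, 21_000)]
    fs = build_features([], islands)
    assert span_set(fs.cpg_shores) == span_set([
        GenomicInterval("c", 18_000, 20_000), GenomicInterval("c", 21_000, 23_000),
    ])
    assert span_set(fs.cpg_shelves) == span_set([
        GenomicInterval("c", 16_000, 18_000), GenomicInterval("c", 23_000, 25_000),
    ])


def test_close_islands_truncate_shores():
    islands = [
        GenomicInterval("c", 20_000, 21_000),
        GenomicInterval("c", 22_000, 23_000),       # 1 kb apart
    ]
    fs = build_features([], islands)
    shore_bases = span_set(fs.cpg_shores)
    island_bases = span_set(fs.cpg_islands)
    assert shore_bases & island_bases == set()
    # the inter-island gap is entirely shore
    assert {("c", p) for p in range(21_000, 22_000)} <= shore_bases


def test_island_shore_shelf_partition_disjoint(rng):
    for _ in range(20):
        starts = np.sort(rng.choice(200_000, size=rng.integers(1, 8), replace=False))
        islands = [
            GenomicInterval("c", int(s), int(s) + int(rng.integers(200, 3_000)))
            for s in starts
        ]
        fs = build_features([], islands)
        i, sh, she = (
            span_set(fs.cpg_islands), span_set(fs.cpg_shores), span_set(fs.cpg_shelves)
        )
        assert i & sh == set()
        assert i & she == set()
        assert sh & she == set()


def test_introns_are_body_minus_exons():
    g = gene("g", "c", "+", 1_000, 9_000, [(1_000, 2_000), (5_000, 6_000)])
    fs = build_features([g], [])
    assert span_set(fs.introns) == {
        ("c", p) for p in range(2_000, 5_000)
    } | {("c", p) for p in range(6_000, 9_000)}


def test_clipping_to_chromosome_bounds():
    fs = build_features(
        [gene("g", "c", "+", 200, 5_000)], [GenomicInterval("c", 0, 500)],
        chrom_lengths={"c": 5_200},
    )
    for ivs in (fs.promoters, fs.cpg_shores, fs.cpg_shelves, fs.three_prime_ends):
        for iv in ivs:
            assert iv.start >= 0 and iv.end <= 5_200


# ---------------------------------------------------------------------------
# annotation flags
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_features():
    g1 = gene("g1", "c", "+", 10_000, 30_000, [(10_000, 12_000), (20_000, 22_000)])
    return build_features([g1], [GenomicInterval("c", 50_000, 51_000)]), g1


def test_flags_exon_only(toy_features):
    fs, _ = toy_features
    annot = annotate_regions([GenomicInterval("c", 10_500, 10_600)], fs)
    row = annot.iloc[0]
    assert row["exon"] and not row["intron"] and not row["intergenic"]


def test_flags_junction_hits_both(toy_features):
    fs, _ = toy_features
    row = annotate_regions([GenomicInterval("c", 11_900, 12_100)], fs).iloc[0]
    assert row["exon"] and row["intron"]


def test_flags_intergenic_only(toy_features):
    fs, _ = toy_features
    row = annotate_regions([GenomicInterval("c", 80_000, 80_100)], fs).iloc[0]
    assert row["intergenic"]
    for cat in ("promoter", "exon", "intron", "three_prime", "island", "shore", "shelf"):
        assert not row[cat]


def test_unknown_chromosome_counts_intergenic(toy_features):
    fs, _ = toy_features
    row = annotate_regions([GenomicInterval("chrUn", 0, 100)], fs).iloc[0]
    assert row["intergenic"] and not row["exon"]


def test_annotation_matches_per_base_oracle(rng, toy_features):
    """Flags equal literal per-base overlap on a toy genome."""
    fs, _ = toy_features
    cats = ("promoter", "exon", "intron", "three_prime", "island", "shore", "shelf")
    base_sets = {c: span_set(fs.category(c)) for c in cats}
    regions = []
    for _ in range(80):
        s = int(rng.integers(0, 99_000))
        regions.append(GenomicInterval("c", s, s + int(rng.integers(1, 1_000))))
    annot = annotate_regions(regions, fs)
    for row, region in zip(annot.itertuples(index=False), regions):
        bases = {("c", p) for p in range(region.start, region.end)}
        for c in cats:
            assert getattr(row, c) == bool(bases & base_sets[c]), (region, c)


def test_category_percentages_non_exclusive(toy_features):
    fs, _ = toy_features
    annot = annotate_regions(
        [GenomicInterval("c", 11_900, 12_100), GenomicInterval("c", 80_000, 80_100)],
        fs,
    )
    pct = category_percentages(annot)
    assert pct["exon"] == 50.0
    assert pct["intron"] == 50.0
    assert pct["intergenic"] == 50.0
    assert sum(pct[c] for c in ("exon", "intron", "intergenic")) > 100.0


# ---------------------------------------------------------------------------
# TSS distance
# ---------------------------------------------------------------------------

def test_tss_distance_downstream_plus():
    tss = [TssPoint("c", 1_000, "+", "g")]
    d, label = tss_distance(GenomicInterval("c", 3_000, 3_200), tss)
    assert d == 2_000
    assert label == "0-5kb_downstream"


def test_tss_distance_zero_when_overlapping():
    tss = [TssPoint("c", 3_100, "+", "g")]
    d, _ = tss_distance(GenomicInterval("c", 3_000, 3_200), tss)
    assert d == 0


def test_tss_distance_minus_strand_sign():
    tss = [TssPoint("c", 5_000, "-", "g")]
    d, label = tss_distance(GenomicInterval("c", 5_500, 5_600), tss)
    assert d == -500                 # right of a minus-strand TSS = upstream
    assert label == "0-5kb_upstream"


def test_tss_distance_nearest_and_tie_break():
    tss = [TssPoint("c", 1_000, "+", "a"), TssPoint("c", 10_000, "+", "b")]
    d, _ = tss_distance(GenomicInterval("c", 3_000, 3_200), tss)
    assert d == 2_000                # nearest is a (2000 vs 6801)
    # exact tie: region midway; downstream of the left TSS wins
    tss = [TssPoint("c", 1_000, "+", "a"), TssPoint("c", 5_199, "+", "b")]
    d, _ = tss_distance(GenomicInterval("c", 3_000, 3_200), tss)
    assert d == 2_000


def test_tss_distance_empty_errors():
    with pytest.raises(ValueError):
        tss_distance(GenomicInterval("c", 0, 10), [])


def test_distance_bins():
    assert distance_bin(0) == "0-5kb_downstream"
    assert distance_bin(5_000) == "0-5kb_downstream"
    assert distance_bin(5_001) == "5-50kb_downstream"
    assert distance_bin(-400_000) == "50-500kb_upstream"
    assert distance_bin(600_000) == ">500kb_downstream"
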