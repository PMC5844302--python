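"""Generator properties: determinism, planted structure, sampling bounds."""

import numpy as np
import pytest

from methylome import simulate
from methylome.simulate import (
    SPIKE_IN_CHROM,
    SimulationConfig,
    build_reference,
    build_truth,
    draw_methylome,
    plant_cpg_snps,
    plant_effects,
    simulate_pileups,
    simulate_study,
    write_outputs,
)
from conftest import small_config


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        small_config(high_frac=0.9, low_frac=0.2, mid_frac=0.1)
    with pytest.raises(ValueError, match="conversion_failure"):
        small_config(conversion_failure=0.1)
    with pytest.raises(ValueError, match="shorter than"):
        small_config(chrom_lengths={"tiny": 1_000})


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = small_config(seed=5)
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    simulate_study(cfg, d1)
    simulate_study(cfg, d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_cpg_count_matches_binomial_expectation():
    cfg = small_config(
        chrom_lengths={"chrA": 100_000}, cpg_rate=0.02,
        n_islands_per_chrom=0, n_genes=5,
    )
    ref = build_reference(cfg)
    n = len(ref.cpg_positions["chrA"])
    # dropped adjacent draws shave ~cpg_rate off the Bernoulli expectation
    assert abs(n - 2000) < 5 * np.sqrt(2000) + 0.02 * 2000


def test_reference_structure(small_study):
    ref = small_study.truth.reference
    assert SPIKE_IN_CHROM in ref.cpg_positions
    assert ref.chrom_lengths[SPIKE_IN_CHROM] == 20_000
    chroms_with_genes = {g.chrom for g in ref.gene_models}
    assert chroms_with_genes == {"chrA", "chrB"}
    for chrom, pos in ref.cpg_positions.items():
        assert np.all(np.diff(pos) >= 2)  # CpGs never overlap


def test_degenerate_mixture_all_high():
    cfg = small_config(high_frac=1.0, low_frac=0.0, mid_frac=0.0)
    truth = draw_methylome(cfg, build_reference(cfg))
    for chrom, levels in truth.true_level_wt.items():
        if chrom == SPIKE_IN_CHROM:
            assert np.all(levels == 0.0)
        else:
            assert np.all(levels > 0.75)


def test_mixture_fractions_recovered_at_scale():
    cfg = SimulationConfig(
        chrom_lengths={"chrA": 2_500_000}, cpg_rate=0.04, n_genes=20,
        n_islands_per_chrom=0, seed=3,
    )
    truth = draw_methylome(cfg, build_reference(cfg))
    levels = truth.true_level_wt["chrA"]
    assert len(levels) > 90_000
    assert np.mean(levels > 0.75) == pytest.approx(0.82, abs=0.01)
    assert np.mean(levels < 0.25) == pytest.approx(0.07, abs=0.01)


def test_plant_effects_bookkeeping_and_clipping():
    cfg = small_config(n_hypo=4, n_hyper=2)
    truth = build_truth(cfg)
    directions = [d for _, d in truth.dmr_truth]
    assert directions.count("hypo") == 4
    assert directions.count("hyper") == 2
    ivs = [iv for iv, _ in truth.dmr_truth]
    for i, a in enumerate(ivs):
        for b in ivs[i + 1:]:
            assert not a.overlaps(b)
    # inside every planted region the effect is the full delta
    for iv, direction in truth.dmr_truth:
        pos = truth.reference.cpg_positions[iv.chrom]
        inside = (pos >= iv.start) & (pos < iv.end)
        wt = truth.true_level_wt[iv.chrom][inside]
        ko = truth.true_level_ko[iv.chrom][inside]
        np.testing.assert_allclose(np.abs(ko - wt), cfg.dmr_delta, atol=1e-12)
        assert np.all((ko - wt < 0) if direction == "hypo" else (ko - wt > 0))
        assert np.all((ko >= 0) & (ko <= 1))


def test_no_effects_means_identical_groups():
    cfg = small_config(n_hypo=0, n_hyper=0)
    truth = build_truth(cfg)
    assert truth.dmr_truth == []
    for chrom in truth.true_level_wt:
        np.testing.assert_array_equal(
            truth.true_level_wt[chrom], truth.true_level_ko[chrom]
        )


def test_snp_count_binomial_bound_and_dmr_exclusion():
    cfg = small_config(snp_rate=0.05, exclude_dmrs=True)
    truth = build_truth(cfg)
    n_cpg = truth.reference.n_cpgs(include_spike_in=False)
    n_snp = sum(len(v) for v in truth.snp_sites.values())
    expected = 0.05 * n_cpg
    assert abs(n_snp - expected) < 3 * np.sqrt(n_cpg * 0.05 * 0.95) + 0.05 * 60
    for iv, _ in truth.dmr_truth:
        snps = truth.snp_sites[iv.chrom]
        assert not np.any((snps >= iv.start) & (snps < iv.end))
    assert len(truth.snp_sites[SPIKE_IN_CHROM]) == 0


def test_snp_rate_zero_gives_no_snps():
    truth = build_truth(small_config(snp_rate=0.0))
    assert all(len(v) == 0 for v in truth.snp_sites.values())


def test_deterministic_limit_full_methylation():
    cfg = small_config(
        chrom_lengths={"chrA": 60_000}, high_frac=1.0, low_frac=0.0,
        mid_frac=0.0, conversion_failure=0.0, miscall_rate=0.0,
        n_hypo=0, n_hyper=0, snp_rate=0.0, n_replicates=1,
    )
    # force level exactly 1 everywhere to remove binomial noise
    truth = build_truth(cfg)
    for chrom in truth.true_level_wt:
        if chrom != SPIKE_IN_CHROM:
            truth.true_level_wt[chrom][:] = 1.0
            truth.true_level_ko[chrom][:] = 1.0
    data = simulate_pileups(truth, cfg)
    g = data.gbed[("wt", 1)]
    auto = g.loc[g["chrom"] != SPIKE_IN_CHROM]
    assert (auto["meth"] == auto["total"]).all()


def test_spike_in_methylation_tracks_conversion_failure(small_study):
    g = small_study.gbed[("wt", 1)]
    spike = g.loc[g["chrom"] == SPIKE_IN_CHROM]
    total = spike["total"].sum()
    frac = spike["meth"].sum() / total
    se = np.sqrt(0.0016 * (1 - 0.0016) / total)
    assert abs(frac - 0.0016) < 4 * se


def test_snp_site_pileup_shows_alternate_base(small_study):
    truth = small_study.truth
    pdf = small_study.pileups[("wt", 1)]
    checked = 0
    for chrom in sorted(truth.snp_sites):
        for pos in truth.snp_sites[chrom][:5]:
            alt = truth.snp_alt_base[(chrom, int(pos))]
            row = pdf.loc[
                (pdf["chrom"] == chrom) & (pdf["pos"] == pos + 1)
                & (pdf["strand"] == "+")
            ].iloc[0]
            total = row[["nA", "nC", "nG", "nT"]].sum()
            if total == 0:
                continue
            assert row[f"n{alt}"] >= row["nG"]
            checked += 1
    assert checked > 0


def test_mean_ratio_converges_to_true_level():
    cfg = small_config(
        chrom_lengths={"chrA": 60_000}, depth_mean=500.0, n_replicates=1,
        snp_rate=0.0, n_hypo=0, n_hyper=0,
    )
    truth = build_truth(cfg)
    data = simulate_pileups(truth, cfg)
    g = data.gbed[("wt", 1)]
    auto = g.loc[g["chrom"] == "chrA"]
    obs = (auto["meth"] / auto["total"]).to_numpy()
    exp = truth.true_level_wt["chrA"] * (1 - 0.0) + (
        1 - truth.true_level_wt["chrA"]
    ) * cfg.conversion_failure
    assert np.max(np.abs(obs - exp)) < 0.08
    assert np.mean(np.abs(obs - exp)) < 0.02


def test_mbias_table_reflects_planted_bias(small_study):
    mb = small_study.mbias_table
    sub = mb.loc[(mb["mate"] == 1) & (mb["length_class"] == "PE150")]
    lvl = (sub["nMeth"] / (sub["nMeth"] + sub["nUnmeth"])).to_numpy()
    mid = lvl[29:100].mean()
    assert np.all(lvl[:5] > mid + 0.05)          # planted +0.1 at positions 1-5
    assert abs(lvl[5:].mean() - mid) < 0.02


def test_expression_table_threshold_fraction(small_study):
    expr = small_study.truth.reference.expression
    fpkm = expr[[c for c in expr.columns if c.startswith("fpkm")]].mean(axis=1)
    frac = (fpkm >= 1.0).mean()
    assert frac == pytest.approx(0.6, abs=0.1)
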