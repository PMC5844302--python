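"""End-to-end orchestration of the synthetic WGBS analysis.

Chains the stages in their natural order — simulate, M-bias QC, context
validation, methylation calling, DMR calling, annotation, enrichment —
and collects every intermediate product in a :class:`PipelineResult` so
drivers, tests, and the acceptance script share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotation, calling, dmr, enrichment, mbias, simulate, validation
from .intervals import GenomicInterval, match_intervals
from .simulate import SPIKE_IN_CHROM, SimulatedData, SimulationConfig


@dataclass
class PipelineResult:
    config: SimulationConfig
    data: SimulatedData
    trim_report: pd.DataFrame
    validation_results: list
    validated_fraction: float
    group_calls: dict                  # group -> merged, validated count table
    conversion: dict                   # source -> ConversionEstimate
    distribution: dict                 # group -> MethylomeSummary
    depth10_fraction: dict             # group -> fraction of validated sites
    paired_sites: pd.DataFrame
    site_diffs: pd.DataFrame
    dmrs: list
    features: annotation.FeatureSet
    dmr_annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)

    def dmr_evaluation(self) -> dict:
        """Sensitivity/precision of called DMRs against the planted truth."""
        truth = self.data.truth
        called = dmr.dmr_intervals(self.dmrs)
        truth_ivs = [iv for iv, _ in truth.dmr_truth]
        n_truth_hit, n_called_hit = match_intervals(called, truth_ivs)
        n_dir_correct = 0
        for d in self.dmrs:
            for iv, direction in truth.dmr_truth:
                if d.interval.overlaps(iv):
                    if d.direction == direction:
                        n_dir_correct += 1
                    break
        return {
            "n_truth": len(truth_ivs),
            "n_called": len(self.dmrs),
            "sensitivity": n_truth_hit / len(truth_ivs) if truth_ivs else float("nan"),
            "precision": n_called_hit / len(self.dmrs) if self.dmrs else float("nan"),
            "n_direction_correct": n_dir_correct,
            "n_called_matching": n_called_hit,
        }


def run_pipeline(
    config: SimulationConfig,
    min_frac: float = 0.95,
    min_g_depth: int = 5,
    min_depth: int = 10,
    dmr_config: dmr.DmrConfig | None = None,
    shuffle_seed: int = 1000,
    with_enrichment: bool = True,
) -> PipelineResult:
    dmr_config = dmr_config or dmr.DmrConfig()
    data = simulate.simulate_study(config)
    ref = data.truth.reference

    # M-bias QC (advisory; the simulated pileups are already trim-clean)
    profiles = mbias.compute_mbias(data.mbias_table)
    trim = mbias.trim_report(profiles)

    # context validation on the all-sample combined pileup
    results = validation.validate_cpg_sites(
        data.combined_pileup(), ref.cpg_positions, min_frac, min_g_depth
    )
    n_assessed = len(results)
    ok = validation.passed_sites(results)
    validated_fraction = len(ok) / n_assessed if n_assessed else float("nan")

    # replicate merge + validation filter + depth filter, per group
    group_calls: dict[str, pd.DataFrame] = {}
    distribution: dict[str, calling.MethylomeSummary] = {}
    depth10: dict[str, float] = {}
    for group in ("wt", "ko"):
        reps = [data.gbed[(group, r)] for r in range(1, config.n_replicates + 1)]
        merged = calling.merge_replicates(reps)
        merged, _ = validation.apply_validation(merged, results)
        group_calls[group] = merged
        autosomal = merged.loc[merged["chrom"] != SPIKE_IN_CHROM]
        depth10[group] = calling.depth_at_least_fraction(autosomal, min_depth)
        called = calling.call_methylation(autosomal, min_depth)
        distribution[group] = calling.summarize_distribution(called)

    # conversion from the (unfiltered, unvalidated) spike-in calls of all
    # replicates pooled — the spike-in has no genotype and needs no context
    # validation
    all_reps = calling.merge_replicates(
        [data.gbed[k] for k in sorted(data.gbed)]
    )
    conversion = calling.estimate_conversion(all_reps, (SPIKE_IN_CHROM,))

    paired = calling.paired_site_table(
        group_calls["wt"].loc[group_calls["wt"]["chrom"] != SPIKE_IN_CHROM],
        group_calls["ko"].loc[group_calls["ko"]["chrom"] != SPIKE_IN_CHROM],
        min_depth,
    )
    site_diffs = dmr.site_difference_table(
        calling.call_methylation(
            group_calls["wt"].loc[group_calls["wt"]["chrom"] != SPIKE_IN_CHROM],
            min_depth,
        ),
        calling.call_methylation(
            group_calls["ko"].loc[group_calls["ko"]["chrom"] != SPIKE_IN_CHROM],
            min_depth,
        ),
        dmr_config,
    )
    dmrs = dmr.call_dmrs(site_diffs, dmr_config)

    features = annotation.build_features(
        ref.gene_models, ref.cpg_islands, ref.chrom_lengths
    )
    result = PipelineResult(
        config=config, data=data, trim_report=trim,
        validation_results=results, validated_fraction=validated_fraction,
        group_calls=group_calls, conversion=conversion,
        distribution=distribution, depth10_fraction=depth10,
        paired_sites=paired, site_diffs=site_diffs, dmrs=dmrs,
        features=features,
    )

    result.dmr_annotations = annotation.annotate_regions(
        dmr.dmr_intervals(dmrs), features
    )
    if with_enrichment and dmrs:
        expressed = enrichment.expressed_gene_bodies(
            ref.expression, ref.gene_models
        )
        categories = {
            "promoter": features.promoters,
            "exon": features.exons,
            "intron": features.introns,
            "three_prime": features.three_prime_ends,
            "island": features.cpg_islands,
            "shore": features.cpg_shores,
            "shelf": features.cpg_shelves,
            "expressed_gene_body": expressed,
        }
        mask = [GenomicInterval(SPIKE_IN_CHROM, 0, config.spike_in_length)]
        result.enrichment = enrichment.enrichment_report(
            {
                "hypo": dmr.dmr_intervals(dmrs, "hypo"),
                "hyper": dmr.dmr_intervals(dmrs, "hyper"),
            },
            categories,
            ref.chrom_lengths,
            enrichment.ShuffleConfig(seed=shuffle_seed, mask=mask),
        )
    return result
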