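"""Per-CpG methylation calling, conversion QC, and distribution summaries.

Strand evidence for one CpG is pooled into a single record (one mCG/CG
value per site), replicates are merged by summing counts (the analogue of
merging replicate alignments), and the comparative analyses use only sites
with read depth >= 10. The global methylome distribution is summarized in
three classes: largely methylated (mCG/CG > 0.75), largely unmethylated
(< 0.25), and intermediate (boundaries inclusive into the intermediate
class, matching the strict outer inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MethylomeSummary:
    n_sites: int
    frac_methylated: float
    frac_unmethylated: float
    frac_intermediate: float
    lo: float = 0.25
    hi: float = 0.75


@dataclass
class ConversionEstimate:
    source: str
    n_calls: int
    n_meth_calls: int

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.n_meth_calls / self.n_calls


def _check_counts(records: pd.DataFrame) -> None:
    if (records["meth"] > records["total"]).any():
        bad = records.loc[records["meth"] > records["total"]].iloc[0]
        raise ValueError(
            f"meth > total at {bad['chrom']}:{bad['start']} "
            f"({bad['meth']}/{bad['total']})"
        )


def call_methylation(records: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Depth-filtered per-CpG calls; ``total >= min_depth`` (inclusive)."""
    _check_counts(records)
    out = records.loc[records["total"] >= min_depth].copy()
    out["ratio"] = out["meth"] / out["total"]
    return out.reset_index(drop=True)


def merge_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts per site across replicates (group-level calls).

    The merged ratio is by construction the depth-weighted mean of the
    replicate ratios.
    """
    if not replicates:
        raise ValueError("no replicates to merge")
    for rep in replicates:
        _check_counts(rep)
    cat = pd.concat(
        [r[["chrom", "start", "end", "total", "meth"]] for r in replicates],
        ignore_index=True,
    )
    spans = cat.groupby(["chrom", "start"])["end"].nunique()
    if (spans > 1).any():
        raise ValueError("conflicting coordinates across replicates")
    merged = cat.groupby(["chrom", "start", "end"], as_index=False)[
        ["total", "meth"]
    ].sum()
    merged["ratio"] = np.where(
        merged["total"] > 0,
        merged["meth"] / merged["total"].replace(0, 1),
        np.nan,
    )
    merged = merged[["chrom", "start", "end", "ratio", "total", "meth"]]
    return merged.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def summarize_distribution(
    calls: pd.DataFrame, lo: float = 0.25, hi: float = 0.75
) -> MethylomeSummary:
    """Fractions of sites per methylation class (outer classes strict)."""
    ratios = calls["ratio"].to_numpy(dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    n = len(ratios)
    if n == 0:
        raise ValueError("no sites with a defined methylation ratio")
    f_meth = float((ratios > hi).sum() / n)
    f_unmeth = float((ratios < lo).sum() / n)
    return MethylomeSummary(
        n_sites=n,
        frac_methylated=f_meth,
        frac_unmethylated=f_unmeth,
        frac_intermediate=1.0 - f_meth - f_unmeth,
        lo=lo, hi=hi,
    )


def estimate_conversion(
    records: pd.DataFrame, control_chroms: tuple = ("lambda", "chrM")
) -> dict:
    """Conversion rate from unmethylated control contigs.

    Every methylation call on a control contig comes from a truly
    unmethylated cytosine, so conversion = 1 - meth calls / total calls.
    Returns one estimate per present control source plus a pooled
    ``composite``; raises if no control calls exist at all.
    """
    out: dict[str, ConversionEstimate] = {}
    tot_all = meth_all = 0
    for chrom in control_chroms:
        sub = records.loc[records["chrom"] == chrom]
        tot = int(sub["total"].sum())
        meth = int(sub["meth"].sum())
        if tot > 0:
            out[chrom] = ConversionEstimate(chrom, tot, meth)
        tot_all += tot
        meth_all += meth
    if tot_all == 0:
        raise ValueError(
            f"no calls on control contigs {control_chroms}; cannot estimate "
            "conversion"
        )
    out["composite"] = ConversionEstimate("composite", tot_all, meth_all)
    return out


def paired_site_table(
    group1: pd.DataFrame, group2: pd.DataFrame, min_depth: int = 10
) -> pd.DataFrame:
    """Sites with depth >= min_depth in BOTH groups, as (ratio1, ratio2) pairs."""
    g1 = call_methylation(group1, min_depth)[["chrom", "start", "ratio", "total", "meth"]]
    g2 = call_methylation(group2, min_depth)[["chrom", "start", "ratio", "total", "meth"]]
    joined = g1.merge(g2, on=["chrom", "start"], suffixes=("1", "2"), how="inner")
    return joined.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def depth_at_least_fraction(records: pd.DataFrame, min_depth: int = 10) -> float:
    """Fraction of sites with read depth >= min_depth."""
    if len(records) == 0:
        raise ValueError("no records")
    return float((records["total"] >= min_depth).mean())
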