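"""Polymorphism-aware genomic-context validation of CpG sites.

A reference CpG keyed by its plus-strand C coordinate ``N`` is kept for
downstream methylation analysis only when, in the pileup combined over all
runs of all samples, the guanine evidence on both strands confirms a CpG
context in every sample's genotype:

1. >= ``min_frac`` of mapped bases at ``N+1`` on the plus strand are G,
2. >= ``min_frac`` of mapped bases at ``N`` on the minus strand are G,
3. G read depth at ``N+1`` on the plus strand >= ``min_g_depth``,
4. G read depth at ``N`` on the minus strand >= ``min_g_depth``.

Thresholds are inclusive (19 G / 20 bases passes at ``min_frac = 0.95``).
The denominator is all mapped bases at the coordinate. Sites without any
coverage at a required coordinate fail with both depth reasons rather than
raising. Only reference CpGs are assessed — there is no de-novo discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FAIL_REASONS = ("plus_frac", "minus_frac", "plus_depth", "minus_depth")


@dataclass
class ValidationResult:
    chrom: str
    cpg_start: int
    plus_g_frac: float
    minus_g_frac: float
    plus_g_depth: int
    minus_g_depth: int
    passed: bool
    fail_reasons: tuple


def validate_cpg_sites(
    combined_pileup: pd.DataFrame,
    reference_cpgs: dict,
    min_frac: float = 0.95,
    min_g_depth: int = 5,
) -> list[ValidationResult]:
    """Apply the four-criterion context check to every reference CpG.

    ``combined_pileup`` must already be summed over all samples/runs;
    ``reference_cpgs`` maps chrom -> sorted array of plus-strand C
    coordinates.
    """
    key = combined_pileup.set_index(["chrom", "pos", "strand"])
    n_g = key["nG"]
    n_total = key[["nA", "nC", "nG", "nT"]].sum(axis=1)

    def lookup(chrom: str, pos: int, strand: str) -> tuple[int, int]:
        try:
            return int(n_g.loc[(chrom, pos, strand)]), int(n_total.loc[(chrom, pos, strand)])
        except KeyError:
            return 0, 0

    results: list[ValidationResult] = []
    for chrom in sorted(reference_cpgs):
        for pos in np.asarray(reference_cpgs[chrom]):
            pos = int(pos)
            g_p, t_p = lookup(chrom, pos + 1, "+")
            g_m, t_m = lookup(chrom, pos, "-")
            frac_p = g_p / t_p if t_p > 0 else 0.0
            frac_m = g_m / t_m if t_m > 0 else 0.0
            reasons = []
            if frac_p < min_frac:
                reasons.append("plus_frac")
            if frac_m < min_frac:
                reasons.append("minus_frac")
            if g_p < min_g_depth:
                reasons.append("plus_depth")
            if g_m < min_g_depth:
                reasons.append("minus_depth")
            results.append(ValidationResult(
                chrom, pos, frac_p, frac_m, g_p, g_m,
                passed=not reasons, fail_reasons=tuple(reasons),
            ))
    return results


def validation_table(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": r.chrom, "cpg_start": r.cpg_start,
            "plus_g_frac": round(r.plus_g_frac, 6),
            "minus_g_frac": round(r.minus_g_frac, 6),
            "plus_g_depth": r.plus_g_depth, "minus_g_depth": r.minus_g_depth,
            "passed": r.passed,
            "fail_reasons": ",".join(r.fail_reasons) or ".",
        }
        for r in results
    ])


def passed_sites(results: list[ValidationResult]) -> set:
    return {(r.chrom, r.cpg_start) for r in results if r.passed}


def apply_validation(
    methyl_records: pd.DataFrame, results: list[ValidationResult]
) -> tuple[pd.DataFrame, dict]:
    """Keep exactly the records at sites that passed validation.

    Records at sites absent from the validation results are dropped and
    counted in the returned report (``n_unvalidated``), mirroring the rule
    that an unassessed site is not a validated site. Input order preserved.
    """
    ok = passed_sites(results)
    assessed = {(r.chrom, r.cpg_start) for r in results}
    keys = list(zip(methyl_records["chrom"], methyl_records["start"]))
    keep = np.array([k in ok for k in keys], dtype=bool)
    unassessed = sum(1 for k in keys if k not in assessed)
    report = {
        "n_input": len(methyl_records),
        "n_kept": int(keep.sum()),
        "n_failed": int((~keep).sum()) - unassessed,
        "n_unvalidated": unassessed,
    }
    return methyl_records.loc[keep].reset_index(drop=True), report
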