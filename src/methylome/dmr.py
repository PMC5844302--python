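"""Differential methylation: site statistics and region calling.

The site statistic is a *credible methylation difference*: each group's
methylation proportion gets a Jeffreys-prior Beta posterior,
``Beta(meth + 0.5, total - meth + 0.5)``, and the equal-tailed credible
interval ``(L, U)`` of ``p2 - p1`` is computed. The credible difference is

    cdif = L  if L > 0      (confidently higher in group 2)
         = U  if U < 0      (confidently lower in group 2)
         = 0  otherwise     (interval straddles zero; not significant)

Regions are built by greedily chaining successive significant sites of the
same sign with inter-CpG gaps <= ``max_gap_bp``; chains with at least
``min_cpgs`` member sites whose pooled (count-weighted) methylation
difference reaches ``min_nominal_dif`` (default 0.2) are reported as DMRs.
A region is *hypo* when group 2 (knockout) is lower than group 1.

Numerics: the interval of the Beta difference is computed by Gauss-
Legendre quadrature in quantile space — ``P(p2 - p1 <= d) =
E_u[F2(Q1(u) + d)]`` with u at Legendre nodes on (0, 1) — and vectorized
bisection on d. A conservative normal-approximation screen (the 80%
normal interval of the difference containing zero) short-circuits clearly
non-significant sites, since the exact 95% interval is strictly wider. A
Monte-Carlo path is retained as a cross-check option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

_SCREEN_Z = stats.norm.ppf(0.9)  # 80% two-sided normal interval


@dataclass
class DmrConfig:
    min_nominal_dif: float = 0.2
    credibility: float = 0.95
    prior_alpha: float = 0.5
    prior_beta: float = 0.5
    max_gap_bp: int = 300
    min_cpgs: int = 3
    method: str = "quadrature"      # or "mc"
    mc_draws: int = 100_000
    mc_seed: int = 0
    quad_nodes: int = 32
    bisect_tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.min_nominal_dif <= 1:
            raise ValueError("min_nominal_dif must be in (0, 1]")
        if not 0 < self.credibility < 1:
            raise ValueError("credibility must be in (0, 1)")


@dataclass
class DMR:
    interval: GenomicInterval
    n_cpgs: int
    mean_ratio1: float
    mean_ratio2: float
    nominal_dif: float
    direction: str                  # hypo <=> group2 < group1
    min_abs_cdif: float


def _posterior_params(meth, total, config: DmrConfig):
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    return meth + config.prior_alpha, total - meth + config.prior_beta


def _diff_interval_quadrature(a1, b1, a2, b2, config: DmrConfig):
    """Equal-tailed interval of p2 - p1 for arrays of Beta parameters.

    Vectorized over sites: Q1 evaluated once per site at Legendre nodes,
    then bisection on d with F2 evaluations.
    """
    a1, b1, a2, b2 = np.atleast_1d(a1, b1, a2, b2)
    nodes, weights = np.polynomial.legendre.leggauss(config.quad_nodes)
    u = 0.5 * (nodes + 1.0)          # map to (0, 1)
    w = 0.5 * weights
    q1 = stats.beta.ppf(u[None, :], a1[:, None], b1[:, None])  # (S, K)

    def cdf_of_diff(d):
        # P(p2 - p1 <= d) per site; d is (S,)
        arg = np.clip(q1 + d[:, None], 0.0, 1.0)
        return stats.beta.cdf(arg, a2[:, None], b2[:, None]) @ w

    def quantile(prob: float) -> np.ndarray:
        lo = np.full(len(a1), -1.0)
        hi = np.full(len(a1), 1.0)
        n_iter = int(np.ceil(np.log2(2.0 / config.bisect_tol)))
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            below = cdf_of_diff(mid) < prob
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)

    alpha = 1.0 - config.credibility
    return quantile(alpha / 2.0), quantile(1.0 - alpha / 2.0)


def _diff_interval_mc(a1, b1, a2, b2, config: DmrConfig):
    rng = np.random.default_rng(config.mc_seed)
    a1, b1, a2, b2 = np.atleast_1d(a1, b1, a2, b2)
    alpha = 1.0 - config.credibility
    L = np.empty(len(a1))
    U = np.empty(len(a1))
    for i in range(len(a1)):
        d = rng.beta(a2[i], b2[i], config.mc_draws) - rng.beta(
            a1[i], b1[i], config.mc_draws
        )
        L[i], U[i] = np.quantile(d, [alpha / 2.0, 1.0 - alpha / 2.0])
    return L, U


def credible_difference(meth1, total1, meth2, total2,
                        config: DmrConfig | None = None) -> np.ndarray:
    """Vectorized signed credible difference of p2 - p1 (0 when not significant)."""
    config = config or DmrConfig()
    meth1, total1, meth2, total2 = np.atleast_1d(meth1, total1, meth2, total2)
    if (total1 <= 0).any() or (total2 <= 0).any():
        raise ValueError("totals must be positive; skip zero-depth sites upstream")
    a1, b1 = _posterior_params(meth1, total1, config)
    a2, b2 = _posterior_params(meth2, total2, config)

    # conservative screen: 80% normal interval containing 0 implies the
    # exact 95% interval does too
    m1, m2 = a1 / (a1 + b1), a2 / (a2 + b2)
    v1 = a1 * b1 / ((a1 + b1) ** 2 * (a1 + b1 + 1.0))
    v2 = a2 * b2 / ((a2 + b2) ** 2 * (a2 + b2 + 1.0))
    maybe = np.abs(m2 - m1) > _SCREEN_Z * np.sqrt(v1 + v2)

    cdif = np.zeros(len(a1))
    if maybe.any():
        idx = np.nonzero(maybe)[0]
        interval = (
            _diff_interval_mc if config.method == "mc" else _diff_interval_quadrature
        )
        L, U = interval(a1[idx], b1[idx], a2[idx], b2[idx], config)
        cdif[idx] = np.where(L > 0, L, np.where(U < 0, U, 0.0))
    return cdif


def site_cdif(meth1: int, total1: int, meth2: int, total2: int,
              config: DmrConfig | None = None) -> float:
    """Scalar credible difference for one site (see module docs)."""
    return float(credible_difference([meth1], [total1], [meth2], [total2], config)[0])


def site_difference_table(
    group1: pd.DataFrame, group2: pd.DataFrame, config: DmrConfig | None = None
) -> pd.DataFrame:
    """Per-site difference statistics on the shared site set.

    Inputs are group-level count tables (chrom, start, total, meth); sites
    with zero depth in either group are skipped.
    """
    config = config or DmrConfig()
    joined = group1[["chrom", "start", "meth", "total"]].merge(
        group2[["chrom", "start", "meth", "total"]],
        on=["chrom", "start"], suffixes=("1", "2"), how="inner",
    )
    joined = joined.loc[(joined["total1"] > 0) & (joined["total2"] > 0)]
    joined = joined.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    r1 = joined["meth1"] / joined["total1"]
    r2 = joined["meth2"] / joined["total2"]
    joined["nominal_dif"] = r2 - r1
    joined["cdif"] = credible_difference(
        joined["meth1"], joined["total1"], joined["meth2"], joined["total2"],
        config,
    )
    joined["significant"] = joined["cdif"] != 0.0
    return joined


def call_dmrs(site_diffs: pd.DataFrame, config: DmrConfig | None = None
              ) -> list[DMR]:
    """Chain significant same-sign sites into regions (see module docs)."""
    config = config or DmrConfig()
    for chrom, grp in site_diffs.groupby("chrom"):
        if not grp["start"].is_monotonic_increasing:
            raise ValueError(f"site differences not sorted on {chrom}")

    dmrs: list[DMR] = []
    sig = site_diffs.loc[site_diffs["significant"]]
    for chrom, grp in sig.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        signs = np.sign(grp["cdif"].to_numpy())
        chains: list[list[int]] = []
        current: list[int] = []
        for i in range(len(grp)):
            if current and (
                signs[i] != signs[current[-1]]
                or starts[i] - starts[current[-1]] > config.max_gap_bp
            ):
                chains.append(current)
                current = []
            current.append(i)
        if current:
            chains.append(current)
        for chain in chains:
            if len(chain) < config.min_cpgs:
                continue
            sub = grp.iloc[chain]
            t1, m1 = sub["total1"].sum(), sub["meth1"].sum()
            t2, m2 = sub["total2"].sum(), sub["meth2"].sum()
            ratio1, ratio2 = m1 / t1, m2 / t2
            nominal = ratio2 - ratio1
            if abs(nominal) < config.min_nominal_dif:
                continue
            iv = GenomicInterval(
                chrom, int(sub["start"].iloc[0]), int(sub["start"].iloc[-1]) + 2
            )
            dmrs.append(DMR(
                interval=iv,
                n_cpgs=len(chain),
                mean_ratio1=float(ratio1),
                mean_ratio2=float(ratio2),
                nominal_dif=float(nominal),
                direction="hypo" if nominal < 0 else "hyper",
                min_abs_cdif=float(np.abs(sub["cdif"]).min()),
            ))
    return dmrs


def dmr_report(dmrs: list[DMR]) -> dict:
    """Per-direction DMR tables (BED-compatible columns first)."""
    cols = [
        "chrom", "start", "end", "n_cpgs", "mean_ratio1", "mean_ratio2",
        "nominal_dif", "direction", "min_abs_cdif",
    ]
    out = {}
    for direction in ("hypo", "hyper"):
        rows = [
            {
                "chrom": d.interval.chrom, "start": d.interval.start,
                "end": d.interval.end, "n_cpgs": d.n_cpgs,
                "mean_ratio1": round(d.mean_ratio1, 6),
                "mean_ratio2": round(d.mean_ratio2, 6),
                "nominal_dif": round(d.nominal_dif, 6),
                "direction": d.direction,
                "min_abs_cdif": round(d.min_abs_cdif, 6),
            }
            for d in dmrs if d.direction == direction
        ]
        df = pd.DataFrame(rows, columns=cols)
        out[direction] = df.sort_values(
            ["chrom", "start"], kind="mergesort"
        ).reset_index(drop=True)
    return out


def dmr_intervals(dmrs: list[DMR], direction: str | None = None
                  ) -> list[GenomicInterval]:
    return [
        d.interval for d in dmrs if direction is None or d.direction == direction
    ]
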