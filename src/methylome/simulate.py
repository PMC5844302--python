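"""Synthetic WGBS study generator.

Emulates the post-alignment inputs of a two-genotype (wild-type vs knockout)
whole-genome bisulfite sequencing comparison on a toy genome:

* a bimodal CpG methylome (by default 82% highly methylated, 7%
  unmethylated, 11% intermediate),
* focal planted hypo-/hyper-methylation effects, hypomethylation
  preferentially inside gene bodies of expressed genes,
* CpG-destroying polymorphisms (the G following the plus-strand C replaced
  by an alternate base in the sample genotype),
* read-end M-bias artifacts in a per-read-position methylation call table,
* incomplete bisulfite conversion (an unmethylated C read as methylated
  with small probability), and
* an always-unmethylated spike-in contig ("lambda") for conversion QC.

The simulation unit is the pileup, not the read: strand-split per-position
base pileups and per-CpG methylation counts are drawn directly, and M-bias
is represented by an aggregate position-resolved call table. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .intervals import GenomicInterval, GeneModel

SPIKE_IN_CHROM = "lambda"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic WGBS experiment.

    Defaults are the conditions exercised throughout the test-bed: a
    2 x 1 Mb genome at CpG rate 0.02 (~40,000 CpGs), an unmethylated 48.5 kb
    spike-in, methylome mixture 0.82/0.07/0.11, per-strand depth 30,
    bisulfite conversion failure 1.6e-3, 5% CpG-destroying polymorphisms,
    20 hypomethylated + 10 hypermethylated planted regions of 10 CpGs with
    effect size 0.4, and 3 replicates per group.
    """

    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    spike_in_length: int = 48_502          # phage lambda genome size
    n_genes: int = 60
    gene_length_mean: int = 12_000
    n_exons_mean: float = 4.0
    cpg_rate: float = 0.02                 # expected CpGs per bp
    island_cpg_rate: float = 0.10          # CpG density inside islands
    n_islands_per_chrom: int = 10
    island_length: int = 1_000
    high_frac: float = 0.82
    low_frac: float = 0.07
    mid_frac: float = 0.11
    depth_mean: float = 30.0               # Poisson mean per CpG per strand
    conversion_failure: float = 0.0016     # unmethylated C read as methylated
    meth_undercall: float = 0.0            # methylated C read as unmethylated
    miscall_rate: float = 0.005            # per-base miscall on G positions
    snp_rate: float = 0.05                 # fraction of CpGs destroyed
    exclude_dmrs: bool = True              # keep SNPs out of planted DMRs
    n_hypo: int = 20
    n_hyper: int = 10
    dmr_n_cpgs: int = 10
    dmr_width_bp: int = 2_000              # max span of a planted region
    dmr_delta: float = 0.4
    p_genic: float = 0.8                   # hypo effects inside expressed bodies
    frac_expressed: float = 0.6            # genes with mean FPKM >= 1
    n_expression_reps: int = 2
    n_replicates: int = 3
    read_length_classes: dict = field(
        default_factory=lambda: {"PE150": 150, "PE75": 75}
    )
    mbias_calls_per_pos: int = 5_000
    mbias_spec: dict = field(
        default_factory=lambda: {
            (1, "PE150"): {p: 0.10 for p in range(1, 6)},
            (2, "PE150"): {p: -0.08 for p in range(146, 151)},
            (1, "PE75"): {p: 0.10 for p in range(1, 6)},
            (2, "PE75"): {p: -0.08 for p in range(71, 76)},
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        weights = self.high_frac + self.low_frac + self.mid_frac
        if abs(weights - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {weights}")
        if not 0 <= self.conversion_failure < 0.05:
            raise ValueError("conversion_failure must be in [0, 0.05)")
        if not 0 < self.dmr_delta <= 1:
            raise ValueError("dmr_delta must be in (0, 1]")
        min_footprint = self.gene_length_mean // 2
        for chrom, length in self.chrom_lengths.items():
            if length < min_footprint:
                raise ValueError(
                    f"chromosome {chrom} ({length} bp) shorter than the "
                    f"minimal gene footprint ({min_footprint} bp)"
                )

    def all_chrom_lengths(self) -> dict:
        out = dict(self.chrom_lengths)
        out[SPIKE_IN_CHROM] = self.spike_in_length
        return out


@dataclass
class Reference:
    """Toy reference: CpG coordinates, gene models, islands, expression."""

    chrom_lengths: dict
    cpg_positions: dict            # chrom -> sorted int array of plus-strand C
    gene_models: list
    cpg_islands: list
    expression: pd.DataFrame       # gene_id + fpkm_rep* columns

    def n_cpgs(self, include_spike_in: bool = True) -> int:
        return sum(
            len(p) for c, p in self.cpg_positions.items()
            if include_spike_in or c != SPIKE_IN_CHROM
        )


@dataclass
class SyntheticTruth:
    """Ground truth: per-CpG methylation levels per genotype and planted features."""

    reference: Reference
    true_level_wt: dict            # chrom -> float array aligned to cpg_positions
    true_level_ko: dict = field(default_factory=dict)
    snp_sites: dict = field(default_factory=dict)   # chrom -> int array (subset)
    snp_alt_base: dict = field(default_factory=dict)  # (chrom, pos) -> base
    dmr_truth: list = field(default_factory=list)   # (GenomicInterval, direction)


@dataclass
class SimulatedData:
    """Per-replicate outputs of the pileup simulator."""

    truth: SyntheticTruth
    gbed: dict        # (group, replicate) -> G.bed DataFrame
    pileups: dict     # (group, replicate) -> pileup DataFrame
    mbias_table: pd.DataFrame

    def combined_pileup(self) -> pd.DataFrame:
        """Sum base counts over all groups/replicates (all runs, all samples)."""
        cat = pd.concat(self.pileups.values(), ignore_index=True)
        agg = cat.groupby(["chrom", "pos", "strand"], as_index=False)[
            ["nA", "nC", "nG", "nT", "nMeth", "nUnmeth"]
        ].sum()
        return agg[mio.PILEUP_COLUMNS]


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _draw_cpg_positions(
    rng: np.random.Generator, length: int, rate: float,
    islands: list[GenomicInterval], island_rate: float,
) -> np.ndarray:
    """Bernoulli CpG placement with elevated density inside islands.

    A CpG occupies [N, N+2); draws landing adjacent to a previous CpG are
    dropped so sites never overlap.
    """
    p = np.full(length, rate)
    for isl in islands:
        p[isl.start:isl.end] = island_rate
    p[length - 1] = 0.0  # the G would fall off the chromosome
    hits = np.nonzero(rng.random(length) < p)[0]
    if hits.size == 0:
        return hits
    keep = [int(hits[0])]
    for h in hits[1:]:
        if h > keep[-1] + 1:
            keep.append(int(h))
    return np.asarray(keep, dtype=np.int64)


def _draw_gene_models(
    rng: np.random.Generator, config: SimulationConfig
) -> list[GeneModel]:
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = np.maximum(
        1, np.round(config.n_genes * lengths / lengths.sum()).astype(int)
    )
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n in zip(chroms, n_per):
        clen = config.chrom_lengths[chrom]
        # non-overlapping spans: partition the chromosome into n slots
        bounds = np.linspace(0, clen, n + 1).astype(int)
        for i in range(n):
            slot_lo, slot_hi = int(bounds[i]), int(bounds[i + 1])
            span = int(
                np.clip(
                    rng.normal(config.gene_length_mean, config.gene_length_mean / 4),
                    2_000, max(2_000, (slot_hi - slot_lo) - 200),
                )
            )
            tx_start = int(rng.integers(slot_lo, max(slot_lo + 1, slot_hi - span)))
            tx_end = min(tx_start + span, slot_hi - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = max(1, int(rng.poisson(config.n_exons_mean)))
            cuts = np.sort(rng.choice(
                np.arange(tx_start + 1, tx_end - 1), size=min(2 * n_exons - 2,
                max(0, tx_end - tx_start - 2)), replace=False,
            )) if n_exons > 1 else np.array([], dtype=int)
            edges = np.concatenate(([tx_start], cuts, [tx_end]))
            exons = tuple(
                GenomicInterval(chrom, int(edges[k]), int(edges[k + 1]), strand)
                for k in range(0, len(edges) - 1, 2)
            )
            if strand == "+":
                tss, tes = tx_start, tx_end - 1
            else:
                tss, tes = tx_end - 1, tx_start
            genes.append(
                GeneModel(f"gene{gid:04d}", chrom, strand, tss, tes, exons)
            )
            gid += 1
    return genes


def _draw_expression(
    rng: np.random.Generator, genes: list[GeneModel], config: SimulationConfig
) -> pd.DataFrame:
    """FPKM per gene per replicate; frac_expressed of genes get mean >= 1."""
    n = len(genes)
    n_expr = int(round(config.frac_expressed * n))
    expressed = np.zeros(n, dtype=bool)
    expressed[rng.choice(n, size=n_expr, replace=False)] = True
    base = np.where(
        expressed,
        1.5 + rng.exponential(8.0, size=n),   # comfortably above threshold
        rng.uniform(0.0, 0.8, size=n),        # comfortably below
    )
    cols = {"gene_id": [g.gene_id for g in genes]}
    for r in range(config.n_expression_reps):
        jitter = rng.uniform(0.9, 1.1, size=n)
        cols[f"fpkm_rep{r + 1}"] = np.round(base * jitter, 4)
    return pd.DataFrame(cols)


def build_reference(config: SimulationConfig, rng=None) -> Reference:
    """Deterministically build the toy reference for a config."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    islands_by_chrom: dict[str, list[GenomicInterval]] = {}
    cpg_positions: dict[str, np.ndarray] = {}
    islands_all: list[GenomicInterval] = []
    for chrom in sorted(config.chrom_lengths):
        clen = config.chrom_lengths[chrom]
        slots = np.linspace(0, clen - config.island_length, config.n_islands_per_chrom + 2
                            ).astype(int)[1:-1]
        islands = [
            GenomicInterval(chrom, int(s), int(s) + config.island_length)
            for s in slots
        ]
        islands_by_chrom[chrom] = islands
        islands_all.extend(islands)
        cpg_positions[chrom] = _draw_cpg_positions(
            rng, clen, config.cpg_rate, islands, config.island_cpg_rate
        )
    cpg_positions[SPIKE_IN_CHROM] = _draw_cpg_positions(
        rng, config.spike_in_length, config.cpg_rate, [], config.cpg_rate
    )
    genes = _draw_gene_models(rng, config)
    expression = _draw_expression(rng, genes, config)
    return Reference(
        chrom_lengths=config.all_chrom_lengths(),
        cpg_positions=cpg_positions,
        gene_models=genes,
        cpg_islands=islands_all,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# Methylome and planted features
# ---------------------------------------------------------------------------

def _mixture_levels(rng: np.random.Generator, n: int, config: SimulationConfig
                    ) -> np.ndarray:
    """Three-component methylation mixture.

    Components are uniform with a small margin inside each class so that
    binomial sampling noise at realistic depth rarely carries a site across
    the 0.25 / 0.75 class boundaries.
    """
    comp = rng.choice(
        3, size=n, p=[config.high_frac, config.low_frac, config.mid_frac]
    )
    levels = np.empty(n)
    levels[comp == 0] = rng.uniform(0.80, 1.00, size=int((comp == 0).sum()))
    levels[comp == 1] = rng.uniform(0.00, 0.20, size=int((comp == 1).sum()))
    levels[comp == 2] = rng.uniform(0.30, 0.70, size=int((comp == 2).sum()))
    return levels


def draw_methylome(config: SimulationConfig, reference: Reference, rng=None
                   ) -> SyntheticTruth:
    """Draw wild-type per-CpG methylation levels; spike-in fixed at 0."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    levels: dict[str, np.ndarray] = {}
    for chrom in sorted(reference.cpg_positions):
        n = len(reference.cpg_positions[chrom])
        if chrom == SPIKE_IN_CHROM:
            levels[chrom] = np.zeros(n)
        else:
            levels[chrom] = _mixture_levels(rng, n, config)
    return SyntheticTruth(reference=reference, true_level_wt=levels)


def _candidate_regions(
    truth: SyntheticTruth, config: SimulationConfig, rng: np.random.Generator,
    genic: bool,
) -> tuple[str, int]:
    """Pick a (chrom, start-index) window of dmr_n_cpgs consecutive CpGs."""
    ref = truth.reference
    chroms = [c for c in sorted(ref.cpg_positions) if c != SPIKE_IN_CHROM]
    if genic:
        expr = ref.expression
        fpkm_cols = [c for c in expr.columns if c.startswith("fpkm")]
        expressed_ids = set(
            expr.loc[expr[fpkm_cols].mean(axis=1) >= 1.0, "gene_id"]
        )
        bodies = [
            g.body_interval() for g in ref.gene_models
            if g.gene_id in expressed_ids
        ]
        body = bodies[int(rng.integers(len(bodies)))]
        pos = ref.cpg_positions[body.chrom]
        lo = int(np.searchsorted(pos, body.start))
        hi = int(np.searchsorted(pos, body.end)) - config.dmr_n_cpgs
        if hi <= lo:
            return None
        return body.chrom, int(rng.integers(lo, hi))
    chrom = chroms[int(rng.integers(len(chroms)))]
    pos = ref.cpg_positions[chrom]
    if len(pos) <= config.dmr_n_cpgs:
        return None
    return chrom, int(rng.integers(0, len(pos) - config.dmr_n_cpgs))


def plant_effects(truth: SyntheticTruth, config: SimulationConfig, rng=None
                  ) -> SyntheticTruth:
    """Plant focal hypo-/hyper-methylation effects; returns a new truth.

    Knockout levels equal wild-type everywhere except inside the planted
    regions, where they are shifted by ``dmr_delta`` (down for hypo, up for
    hyper) and clipped to [0, 1]. Wild-type levels inside a planted region
    are resampled into a range that accommodates the full shift, so the
    planted |KO − WT| equals ``dmr_delta`` at every member CpG. Hypo effects
    land inside expressed gene bodies with probability ``p_genic``; hyper
    effects are placed uniformly.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    ref = truth.reference
    wt = {c: v.copy() for c, v in truth.true_level_wt.items()}
    ko = {c: v.copy() for c, v in wt.items()}
    placed: list[tuple[GenomicInterval, str]] = []
    delta = config.dmr_delta

    def try_place(direction: str) -> bool:
        genic = direction == "hypo" and rng.random() < config.p_genic
        cand = _candidate_regions(truth, config, rng, genic)
        if cand is None:
            return False
        chrom, i0 = cand
        pos = ref.cpg_positions[chrom]
        i1 = i0 + config.dmr_n_cpgs  # exclusive
        span = int(pos[i1 - 1] + 2 - pos[i0])
        if span > config.dmr_width_bp:
            return False
        iv = GenomicInterval(chrom, int(pos[i0]), int(pos[i1 - 1] + 2))
        if any(iv.overlaps(p_iv) for p_iv, _ in placed):
            return False
        idx = slice(i0, i1)
        if direction == "hypo":
            wt[chrom][idx] = rng.uniform(max(delta, 0.6), 1.0, i1 - i0)
            ko[chrom][idx] = np.clip(wt[chrom][idx] - delta, 0.0, 1.0)
        else:
            wt[chrom][idx] = rng.uniform(0.0, min(1 - delta, 0.4), i1 - i0)
            ko[chrom][idx] = np.clip(wt[chrom][idx] + delta, 0.0, 1.0)
        placed.append((iv, direction))
        return True

    for direction, count in (("hypo", config.n_hypo), ("hyper", config.n_hyper)):
        for k in range(count):
            for _ in range(1000):
                if try_place(direction):
                    break
            else:
                raise RuntimeError(
                    f"could not place {direction} region {k + 1}/{count} "
                    f"after 1000 attempts; genome too small for the request"
                )
    return replace(
        truth, true_level_wt=wt, true_level_ko=ko, dmr_truth=placed,
    )


def plant_cpg_snps(truth: SyntheticTruth, config: SimulationConfig, rng=None
                   ) -> SyntheticTruth:
    """Mark a fraction of reference CpGs as destroyed by polymorphism.

    At a destroyed site the sample genotype carries a non-G base at N+1 on
    the plus strand, so context validation must reject it. With
    ``exclude_dmrs`` the planted effect regions are never hit.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    ref = truth.reference
    snp_sites: dict[str, np.ndarray] = {}
    alt: dict[tuple, str] = {}
    dmr_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv, _ in truth.dmr_truth:
        dmr_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(ref.cpg_positions):
        if chrom == SPIKE_IN_CHROM:
            snp_sites[chrom] = np.array([], dtype=np.int64)
            continue
        pos = ref.cpg_positions[chrom]
        hit = rng.random(len(pos)) < config.snp_rate
        if config.exclude_dmrs and chrom in dmr_by_chrom:
            for iv in dmr_by_chrom[chrom]:
                inside = (pos >= iv.start) & (pos < iv.end)
                hit &= ~inside
        sites = pos[hit]
        snp_sites[chrom] = sites
        bases = rng.choice(np.array(["A", "C", "T"]), size=len(sites))
        for p, b in zip(sites, bases):
            alt[(chrom, int(p))] = str(b)
    return replace(truth, snp_sites=snp_sites, snp_alt_base=alt)


def build_truth(config: SimulationConfig) -> SyntheticTruth:
    """Reference + methylome + planted effects + polymorphisms in one call."""
    reference = build_reference(config)
    truth = draw_methylome(config, reference)
    truth = plant_effects(truth, config)
    truth = plant_cpg_snps(truth, config)
    return truth


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

def _base_counts(rng, depth: np.ndarray, true_base_idx: np.ndarray,
                 miscall: float) -> np.ndarray:
    """Multinomial base counts (n, 4) with a uniform miscall model."""
    n = len(depth)
    counts = np.zeros((n, 4), dtype=np.int64)
    correct = rng.binomial(depth, 1.0 - miscall)
    counts[np.arange(n), true_base_idx] = correct
    errors = depth - correct
    if errors.max(initial=0) > 0:
        err_split = rng.multinomial(errors, [1 / 3] * 3)
        for true_idx in range(4):
            mask = true_base_idx == true_idx
            if not mask.any():
                continue
            others = [b for b in range(4) if b != true_idx]
            counts[np.ix_(np.nonzero(mask)[0], others)] += err_split[mask]
    return counts


def simulate_pileups(truth: SyntheticTruth, config: SimulationConfig, rng=None
                     ) -> SimulatedData:
    """Draw per-replicate G.bed tables, strand-split base pileups, and the
    M-bias call table.

    Per CpG and strand, depth ~ Poisson(depth_mean) and the methylated count
    is Binomial(depth, q) with
    ``q = level * (1 - meth_undercall) + (1 - level) * conversion_failure``.
    Base pileups cover the four (position, strand) coordinates of each CpG;
    at polymorphic sites the plus-strand N+1 base is the configured
    alternate instead of G.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    ref = truth.reference
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    groups = {"wt": truth.true_level_wt, "ko": truth.true_level_ko or truth.true_level_wt}

    gbed: dict[tuple, pd.DataFrame] = {}
    pileups: dict[tuple, pd.DataFrame] = {}

    for group, levels_by_chrom in groups.items():
        for rep in range(1, config.n_replicates + 1):
            g_rows = []
            p_rows = []
            for chrom in sorted(ref.cpg_positions):
                pos = ref.cpg_positions[chrom]
                n = len(pos)
                if n == 0:
                    continue
                level = levels_by_chrom[chrom]
                q = level * (1.0 - config.meth_undercall) + (
                    1.0 - level
                ) * config.conversion_failure
                depth_p = rng.poisson(config.depth_mean, n)
                depth_m = rng.poisson(config.depth_mean, n)
                meth_p = rng.binomial(depth_p, q)
                meth_m = rng.binomial(depth_m, q)

                total = depth_p + depth_m
                meth = meth_p + meth_m
                ratio = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
                g_rows.append(pd.DataFrame({
                    "chrom": chrom, "start": pos, "end": pos + 2,
                    "ratio": ratio, "total": total, "meth": meth,
                }))

                # Base pileups at the four CpG coordinates. True bases:
                #   (N, +)   = C (methylated) / T (converted)
                #   (N+1, +) = G, or the alternate base at a polymorphic site
                #   (N, -)   = G (opposite the plus-strand C)
                #   (N+1, -) = C (methylated) / T (converted)
                snp = truth.snp_sites.get(chrom, np.array([], dtype=np.int64))
                is_snp = np.isin(pos, snp)
                plus_g_idx = np.full(n, base_idx["G"])
                for i in np.nonzero(is_snp)[0]:
                    plus_g_idx[i] = base_idx[
                        truth.snp_alt_base[(chrom, int(pos[i]))]
                    ]
                depth_gp = rng.poisson(config.depth_mean, n)
                depth_gm = rng.poisson(config.depth_mean, n)
                cnt_gp = _base_counts(rng, depth_gp, plus_g_idx, config.miscall_rate)
                cnt_gm = _base_counts(
                    rng, depth_gm, np.full(n, base_idx["G"]), config.miscall_rate
                )

                def frame(p, strand, nA, nC, nG, nT, nMeth, nUnmeth):
                    return pd.DataFrame({
                        "chrom": chrom, "pos": p, "strand": strand,
                        "nA": nA, "nC": nC, "nG": nG, "nT": nT,
                        "nMeth": nMeth, "nUnmeth": nUnmeth,
                    })

                zeros = np.zeros(n, dtype=np.int64)
                p_rows.extend([
                    frame(pos, "+", zeros, meth_p, zeros, depth_p - meth_p,
                          meth_p, depth_p - meth_p),
                    frame(pos + 1, "+", cnt_gp[:, 0], cnt_gp[:, 1],
                          cnt_gp[:, 2], cnt_gp[:, 3], zeros, zeros),
                    frame(pos, "-", cnt_gm[:, 0], cnt_gm[:, 1],
                          cnt_gm[:, 2], cnt_gm[:, 3], zeros, zeros),
                    frame(pos + 1, "-", zeros, meth_m, zeros, depth_m - meth_m,
                          meth_m, depth_m - meth_m),
                ])
            gdf = pd.concat(g_rows, ignore_index=True)
            gdf = gdf.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            pdf = pd.concat(p_rows, ignore_index=True)
            pdf = pdf.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
            gbed[(group, rep)] = gdf
            pileups[(group, rep)] = pdf

    mbias_table = _simulate_mbias_table(truth, config, rng)
    return SimulatedData(truth=truth, gbed=gbed, pileups=pileups,
                         mbias_table=mbias_table)


def _simulate_mbias_table(truth: SyntheticTruth, config: SimulationConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Aggregate per-read-position methylation calls with planted bias.

    The genome-wide mean apparent methylation level is perturbed additively
    at the positions named in ``mbias_spec``; per position, calls are
    Binomial(mbias_calls_per_pos, clipped level).
    """
    levels = np.concatenate([
        v for c, v in sorted(truth.true_level_wt.items()) if c != SPIKE_IN_CHROM
    ])
    base = float(np.mean(
        levels * (1 - config.meth_undercall)
        + (1 - levels) * config.conversion_failure
    ))
    rows = []
    for lc, length in sorted(config.read_length_classes.items()):
        for mate in (1, 2):
            bias = config.mbias_spec.get((mate, lc), {})
            for p in range(1, length + 1):
                lvl = float(np.clip(base + bias.get(p, 0.0), 0.0, 1.0))
                ncalls = config.mbias_calls_per_pos
                nmeth = int(rng.binomial(ncalls, lvl))
                rows.append((mate, lc, p, nmeth, ncalls - nmeth))
    return pd.DataFrame(rows, columns=mio.MBIAS_COLUMNS)


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------

def write_outputs(data: SimulatedData, outdir) -> Path:
    """Write every simulator product under ``outdir`` (see module docs)."""
    out = mio.ensure_dir(outdir)
    truth = data.truth
    ref = truth.reference
    for (group, rep), gdf in sorted(data.gbed.items()):
        mio.write_gbed(gdf, out / f"{group}_rep{rep}.G.bed")
    for (group, rep), pdf in sorted(data.pileups.items()):
        mio.write_pileup(pdf, out / f"{group}_rep{rep}.pileup.tsv")
    mio.write_mbias_table(data.mbias_table, out / "mbias_calls.tsv")
    mio.write_gene_models(ref.gene_models, out / "gene_models.tsv")
    mio.write_bed(ref.cpg_islands, out / "cpg_islands.bed", bed6=False)
    mio.write_expression(ref.expression, out / "expression.tsv")
    cpg_rows = [
        GenomicInterval(c, int(p), int(p) + 2)
        for c in sorted(ref.cpg_positions) for p in ref.cpg_positions[c]
    ]
    mio.write_bed(cpg_rows, out / "reference_cpgs.bed", bed6=False)
    mio.write_bed(
        [GenomicInterval(c, int(p), int(p) + 2)
         for c in sorted(truth.snp_sites) for p in truth.snp_sites[c]],
        out / "truth_snp_sites.bed", bed6=False,
    )
    mio.write_bed(
        [GenomicInterval(iv.chrom, iv.start, iv.end, ".", direction)
         for iv, direction in truth.dmr_truth],
        out / "truth_dmrs.bed",
    )
    truth_rows = []
    for chrom in sorted(ref.cpg_positions):
        pos = ref.cpg_positions[chrom]
        ko = truth.true_level_ko.get(chrom, truth.true_level_wt[chrom])
        for p, w, k in zip(pos, truth.true_level_wt[chrom], ko):
            truth_rows.append((chrom, int(p), round(float(w), 6), round(float(k), 6)))
    pd.DataFrame(
        truth_rows, columns=["chrom", "cpg_start", "level_wt", "level_ko"]
    ).to_csv(out / "truth_levels.tsv", sep="\t", index=False)
    return out


def simulate_study(config: SimulationConfig, outdir=None) -> SimulatedData:
    """Full simulation: truth, pileups, and (optionally) on-disk outputs."""
    truth = build_truth(config)
    data = simulate_pileups(truth, config)
    if outdir is not None:
        write_outputs(data, outdir)
    return data
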