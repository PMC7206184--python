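"""Locus definition, gene annotation, and matched-null enrichment testing.

Genome-wide significant variants are grouped into loci by greedy LD
clumping (ascending p; correlated significant neighbours join the lead,
uncorrelated significant neighbours inside the window are recorded as
secondary, allelically heterogeneous signals).  Each locus is annotated
with its nearest gene.  Enrichment of lead SNPs near a Mendelian
cardiomyopathy gene panel is assessed against null SNP sets matched on
minor-allele frequency, LD-buddy count, distance to the nearest gene and
local gene density, with a one-tailed permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class ClumpConfig:
    p_threshold: float = 5e-8
    r2_threshold: float = 0.2
    window_kb: float = 500.0
    stringent_p: float = 5e-9  # optional sensitivity threshold

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class Locus:
    lead_snp: str
    chrom: int
    lead_pos: int
    lead_p: float
    member_snps: list[str] = field(default_factory=list)
    secondary_snps: list[str] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)
    nearest_gene: str | None = None
    nearest_gene_distance: int | None = None
    nearest_gene_tie: bool = False


def ld_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    gi = panel.dosages[:, i]
    gj = panel.dosages[:, j]
    if gi.std() == 0 or gj.std() == 0:
        raise ValueError("monomorphic variant has no defined LD")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def clump_loci(
    sumstats: pd.DataFrame, panel: GenotypePanel, config: ClumpConfig | None = None
) -> list[Locus]:
    """Greedy LD clumping of genome-wide significant variants into loci.

    Significant variants are taken best-first (ascending p).  Each lead
    absorbs, as members, the significant variants within ``window_kb`` whose
    r^2 with the lead reaches ``r2_threshold``; significant variants inside
    the window but below the r^2 threshold are attached as secondary
    (independent) signals of the locus rather than seeding further loci, so
    lead SNPs of distinct loci are always more than a window apart.
    """
    cfg = config or ClumpConfig()
    if len(sumstats) != panel.n_variants:
        raise ValueError("sumstats and panel are not aligned")
    p = sumstats["P"].to_numpy(dtype=float)
    chrom = sumstats["CHR"].to_numpy()
    pos = sumstats["POS"].to_numpy(dtype=int)
    ids = sumstats["ID"].to_numpy()
    sig = np.flatnonzero(p < cfg.p_threshold)
    order = sig[np.argsort(p[sig], kind="stable")]
    window = cfg.window_kb * 1000.0

    assigned = np.zeros(panel.n_variants, dtype=bool)
    loci: list[Locus] = []
    for lead in order:
        if assigned[lead]:
            continue
        assigned[lead] = True
        members, secondary = [], []
        near = [
            j
            for j in order
            if not assigned[j]
            and chrom[j] == chrom[lead]
            and abs(int(pos[j]) - int(pos[lead])) <= window
        ]
        for j in near:
            if ld_r2(panel, lead, j) >= cfg.r2_threshold:
                members.append(j)
            else:
                secondary.append(j)
            assigned[j] = True
        span_idx = [lead] + members + secondary
        loci.append(
            Locus(
                lead_snp=str(ids[lead]),
                chrom=int(chrom[lead]),
                lead_pos=int(pos[lead]),
                lead_p=float(p[lead]),
                member_snps=[str(ids[j]) for j in members],
                secondary_snps=[str(ids[j]) for j in secondary],
                span=(int(pos[span_idx].min()), int(pos[span_idx].max())),
            )
        )
    return loci


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a 1-based position to a 1-based inclusive interval."""
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def annotate_nearest_gene(loci: list[Locus], gene_map: pd.DataFrame) -> list[Locus]:
    """Annotate each locus with the gene nearest its lead SNP.

    ``gene_map`` is internal 1-based inclusive with columns
    ``chrom, start, end, gene``.  Distance is to the gene interval (0 when
    the SNP is inside the gene body); ties go to the gene with the smaller
    start coordinate, and the tie is recorded.
    """
    if gene_map.empty:
        raise ValueError("gene map is empty")
    out = []
    for locus in loci:
        genes = gene_map[gene_map["chrom"] == locus.chrom]
        if genes.empty:
            genes = gene_map
        d = np.array(
            [
                _interval_distance(locus.lead_pos, int(s), int(e))
                for s, e in zip(genes["start"], genes["end"])
            ]
        )
        best = d.min()
        cand = genes.iloc[np.flatnonzero(d == best)].sort_values("start")
        locus.nearest_gene = str(cand.iloc[0]["gene"])
        locus.nearest_gene_distance = int(best)
        locus.nearest_gene_tie = len(cand) > 1
        out.append(locus)
    return out


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lead_snp": [x.lead_snp for x in loci],
            "chrom": [x.chrom for x in loci],
            "lead_pos": [x.lead_pos for x in loci],
            "lead_p": [x.lead_p for x in loci],
            "n_members": [len(x.member_snps) for x in loci],
            "n_secondary": [len(x.secondary_snps) for x in loci],
            "span_start": [x.span[0] for x in loci],
            "span_end": [x.span[1] for x in loci],
            "nearest_gene": [x.nearest_gene for x in loci],
            "nearest_gene_distance": [x.nearest_gene_distance for x in loci],
            "nearest_gene_tie": [x.nearest_gene_tie for x in loci],
            "member_snps": [",".join(x.member_snps) for x in loci],
            "secondary_snps": [",".join(x.secondary_snps) for x in loci],
        }
    )


def matching_properties(
    panel: GenotypePanel,
    gene_map: pd.DataFrame,
    window_kb: float = 500.0,
    buddy_r2: float = 0.5,
) -> pd.DataFrame:
    """Per-SNP properties used to match null SNPs to lead SNPs.

    For every variant: minor-allele frequency, number of LD buddies
    (r^2 >= ``buddy_r2`` within ``window_kb``), distance to the nearest gene
    interval, and gene density (genes whose interval overlaps the window).
    Computed identically for lead and candidate null SNPs.
    """
    window = window_kb * 1000.0
    maf = panel.realized_maf()
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy(dtype=int)
    z = panel.standardized()
    n = panel.n_samples

    buddies = np.zeros(panel.n_variants, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        zc = z[:, idx]
        r2 = (zc.T @ zc / n) ** 2
        within = np.abs(pos[idx][:, None] - pos[idx][None, :]) <= window
        np.fill_diagonal(within, False)
        buddies[idx] = ((r2 >= buddy_r2) & within).sum(axis=1)

    gene_dist = np.zeros(panel.n_variants, dtype=int)
    density = np.zeros(panel.n_variants, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        genes = gene_map[gene_map["chrom"] == c]
        if genes.empty:
            gene_dist[idx] = 10**9
            continue
        gs = genes["start"].to_numpy(dtype=int)
        ge = genes["end"].to_numpy(dtype=int)
        for i in idx:
            d = np.where(
                (gs <= pos[i]) & (pos[i] <= ge),
                0,
                np.minimum(np.abs(gs - pos[i]), np.abs(ge - pos[i])),
            )
            gene_dist[i] = int(d.min())
            density[i] = int(((gs <= pos[i] + window) & (ge >= pos[i] - window)).sum())
    return pd.DataFrame(
        {
            "id": panel.variants["id"],
            "maf": maf,
            "n_ld_buddies": buddies,
            "dist_to_nearest_gene": gene_dist,
            "gene_density": density,
        }
    )


@dataclass
class MatchTolerances:
    maf_abs: float = 0.02
    buddies_rel: float = 0.20
    gene_dist_rel: float = 0.20
    gene_density_rel: float = 0.20

    def widened(self, factor: float = 2.0) -> "MatchTolerances":
        return MatchTolerances(
            self.maf_abs * factor,
            self.buddies_rel * factor,
            self.gene_dist_rel * factor,
            self.gene_density_rel * factor,
        )


def _admissible_pool(
    lead_row: pd.Series, props: pd.DataFrame, tol: MatchTolerances, exclude: np.ndarray
) -> np.ndarray:
    ok = np.abs(props["maf"].to_numpy() - lead_row["maf"]) <= tol.maf_abs
    for col, rel, floor in (
        ("n_ld_buddies", tol.buddies_rel, 1.0),
        ("dist_to_nearest_gene", tol.gene_dist_rel, 1.0),
        ("gene_density", tol.gene_density_rel, 1.0),
    ):
        band = max(rel * float(lead_row[col]), floor)
        ok &= np.abs(props[col].to_numpy() - float(lead_row[col])) <= band
    ok &= ~exclude
    return np.flatnonzero(ok)


def matched_null_sets(
    lead_indices: np.ndarray,
    properties: pd.DataFrame,
    n_sets: int = 10_000,
    tolerances: MatchTolerances | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n_sets`` null SNP sets matched to the lead SNPs.

    For each set, every lead is replaced by a pool SNP whose four matching
    properties fall within the tolerance bins of the lead's; lead SNPs are
    excluded from all pools, and SNPs are not reused within one set.  A lead
    whose pool is thinner than ``n_sets / 10`` has its tolerances doubled
    (with a warning), at most twice; an empty pool after widening raises.
    """
    tol = tolerances or MatchTolerances()
    leads = np.asarray(lead_indices, dtype=int)
    if leads.size == 0:
        raise ValueError("no lead SNPs to match")
    is_lead = np.zeros(len(properties), dtype=bool)
    is_lead[leads] = True

    pools: list[np.ndarray] = []
    for li in leads:
        t = tol
        pool = _admissible_pool(properties.iloc[li], properties, t, is_lead)
        for _ in range(2):
            if pool.size >= max(1, n_sets // 10):
                break
            t = t.widened()
            warnings.warn(
                f"thin matching pool for lead index {li} ({pool.size} SNPs); "
                "widening tolerances",
                stacklevel=2,
            )
            pool = _admissible_pool(properties.iloc[li], properties, t, is_lead)
        if pool.size == 0:
            raise ValueError(f"empty matching pool for lead index {li} after widening")
        pools.append(pool)

    rng = np.random.default_rng(seed)
    out = np.empty((n_sets, leads.size), dtype=int)
    for s in range(n_sets):
        used: set[int] = set()
        for k, pool in enumerate(pools):
            avail = pool[~np.isin(pool, list(used))] if used else pool
            if avail.size == 0:
                avail = pool  # fall back to reuse rather than fail mid-set
            choice = int(rng.choice(avail))
            out[s, k] = choice
            used.add(choice)
    return out


def gene_panel_overlap(
    snp_chrom: np.ndarray,
    snp_pos: np.ndarray,
    gene_map: pd.DataFrame,
    panel_genes: list[str],
    radius_kb: float = 500.0,
) -> int:
    """Count SNPs lying within ``radius_kb`` of any panel-gene interval
    (interval inflated by the radius on both sides, boundary inclusive)."""
    radius = radius_kb * 1000.0
    genes = gene_map[gene_map["gene"].isin(panel_genes)]
    count = 0
    for c, p in zip(np.asarray(snp_chrom), np.asarray(snp_pos)):
        g = genes[genes["chrom"] == c]
        if g.empty:
            continue
        hit = (
            (g["start"].to_numpy() - radius <= p) & (p <= g["end"].to_numpy() + radius)
        ).any()
        count += bool(hit)
    return count


def permutation_enrichment_p(observed: int, null_overlaps: np.ndarray) -> float:
    """One-tailed permutation p with the add-one convention:
    ``(1 + #{null >= observed}) / (1 + n_sets)``."""
    nulls = np.asarray(null_overlaps)
    if nulls.size == 0:
        raise ValueError("no null overlaps supplied")
    return float((1 + (nulls >= observed).sum()) / (1 + nulls.size))


def enrichment_report(observed: int, null_overlaps: np.ndarray) -> pd.DataFrame:
    nulls = np.asarray(null_overlaps, dtype=float)
    return pd.DataFrame(
        {
            "observed": [observed],
            "null_mean": [nulls.mean()],
            "null_sd": [nulls.std(ddof=1) if nulls.size > 1 else 0.0],
            "n_sets": [nulls.size],
            "p_one_tailed": [permutation_enrichment_p(observed, nulls)],
        }
    )


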