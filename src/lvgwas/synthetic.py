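"""Synthetic cohort generator.

Emulates the statistical structure of an imaging-genetics biobank study:
LD-blocked imputed genotype dosages, additive polygenic left-ventricular
volumes with covariate and scanner-batch effects, proportional-hazards
incident-disease outcomes driven by a true genetic score, binary comorbidity
phenotypes for PheWAS, and rare truncating-variant carrier flags.

Every generator is deterministic under the configured seed.  A single master
seed fans out to per-component child seeds by fixed offsets, so adding one
component to a run never perturbs the draws of another.

The LD model is a Gaussian copula: a latent multivariate normal with
equicorrelated blocks is thresholded per haplotype at the allele-frequency
quantile and the two haplotypes summed to a dosage.  Thresholding attenuates
the latent correlation, so the realized dosage correlation within a block is
somewhat below ``within_block_r``; the ``r = 0`` case is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

# fixed child-seed offsets (single master seed fans out; see module docstring)
_SEED_GENO = 1
_SEED_PHENO = 2
_SEED_OUTCOME = 3
_SEED_CARRIER = 4
_SEED_GENEMAP = 5

_MOD = 2**31


def _child_rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % _MOD)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort the pipeline is designed around: a mean MRI age
    of 64 years, female/male mean LVEDV of 120/150 mL and LVESV of 41/58 mL,
    a truncating-variant carrier frequency of ~0.5%, and a hazard ratio of
    1.58 per SD of the true score for the incident-disease outcome.
    """

    n_samples: int = 2000
    n_variants: int = 1000
    ld_block_size: int = 20
    within_block_r: float = 0.6
    maf_range: tuple[float, float] = (0.01, 0.5)
    h2_target: float = 0.4
    n_causal: int = 100
    genetic_corr: float = 0.65
    batch_effect_sd: float = 2.0
    hr_per_sd: float = 1.58
    censoring_rate: float = 0.98
    carrier_freq: float = 0.005
    seed: int = 0
    # trait-scale parameters (mL); residual scale of LVEDV/LVESV after the
    # sex/age baseline is removed
    lvedv_sd: float = 21.0
    lvesv_sd: float = 12.0
    female_lvedv_mean: float = 120.0
    male_lvedv_mean: float = 150.0
    female_lvesv_mean: float = 41.0
    male_lvesv_mean: float = 58.0
    n_scanners: int = 3
    dosage_jitter: float = 0.04

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0 or self.ld_block_size <= 0:
            raise ValueError("n_samples, n_variants and ld_block_size must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must be in [0, 1)")
        if not (0.0 <= self.h2_target < 1.0):
            raise ValueError("h2_target must be in [0, 1)")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not (0.0 < self.carrier_freq <= 0.05):
            raise ValueError("carrier_freq must be in (0, 0.05]")
        if self.hr_per_sd <= 0:
            raise ValueError("hr_per_sd must be positive")


def simulate_genotypes(
    config: SimulationConfig, template_variants: pd.DataFrame | None = None
) -> GenotypePanel:
    """Draw an LD-blocked diploid dosage panel.

    Within each block of ``ld_block_size`` variants the latent haplotype
    normals are equicorrelated at ``within_block_r``; blocks are independent.
    A small uniform jitter emulates imputation noise (clipped to [0, 2]);
    the recorded INFO is the assigned, not realized, imputation quality so
    that INFO filtering is deterministic.

    Passing ``template_variants`` reuses an existing panel's variant table
    (alleles, frequencies, positions) and draws only new samples — the
    "same genotyping panel, different cohort" scenario used when scoring an
    independent outcome cohort.
    """
    rng = _child_rng(config.seed, _SEED_GENO)
    n = config.n_samples
    if template_variants is not None:
        m = len(template_variants)
        mafs = template_variants["maf"].to_numpy(dtype=float)
    else:
        m = config.n_variants
        mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    r = config.within_block_r

    dosage = np.zeros((n, m))
    thresholds = stats.norm.ppf(mafs)
    for hap in range(2):
        z = rng.standard_normal((n, m))
        if r > 0:
            start = 0
            while start < m:
                stop = min(start + config.ld_block_size, m)
                shared = rng.standard_normal(n)
                z[:, start:stop] = (
                    np.sqrt(r) * shared[:, None] + np.sqrt(1.0 - r) * z[:, start:stop]
                )
                start = stop
        dosage += (z < thresholds[None, :]).astype(float)

    if config.dosage_jitter > 0:
        dosage = dosage + rng.uniform(-config.dosage_jitter, config.dosage_jitter, size=(n, m))
        dosage = np.clip(dosage, 0.0, 2.0)

    if template_variants is not None:
        return GenotypePanel(dosages=dosage, variants=template_variants.copy())

    # variant metadata: spread blocks over chromosomes, 1-based increasing pos
    n_blocks = int(np.ceil(m / config.ld_block_size))
    n_chrom = min(22, n_blocks)
    blocks_per_chrom = int(np.ceil(n_blocks / n_chrom))
    chroms = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    i = 0
    for b in range(n_blocks):
        c = b // blocks_per_chrom + 1
        size = min(config.ld_block_size, m - i)
        first_of_chrom = b % blocks_per_chrom == 0
        base = 10_000 if first_of_chrom else pos[i - 1]
        steps = rng.integers(2_000, 8_000, size=size)
        pos[i : i + size] = base + np.cumsum(steps)
        chroms[i : i + size] = c
        i += size

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=m)
    alt = np.array([rng.choice([b for b in "ACGT" if b != rf]) for rf in ref])
    variants = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": mafs,
            "info": rng.uniform(0.31, 1.0, size=m),
            "call_rate": rng.uniform(0.96, 1.0, size=m),
        }
    )
    return GenotypePanel(dosages=dosage, variants=variants)


@dataclass
class PhenotypeTruth:
    """Ground truth of a phenotype simulation, for parameter-recovery checks."""

    causal_index: np.ndarray
    genetic_score_lvedv: np.ndarray
    genetic_score_lvesv: np.ndarray
    realized_h2_lvedv: float
    realized_h2_lvesv: float
    realized_genetic_corr: float


def simulate_lv_phenotypes(
    panel: GenotypePanel, config: SimulationConfig
) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Simulate raw LV volumes plus covariates on top of a genotype panel.

    LVEDV is a sex/age baseline plus an additive genetic score over
    ``n_causal`` standardized dosages, a scanner batch effect, and Gaussian
    noise, with variance components scaled so the genetic fraction of the
    residual (baseline-removed) variance equals ``h2_target``.  LVESV shares
    genetics with LVEDV at ``genetic_corr``.  Samples violating
    LVESV < LVEDV have their noise redrawn.
    """
    if panel.n_samples != config.n_samples:
        raise ValueError("panel sample count does not match config")
    rng = _child_rng(config.seed, _SEED_PHENO)
    n = config.n_samples

    sex = (rng.random(n) < 0.471).astype(int)  # 1 = male; majority female
    age = np.clip(rng.normal(64.0, 7.5, size=n), 45, 82)
    mri_year = rng.integers(2014, 2019, size=n)
    birth_year = mri_year - np.round(age).astype(int)
    scanner = rng.integers(0, config.n_scanners, size=n)
    height = np.where(sex == 1, rng.normal(176, 7, n), rng.normal(162, 6, n))
    weight = np.where(sex == 1, rng.normal(82, 13, n), rng.normal(70, 12, n))
    weight = np.clip(weight, 35, None)
    pcs = rng.standard_normal((n, 5))

    causal = rng.choice(panel.n_variants, size=config.n_causal, replace=False)
    zc = panel.standardized()[:, causal]
    eff1 = rng.standard_normal(config.n_causal)
    eff2 = rng.standard_normal(config.n_causal)

    def _std(v: np.ndarray) -> np.ndarray:
        s = v.std()
        return (v - v.mean()) / (s if s > 0 else 1.0)

    g1 = _std(zc @ eff1)
    g_ind = _std(zc @ eff2)
    rg = config.genetic_corr
    g2 = rg * g1 + np.sqrt(max(0.0, 1.0 - rg**2)) * g_ind

    def _assemble(total_sd: float, g: np.ndarray, baseline: np.ndarray) -> np.ndarray:
        var_g = config.h2_target * total_sd**2
        var_batch = config.batch_effect_sd**2
        var_e = total_sd**2 - var_g - var_batch
        if var_e <= 0:
            raise ValueError("h2_target and batch_effect_sd exceed the trait variance")
        batch_shift = rng.normal(0.0, config.batch_effect_sd, size=config.n_scanners)
        noise = rng.normal(0.0, np.sqrt(var_e), size=n)
        return baseline + np.sqrt(var_g) * g + batch_shift[scanner] + noise, noise, np.sqrt(var_e)

    base_edv = np.where(
        sex == 1, config.male_lvedv_mean, config.female_lvedv_mean
    ) - 0.35 * (age - 64.0)
    base_esv = np.where(
        sex == 1, config.male_lvesv_mean, config.female_lvesv_mean
    ) - 0.20 * (age - 64.0)

    lvedv, noise1, sd_e1 = _assemble(config.lvedv_sd, g1, base_edv)
    lvesv, noise2, sd_e2 = _assemble(config.lvesv_sd, g2, base_esv)

    # enforce physiologic ordering: redraw noise for violators
    for _ in range(60):
        bad = (lvesv >= lvedv) | (lvesv < 1.0)
        if bad.mean() < 0.001 or not bad.any():
            break
        k = int(bad.sum())
        lvedv[bad] = lvedv[bad] - noise1[bad]
        lvesv[bad] = lvesv[bad] - noise2[bad]
        noise1[bad] = rng.normal(0.0, sd_e1, size=k)
        noise2[bad] = rng.normal(0.0, sd_e2, size=k)
        lvedv[bad] += noise1[bad]
        lvesv[bad] += noise2[bad]

    g1_scaled = np.sqrt(config.h2_target) * config.lvedv_sd * g1
    g2_scaled = np.sqrt(config.h2_target) * config.lvesv_sd * g2
    resid1 = lvedv - base_edv
    resid2 = lvesv - base_esv
    truth = PhenotypeTruth(
        causal_index=causal,
        genetic_score_lvedv=g1_scaled,
        genetic_score_lvesv=g2_scaled,
        realized_h2_lvedv=float(np.var(g1_scaled) / np.var(resid1)),
        realized_h2_lvesv=float(np.var(g2_scaled) / np.var(resid2)),
        realized_genetic_corr=float(np.corrcoef(g1, g2)[0, 1]),
    )
    cohort = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "lvedv_ml": lvedv,
            "lvesv_ml": lvesv,
            "height_cm": height,
            "weight_kg": weight,
            "sex": sex,
            "age_at_mri": age,
            "birth_year": birth_year,
            "scanner_id": scanner,
            **{f"pc{i + 1}": pcs[:, i] for i in range(5)},
        }
    )
    return cohort, truth


#: default comorbidity phenotypes: (logit intercept, loading per SD of score)
DEFAULT_PHEWAS_PHENOTYPES: dict[str, tuple[float, float]] = {
    "dilated_cardiomyopathy": (-3.2, np.log(1.51)),
    "hypothyroidism": (-2.6, -0.15),
    "psoriasis": (-3.0, -0.10),
    "null_pheno_1": (-2.4, 0.0),
    "null_pheno_2": (-3.0, 0.0),
}


@dataclass
class OutcomeTable:
    """Per-sample follow-up, event status, covariates and binary phenotypes."""

    frame: pd.DataFrame  # follow_up_years, event, age_at_enroll, sex, array_batch, pc1..pc5
    phenotypes: pd.DataFrame  # one binary column per comorbidity phenotype

    def case_counts(self) -> pd.Series:
        return self.phenotypes.sum(axis=0).astype(int)


def simulate_outcomes(
    true_score: np.ndarray,
    config: SimulationConfig,
    phewas_phenotypes: dict[str, tuple[float, float]] | None = None,
) -> OutcomeTable:
    """Draw proportional-hazards event times and binary comorbidities.

    The hazard is ``lambda0 * exp(log(hr_per_sd) * z)`` for standardized true
    score ``z``; administrative censoring at the empirical quantile of the
    latent event times yields approximately ``censoring_rate`` censored.
    Binary phenotypes come from per-phenotype logistic models whose loadings
    may be zero (null phenotypes for calibration).
    """
    rng = _child_rng(config.seed, _SEED_OUTCOME)
    score = np.asarray(true_score, dtype=float)
    n = score.size
    sd = score.std()
    z = (score - score.mean()) / (sd if sd > 0 else 1.0)

    log_hr = np.log(config.hr_per_sd)
    lam0 = 0.002  # baseline events per person-year; scale is absorbed by censoring
    t_latent = rng.exponential(1.0, size=n) / (lam0 * np.exp(log_hr * z))
    c_admin = np.quantile(t_latent, 1.0 - config.censoring_rate)
    event = t_latent <= c_admin
    follow_up = np.minimum(t_latent, c_admin)
    follow_up = np.maximum(follow_up, 1e-6)

    frame = pd.DataFrame(
        {
            "follow_up_years": follow_up,
            "event": event.astype(int),
            "age_at_enroll": np.clip(rng.normal(57.0, 8.0, size=n), 40, 72),
            "sex": rng.integers(0, 2, size=n),
            "array_batch": rng.integers(0, 2, size=n),
            **{f"pc{i + 1}": rng.standard_normal(n) for i in range(5)},
        }
    )
    phen = phewas_phenotypes if phewas_phenotypes is not None else DEFAULT_PHEWAS_PHENOTYPES
    cols = {}
    for name, (intercept, loading) in phen.items():
        p = 1.0 / (1.0 + np.exp(-(intercept + loading * z)))
        cols[name] = (rng.random(n) < p).astype(int)
    return OutcomeTable(frame=frame, phenotypes=pd.DataFrame(cols))


def spike_rare_carriers(
    n_samples: int,
    config: SimulationConfig,
) -> tuple[np.ndarray, dict[str, float]]:
    """Flag rare truncating-variant carriers and return their trait offsets.

    Carrier status is Bernoulli(``carrier_freq``).  The default offsets add
    +11.8 mL LVEDV and +7.7 mL LVESV to carriers' raw volumes; at typical
    female volumes this induces the expected ~-2.8 percentage-point LVEF
    change through the derived-trait identities, so no separate LVEF offset
    is applied to the volumes.
    """
    rng = _child_rng(config.seed, _SEED_CARRIER)
    flags = rng.random(n_samples) < config.carrier_freq
    offsets = {"lvedv_ml": 11.8, "lvesv_ml": 7.7}
    return flags, offsets


def apply_carrier_offsets(
    cohort: pd.DataFrame, flags: np.ndarray, offsets: dict[str, float]
) -> pd.DataFrame:
    """Add per-trait carrier offsets to the flagged rows of a cohort table."""
    out = cohort.copy()
    for col, delta in offsets.items():
        if col not in out.columns:
            raise KeyError(f"cohort table has no column {col!r}")
        out.loc[np.asarray(flags, dtype=bool), col] += delta
    out["ttntv_carrier"] = np.asarray(flags, dtype=int)
    return out


def make_gene_map(
    panel: GenotypePanel,
    n_genes: int = 60,
    n_panel_genes: int = 12,
    panel_near_variants: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a BED-like gene map (0-based half-open) over the panel's span.

    Genes are placed uniformly along each chromosome's variant span;
    ``n_panel_genes`` are flagged as members of the Mendelian cardiomyopathy
    panel.  If ``panel_near_variants`` gives variant indices, panel genes are
    placed on top of those variants (used to build enriched instances).
    """
    rng = _child_rng(seed, _SEED_GENEMAP)
    rows = []
    gene_i = 0
    for chrom, grp in panel.variants.groupby("chrom", sort=True):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        span = max(hi - lo, 10_000)
        k = max(1, int(round(n_genes * len(grp) / panel.n_variants)))
        starts = np.sort(rng.integers(max(0, lo - span // 4), hi + span // 4, size=k))
        for s in starts:
            length = int(rng.integers(5_000, 120_000))
            rows.append((int(chrom), int(s), int(s) + length, f"GENE{gene_i}", 0))
            gene_i += 1
    gmap = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "panel_flag"])

    if panel_near_variants is not None and len(panel_near_variants) > 0:
        extra = []
        for j, vi in enumerate(np.asarray(panel_near_variants)[:n_panel_genes]):
            v = panel.variants.iloc[int(vi)]
            start = max(0, int(v["pos"]) - 1 - int(rng.integers(0, 20_000)))
            extra.append((int(v["chrom"]), start, start + 40_000, f"CMP{j}", 1))
        gmap = pd.concat([gmap, pd.DataFrame(extra, columns=gmap.columns)], ignore_index=True)
    else:
        flag_idx = rng.choice(len(gmap), size=min(n_panel_genes, len(gmap)), replace=False)
        gmap.loc[flag_idx, "panel_flag"] = 1
    return gmap.sort_values(["chrom", "start"]).reset_index(drop=True)
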