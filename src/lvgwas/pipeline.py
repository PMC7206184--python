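"""End-to-end pipeline driver.

Orders the stages the way the analysis runs on a real cohort: synthetic
cohort generation (optional, replaced by user files in real-data mode) ->
phenotype derivation -> variant QC -> association scans -> LD clumping and
gene annotation -> Mendelian-panel enrichment -> polygenic score and its
PheWAS / incident-disease / stratified-incidence / carrier analyses ->
split-sample direction-concordance replication.  Every stage writes a TSV
into the output directory and logs input/output counts; a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas, io, loci, phenotypes, prs, qc, replication
from .synthetic import (
    SimulationConfig,
    apply_carrier_offsets,
    make_gene_map,
    simulate_genotypes,
    simulate_lv_phenotypes,
    simulate_outcomes,
    spike_rare_carriers,
)

log = logging.getLogger("lvgwas.pipeline")

#: stage execution order and, implicitly, the dependency chain
STAGES = (
    "simulate",
    "derive",
    "qc",
    "scan",
    "clump",
    "enrich",
    "score",
    "phewas",
    "cox",
    "incidence",
    "carriers",
    "replicate",
)


@dataclass
class PipelineConfig:
    """Serializable pipeline configuration; defaults follow the study's
    printed thresholds wherever one exists."""

    out_dir: str = "lvgwas_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # synthetic cohort
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # QC / clumping / enrichment
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    clump: loci.ClumpConfig = field(default_factory=loci.ClumpConfig)
    n_null_sets: int = 1000
    enrichment_radius_kb: float = 500.0
    # scan traits
    traits: list[str] = field(default_factory=lambda: ["lvedv", "lvesv"])
    score_trait: str = "lvesv"
    # outcome cohort for the score analyses
    outcome_n_samples: int = 20_000

    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in d:
            sim = d["sim"]
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            d["sim"] = SimulationConfig(**sim)
        if "qc_thresholds" in d:
            d["qc_thresholds"] = qc.QCThresholds(**d["qc_thresholds"])
        if "clump" in d:
            d["clump"] = loci.ClumpConfig(**d["clump"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


class MissingArtifactError(RuntimeError):
    """A requested stage needs an output that an earlier stage did not write."""

    def __init__(self, stage: str, artifact: Path, produced_by: str):
        super().__init__(
            f"stage {stage!r} needs {artifact} (produced by stage {produced_by!r}); "
            "run that stage first"
        )


def _need(out: Path, name: str, stage: str, produced_by: str) -> Path:
    p = out / name
    if not p.exists():
        raise MissingArtifactError(stage, p, produced_by)
    return p


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages; returns a map of artifact name -> path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("lvgwas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {}
    try:
        for stage in config.stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            log.info("stage %s: start (seed=%d)", stage, config.seed)
            _RUNNERS[stage](config, out, artifacts)
            log.info("stage %s: done", stage)
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts


# ------------------------------------------------------------------ stage impls

def _stage_simulate(cfg: PipelineConfig, out: Path, art: dict) -> None:
    sim = cfg.sim
    panel = simulate_genotypes(sim)
    cohort, truth = simulate_lv_phenotypes(panel, sim)
    flags, offsets = spike_rare_carriers(sim.n_samples, sim)
    cohort = apply_carrier_offsets(cohort, flags, offsets)
    gmap = make_gene_map(panel, panel_near_variants=truth.causal_index, seed=sim.seed)

    io.write_genotypes_matrix(panel, out / "panel")
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False, float_format="%.6g")
    io.write_gene_map(gmap, out / "gene_map.tsv")
    io.write_gene_panel(
        gmap.loc[gmap["panel_flag"] == 1, "gene"].tolist(), out / "gene_panel.txt"
    )
    np.savetxt(out / "true_score.tsv", truth.genetic_score_lvesv, fmt="%.6g")
    pd.DataFrame(
        {
            "key": ["realized_h2_lvedv", "realized_h2_lvesv", "realized_genetic_corr"],
            "value": [
                truth.realized_h2_lvedv,
                truth.realized_h2_lvesv,
                truth.realized_genetic_corr,
            ],
        }
    ).to_csv(out / "simulation_truth.tsv", sep="\t", index=False)
    art["panel"] = out / "panel"
    art["cohort"] = out / "cohort.tsv"
    log.info(
        "simulate: %d samples x %d variants, %d carriers",
        panel.n_samples,
        panel.n_variants,
        int(flags.sum()),
    )


def _stage_derive(cfg: PipelineConfig, out: Path, art: dict) -> None:
    cohort = pd.read_csv(_need(out, "cohort.tsv", "derive", "simulate"), sep="\t")
    traits = phenotypes.derive_traits(cohort)
    traits["outlier_flag"] = phenotypes.flag_volume_outliers(traits)
    manifest = pd.DataFrame(
        {
            "sample_id": traits["sample_id"],
            "mistracing": traits["outlier_flag"] | ~traits["valid"],
            "genotype_qc": False,
            "prevalent_disease": False,
        }
    )
    retained, accounting = phenotypes.apply_cohort_exclusions(manifest)
    for trait in cfg.traits:
        traits[f"{trait}_int"] = phenotypes.inverse_normal_transform(traits[trait])
    traits.to_csv(out / "traits.tsv", sep="\t", index=False, float_format="%.6g")
    accounting.to_csv(out / "exclusion_accounting.tsv", sep="\t", index=False)
    for _, row in accounting.iterrows():
        log.info("derive accounting: %s = %d (remaining %d)", *row)
    art["traits"] = out / "traits.tsv"


def _stage_qc(cfg: PipelineConfig, out: Path, art: dict) -> None:
    _need(out, "panel.variants.tsv", "qc", "simulate")
    panel = io.read_genotypes_matrix(out / "panel")
    mask, report = qc.variant_qc_filter(panel, cfg.qc_thresholds)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
    attrition = qc.qc_attrition(report)
    attrition.to_frame("count").to_csv(out / "qc_attrition.tsv", sep="\t")
    log.info("qc: retained %d / %d variants", int(mask.sum()), panel.n_variants)
    art["qc_report"] = out / "qc_report.tsv"


def _stage_scan(cfg: PipelineConfig, out: Path, art: dict) -> None:
    _need(out, "panel.variants.tsv", "scan", "simulate")
    panel = io.read_genotypes_matrix(out / "panel")
    traits = pd.read_csv(_need(out, "traits.tsv", "scan", "derive"), sep="\t")
    qc_report = pd.read_csv(_need(out, "qc_report.tsv", "scan", "qc"), sep="\t")
    keep = qc_report["keep"].to_numpy(dtype=bool)
    panel_kept = panel.subset_variants(keep)
    cov = gwas.build_covariates(traits)
    for trait in cfg.traits:
        y = traits[f"{trait}_int"].to_numpy(dtype=float)
        stats = gwas.association_scan(panel_kept, y, cov)
        lam = gwas.genomic_inflation(stats) if len(stats) >= 100 else np.nan
        io.write_sumstats(stats, out / f"sumstats_{trait}.tsv")
        log.info("scan %s: %d variants, lambda_GC = %.3f", trait, len(stats), lam)
        art[f"sumstats_{trait}"] = out / f"sumstats_{trait}.tsv"


def _stage_clump(cfg: PipelineConfig, out: Path, art: dict) -> None:
    _need(out, "panel.variants.tsv", "clump", "simulate")
    panel = io.read_genotypes_matrix(out / "panel")
    qc_report = pd.read_csv(_need(out, "qc_report.tsv", "clump", "qc"), sep="\t")
    panel_kept = panel.subset_variants(qc_report["keep"].to_numpy(dtype=bool))
    gmap = io.read_gene_map(_need(out, "gene_map.tsv", "clump", "simulate"))
    all_loci = []
    for trait in cfg.traits:
        stats = io.read_sumstats(_need(out, f"sumstats_{trait}.tsv", "clump", "scan"))
        locus_list = loci.clump_loci(stats, panel_kept, cfg.clump)
        locus_list = loci.annotate_nearest_gene(locus_list, gmap) if locus_list else []
        # HWE exact test on lead SNPs only, as in the QC protocol
        idmap = {v: j for j, v in enumerate(panel_kept.variants["id"])}
        tbl = loci.loci_table(locus_list)
        tbl.insert(0, "trait", trait)
        tbl["lead_hwe_p"] = [
            qc.hwe_exact_test(
                *qc.dosage_genotype_counts(panel_kept.dosages[:, idmap[ls]])
            )
            for ls in tbl["lead_snp"]
        ]
        all_loci.append(tbl)
        log.info("clump %s: %d loci", trait, len(tbl))
    pd.concat(all_loci, ignore_index=True).to_csv(
        out / "loci.tsv", sep="\t", index=False, float_format="%.6g"
    )
    art["loci"] = out / "loci.tsv"


def _stage_enrich(cfg: PipelineConfig, out: Path, art: dict) -> None:
    _need(out, "panel.variants.tsv", "enrich", "simulate")
    panel = io.read_genotypes_matrix(out / "panel")
    qc_report = pd.read_csv(_need(out, "qc_report.tsv", "enrich", "qc"), sep="\t")
    panel_kept = panel.subset_variants(qc_report["keep"].to_numpy(dtype=bool))
    gmap = io.read_gene_map(_need(out, "gene_map.tsv", "enrich", "simulate"))
    panel_genes = io.read_gene_panel(_need(out, "gene_panel.txt", "enrich", "simulate"))
    loci_tbl = pd.read_csv(_need(out, "loci.tsv", "enrich", "clump"), sep="\t")
    lead_ids = loci_tbl["lead_snp"].drop_duplicates().tolist()
    if not lead_ids:
        log.warning("enrich: no loci; writing empty report")
        pd.DataFrame().to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return
    idmap = {v: j for j, v in enumerate(panel_kept.variants["id"])}
    lead_idx = np.array([idmap[i] for i in lead_ids])
    props = loci.matching_properties(panel_kept, gmap)
    null_sets = loci.matched_null_sets(
        lead_idx, props, n_sets=cfg.n_null_sets, seed=cfg.seed
    )
    chrom = panel_kept.variants["chrom"].to_numpy()
    pos = panel_kept.variants["pos"].to_numpy()
    observed = loci.gene_panel_overlap(
        chrom[lead_idx], pos[lead_idx], gmap, panel_genes, cfg.enrichment_radius_kb
    )
    nulls = np.array(
        [
            loci.gene_panel_overlap(
                chrom[s], pos[s], gmap, panel_genes, cfg.enrichment_radius_kb
            )
            for s in null_sets
        ]
    )
    report = loci.enrichment_report(observed, nulls)
    report.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    log.info(
        "enrich: observed %d, null mean %.2f, p = %.4g",
        observed,
        report["null_mean"].iloc[0],
        report["p_one_tailed"].iloc[0],
    )
    art["enrichment"] = out / "enrichment.tsv"


def _score_weights_from_loci(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    loci_tbl = pd.read_csv(_need(out, "loci.tsv", "score", "clump"), sep="\t")
    stats = io.read_sumstats(
        _need(out, f"sumstats_{cfg.score_trait}.tsv", "score", "scan")
    )
    leads = loci_tbl.loc[loci_tbl["trait"] == cfg.score_trait, "lead_snp"]
    w = stats[stats["ID"].isin(leads)][["ID", "EA", "BETA"]].rename(
        columns={"ID": "id", "EA": "effect_allele", "BETA": "beta"}
    )
    if w.empty:
        raise MissingArtifactError("score", out / "loci.tsv", "clump")
    return w


def _stage_score(cfg: PipelineConfig, out: Path, art: dict) -> None:
    _need(out, "panel.variants.tsv", "score", "simulate")
    panel = io.read_genotypes_matrix(out / "panel")
    weights = _score_weights_from_loci(cfg, out)
    weights.to_csv(out / "score_weights.tsv", sep="\t", index=False, float_format="%.6g")
    result = prs.compute_prs(panel, weights)
    pd.DataFrame(
        {
            "sample_id": panel.samples,
            "prs_raw": result.raw,
            "prs_standardized": result.standardized,
        }
    ).to_csv(out / "prs.tsv", sep="\t", index=False, float_format="%.6g")
    log.info("score: %d SNPs, %d samples", result.n_snps_used, panel.n_samples)
    art["prs"] = out / "prs.tsv"


def _outcome_cohort(cfg: PipelineConfig, out: Path) -> tuple:
    """Simulate the (non-imaged) outcome cohort scored with the fitted weights."""
    sim_out = SimulationConfig(
        **{
            **asdict(cfg.sim),
            "n_samples": cfg.outcome_n_samples,
            "seed": (cfg.sim.seed + 104729) % 2**31,
        }
    )
    sim_out.maf_range = tuple(sim_out.maf_range)
    _need(out, "panel.variants.tsv", "score", "simulate")
    discovery_panel = io.read_genotypes_matrix(out / "panel")
    panel = simulate_genotypes(sim_out, template_variants=discovery_panel.variants)
    weights = _score_weights_from_loci(cfg, out)
    score = prs.compute_prs(panel, weights).standardized
    # the true driving score shares the causal architecture via the PRS itself
    outcomes = simulate_outcomes(score, sim_out)
    return score, outcomes


def _stage_phewas(cfg: PipelineConfig, out: Path, art: dict) -> None:
    score, outcomes = _outcome_cohort(cfg, out)
    report = prs.phewas(score, outcomes, n_scores=len(cfg.traits))
    report.to_csv(out / "phewas.tsv", sep="\t", index=False, float_format="%.6g")
    log.info("phewas: tested %d phenotypes", len(report))
    art["phewas"] = out / "phewas.tsv"


def _stage_cox(cfg: PipelineConfig, out: Path, art: dict) -> None:
    score, outcomes = _outcome_cohort(cfg, out)
    res = prs.cox_incident(score, outcomes)
    pd.DataFrame([res.__dict__]).to_csv(
        out / "cox.tsv", sep="\t", index=False, float_format="%.6g"
    )
    log.info("cox: HR %.3f per SD (%d events)", res.hr_per_sd, res.n_events)
    art["cox"] = out / "cox.tsv"


def _stage_incidence(cfg: PipelineConfig, out: Path, art: dict) -> None:
    score, outcomes = _outcome_cohort(cfg, out)
    curves = prs.cumulative_incidence_by_stratum(score, outcomes)
    curves.to_csv(out / "incidence.tsv", sep="\t", index=False, float_format="%.6g")
    art["incidence"] = out / "incidence.tsv"


def _stage_carriers(cfg: PipelineConfig, out: Path, art: dict) -> None:
    traits = pd.read_csv(_need(out, "traits.tsv", "carriers", "derive"), sep="\t")
    prs_tbl = pd.read_csv(_need(out, "prs.tsv", "carriers", "score"), sep="\t")
    score = prs_tbl["prs_standardized"].to_numpy(dtype=float)
    flags = traits["ttntv_carrier"].to_numpy(dtype=bool)
    spline = prs.natural_cubic_spline_basis(traits["age_at_mri"].to_numpy(dtype=float))
    cov = pd.DataFrame(
        {
            **{f"pc{i}": traits[f"pc{i}"] for i in range(1, 6)},
            "sex": traits["sex"],
            **{f"age_s{j}": spline[:, j] for j in range(spline.shape[1])},
        }
    )
    try:
        report = prs.carrier_modifier_regression(score, flags, traits, cov)
    except ValueError as exc:
        log.warning("carriers: %s; writing empty report", exc)
        report = pd.DataFrame(
            columns=["trait", "beta_per_sd", "se", "p", "significant", "n_carriers"]
        )
    report.to_csv(out / "carriers.tsv", sep="\t", index=False, float_format="%.6g")
    art["carriers"] = out / "carriers.tsv"


def _stage_replicate(cfg: PipelineConfig, out: Path, art: dict) -> None:
    """Split-sample replication: rescan each trait in two disjoint halves and
    test direction concordance at the discovery loci."""
    _need(out, "panel.variants.tsv", "replicate", "simulate")
    panel = io.read_genotypes_matrix(out / "panel")
    traits = pd.read_csv(_need(out, "traits.tsv", "replicate", "derive"), sep="\t")
    qc_report = pd.read_csv(_need(out, "qc_report.tsv", "replicate", "qc"), sep="\t")
    loci_tbl = pd.read_csv(_need(out, "loci.tsv", "replicate", "clump"), sep="\t")
    panel_kept = panel.subset_variants(qc_report["keep"].to_numpy(dtype=bool))

    rng = np.random.default_rng(cfg.seed)
    half = rng.permutation(panel.n_samples)
    a_idx, b_idx = half[: panel.n_samples // 2], half[panel.n_samples // 2 :]
    reports = []
    for trait in cfg.traits:
        lead_ids = loci_tbl.loc[loci_tbl["trait"] == trait, "lead_snp"].tolist()
        if not lead_ids:
            continue
        keep_lead = panel_kept.variants["id"].isin(lead_ids).to_numpy()
        sub = panel_kept.subset_variants(keep_lead)
        halves = []
        for idx in (a_idx, b_idx):
            cohort_h = traits.iloc[idx].reset_index(drop=True)
            y = phenotypes.inverse_normal_transform(cohort_h[trait])
            cov = gwas.build_covariates(cohort_h)
            halves.append(gwas.association_scan(sub.subset_samples(idx), y, cov))
        aligned, _ = replication.harmonize_alleles(halves[0], halves[1])
        if aligned.empty:
            continue
        rep = replication.concordance_report(aligned).to_frame()
        rep.insert(0, "trait", trait)
        reports.append(rep)
    if reports:
        pd.concat(reports, ignore_index=True).to_csv(
            out / "concordance.tsv", sep="\t", index=False, float_format="%.6g"
        )
        art["concordance"] = out / "concordance.tsv"
    else:
        log.warning("replicate: no loci to replicate")


_RUNNERS = {
    "simulate": _stage_simulate,
    "derive": _stage_derive,
    "qc": _stage_qc,
    "scan": _stage_scan,
    "clump": _stage_clump,
    "enrich": _stage_enrich,
    "score": _stage_score,
    "phewas": _stage_phewas,
    "cox": _stage_cox,
    "incidence": _stage_incidence,
    "carriers": _stage_carriers,
    "replicate": _stage_replicate,
}
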