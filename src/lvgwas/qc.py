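"""Variant-level genotype quality control.

Filters follow the imputed-biobank conventions: genotyping call rate,
imputation INFO score, minor-allele frequency, effective minor allele count
(MAF x 2N x INFO), and the Hardy-Weinberg exact test.  All inequalities are
strict exactly as printed in the thresholds: a variant at a threshold value
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class QCThresholds:
    min_call_rate: float = 0.95
    min_info: float = 0.3
    min_maf: float = 0.001
    min_effective_mac: float = 100.0
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 <= self.min_call_rate <= 1 and 0 <= self.min_info <= 1):
            raise ValueError("call-rate and INFO thresholds must be in [0, 1]")
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_effective_mac < 0 or not (0 <= self.hwe_p_floor <= 1):
            raise ValueError("invalid eMAC or HWE thresholds")


def effective_minor_allele_count(maf, n_samples: int, info) -> np.ndarray | float:
    """Effective minor allele count: MAF x (2 * n_samples) x INFO.

    "Number of alleles in the analysis" is 2 * n_samples for diploid
    autosomes; the INFO factor discounts imputation uncertainty.
    """
    maf_a = np.asarray(maf, dtype=float)
    info_a = np.asarray(info, dtype=float)
    if np.any((maf_a < 0) | (maf_a > 0.5)):
        raise ValueError("maf must be in [0, 0.5]")
    if np.any((info_a < 0) | (info_a > 1)):
        raise ValueError("info must be in [0, 1]")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    out = maf_a * (2.0 * n_samples) * info_a
    return float(out) if out.ndim == 0 else out


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton-style, plain tail sum).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one.  Monomorphic sites return p = 1.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v != int(v) or v < 0:
            raise ValueError("genotype counts must be nonnegative integers")
    n_aa, n_ab, n_bb = int(n_hom_ref), int(n_het), int(n_hom_alt)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_aa, n_bb) + n_ab  # minor allele count
    if n_rare == 0:
        return 1.0

    # probabilities over all het counts with the same allele margins,
    # via the standard recurrence from the mid het count
    het_min = n_rare % 2
    probs = np.zeros(n_rare // 2 + 1)

    # start from the most probable het count (near expectation), recurse out
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if (mid - het_min) % 2 != 0:
        mid += 1 if mid < n_rare else -1
    idx = lambda h: (h - het_min) // 2  # noqa: E731 - local index map
    probs[idx(mid)] = 1.0
    # downward recurrence: P(h-2)/P(h) = h*(h-1) / ((r-h+2)/2 * (c-h+2)/2) terms
    for h in range(mid, het_min + 1, -2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[idx(h - 2)] = probs[idx(h)] * h * (h - 1.0) / (
            4.0 * (rare_hom + 1.0) * (common_hom + 1.0)
        )
    for h in range(mid, n_rare - 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        probs[idx(h + 2)] = probs[idx(h)] * 4.0 * rare_hom * common_hom / (
            (h + 2.0) * (h + 1.0)
        )
    probs /= probs.sum()
    p_obs = probs[idx(n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def dosage_genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts from a dosage vector (rounded to 0/1/2)."""
    g = np.clip(np.rint(np.asarray(dosages, dtype=float)), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def variant_qc_filter(
    panel: GenotypePanel,
    thresholds: QCThresholds | None = None,
    apply_hwe: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the variant filters; return the keep-mask and a QC report.

    The overall mask is the conjunction of the individual filter masks, so it
    is order-independent.  The report carries each variant's per-filter
    pass/fail, eMAC, and (when ``apply_hwe``) the exact-test p-value.  The
    HWE filter defaults to off here because the source protocol applies it
    only to lead SNPs; pass ``apply_hwe=True`` to screen every variant.
    """
    th = thresholds or QCThresholds()
    v = panel.variants
    for colname in ("maf", "info", "call_rate"):
        if v[colname].isna().any():
            raise ValueError(f"variant metadata column {colname!r} has missing values")
    n = panel.n_samples
    emac = effective_minor_allele_count(v["maf"].to_numpy(), n, v["info"].to_numpy())
    pass_call = v["call_rate"].to_numpy() >= th.min_call_rate
    pass_info = v["info"].to_numpy() >= th.min_info
    pass_maf = v["maf"].to_numpy() >= th.min_maf
    pass_emac = emac >= th.min_effective_mac
    report = pd.DataFrame(
        {
            "id": v["id"],
            "pass_call_rate": pass_call,
            "pass_info": pass_info,
            "pass_maf": pass_maf,
            "emac": emac,
            "pass_emac": pass_emac,
        }
    )
    mask = pass_call & pass_info & pass_maf & pass_emac
    if apply_hwe:
        hwe_p = np.array(
            [
                hwe_exact_test(*dosage_genotype_counts(panel.dosages[:, j]))
                for j in range(panel.n_variants)
            ]
        )
        report["hwe_p"] = hwe_p
        report["pass_hwe"] = hwe_p >= th.hwe_p_floor
        mask = mask & report["pass_hwe"].to_numpy()
    report["keep"] = mask
    return mask, report


def qc_attrition(report: pd.DataFrame) -> pd.Series:
    """Per-filter failure counts (non-exclusive) plus the overall removal."""
    counts = {}
    for col in report.columns:
        if col.startswith("pass_"):
            counts[col.replace("pass_", "fail_")] = int((~report[col]).sum())
    counts["removed_total"] = int((~report["keep"]).sum())
    counts["retained"] = int(report["keep"].sum())
    return pd.Series(counts, dtype=int)
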