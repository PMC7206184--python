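"""Association scanning, inflation diagnostics and Haseman-Elston heritability.

The scan is a covariate-residualized per-variant linear regression: the
inverse-normal-transformed trait and every dosage vector are residualized
once on the covariates plus intercept, and the per-variant slope, standard
error and two-sided t-test follow from the residual inner products
(Frisch-Waugh-Lovell, so the betas equal those of the joint OLS fit with
covariates included).  Relatedness/mixed-model corrections are intentionally
absent: the cohorts this package targets (simulated or pre-pruned) are
unrelated by construction.

SNP-heritability and genetic correlation use Haseman-Elston regression of
phenotype cross-products on genomic-relationship entries; LD-score
regression partitions test-statistic inflation into a polygenic slope and a
confounding intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

#: theoretical median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))

SUMSTATS_COLUMNS = ("CHR", "POS", "ID", "EA", "NEA", "EAF", "BETA", "SE", "P", "INFO")


def build_covariates(cohort: pd.DataFrame, n_pcs: int = 5) -> pd.DataFrame:
    """Assemble the scan covariates: first five ancestry PCs, sex, year of
    birth, age at MRI, and one-hot MRI scanner id (first scanner dropped)."""
    cols = {}
    for i in range(1, n_pcs + 1):
        cols[f"pc{i}"] = cohort[f"pc{i}"].to_numpy(dtype=float)
    cols["sex"] = cohort["sex"].to_numpy(dtype=float)
    cols["birth_year"] = cohort["birth_year"].to_numpy(dtype=float)
    cols["age_at_mri"] = cohort["age_at_mri"].to_numpy(dtype=float)
    scanner = pd.get_dummies(cohort["scanner_id"], prefix="scanner", drop_first=True)
    for c in scanner.columns:
        cols[str(c)] = scanner[c].to_numpy(dtype=float)
    cov = pd.DataFrame(cols, index=cohort.index)
    return cov


def _residualize(mat: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize columns of ``mat`` on ``design`` (which includes the
    intercept) via least squares."""
    coef, *_ = np.linalg.lstsq(design, mat, rcond=None)
    return mat - design @ coef


def association_scan(
    panel: GenotypePanel,
    trait: np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant association scan of a (transformed) trait.

    Returns a summary-statistics table with one row per variant: effect
    allele (the panel's alt allele, whose dosage is counted), effect-allele
    frequency, beta in trait units per allele, SE and two-sided p from the
    t reference with ``n - n_covariates - 2`` degrees of freedom.
    Variants monomorphic after residualization are emitted with ``beta = 0``,
    ``p = 1`` and ``zero_variance = True`` rather than dropped.
    """
    y = np.asarray(trait, dtype=float)
    n = panel.n_samples
    if y.shape != (n,):
        raise ValueError("trait length does not match panel samples")
    c = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("covariate design is rank deficient")
    k = covariates.shape[1]
    df = n - k - 2
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")

    y_r = _residualize(y[:, None], c)[:, 0]
    g_r = _residualize(panel.dosages, c)

    gg = np.einsum("ij,ij->j", g_r, g_r)
    gy = g_r.T @ y_r
    yy = float(y_r @ y_r)

    zero = gg <= 1e-12
    gg_safe = np.where(zero, 1.0, gg)
    beta = np.where(zero, 0.0, gy / gg_safe)
    rss = np.maximum(yy - beta**2 * gg_safe, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    se = np.where(zero, np.inf, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(zero, 0.0, beta / se)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(zero, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))

    v = panel.variants
    eaf = panel.dosages.mean(axis=0) / 2.0
    return pd.DataFrame(
        {
            "CHR": v["chrom"].to_numpy(),
            "POS": v["pos"].to_numpy(),
            "ID": v["id"].to_numpy(),
            "EA": v["alt"].to_numpy(),
            "NEA": v["ref"].to_numpy(),
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "INFO": v["info"].to_numpy(),
            "zero_variance": zero,
        }
    )


def genomic_inflation(sumstats: pd.DataFrame) -> float:
    """Genomic-control lambda: median test chi-square over its null median."""
    if len(sumstats) < 100:
        raise ValueError("need >= 100 variants for a stable lambda estimate")
    chi2 = stats.chi2.isf(sumstats["P"].to_numpy(dtype=float), df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def compute_ld_scores(panel: GenotypePanel, window: int = 500) -> np.ndarray:
    """In-panel LD score of each variant: 1 + sum of r^2 with neighbours
    within ``window`` variants on the same chromosome."""
    z = panel.standardized()
    n, m = z.shape
    ld = np.ones(m)
    chroms = panel.variants["chrom"].to_numpy()
    for d in range(1, window + 1):
        if d >= m:
            break
        r = np.einsum("ij,ij->j", z[:, :-d], z[:, d:]) / n
        same = chroms[:-d] == chroms[d:]
        r2 = np.where(same, r**2, 0.0)
        ld[: m - d] += r2
        ld[d:] += r2
    return ld


@dataclass
class LdscResult:
    intercept: float
    slope: float
    slope_se: float
    slope_z: float


def ld_score_regression(
    sumstats: pd.DataFrame,
    ld_scores: np.ndarray,
    min_maf: float = 0.01,
) -> LdscResult:
    """Weighted regression of the test chi-square on the LD score.

    Under pure polygenicity the intercept is ~1 and the slope scales with
    heritability; stratification or confounding inflates the intercept.
    Weights are ``1 / max(ld_score, 1)``, a simple heteroskedasticity proxy.
    Variants with MAF below ``min_maf`` are excluded.
    """
    ld = np.asarray(ld_scores, dtype=float)
    if ld.shape[0] != len(sumstats):
        raise ValueError("ld_scores not aligned to sumstats")
    if np.ptp(ld) <= 0:
        raise ValueError("constant LD scores: regression undefined")
    eaf = sumstats["EAF"].to_numpy(dtype=float)
    maf = np.minimum(eaf, 1 - eaf)
    keep = maf >= min_maf
    chi2 = stats.chi2.isf(sumstats["P"].to_numpy(dtype=float), df=1)[keep]
    x = ld[keep]
    w = 1.0 / np.maximum(x, 1.0)
    xm = np.column_stack([np.ones(x.size), x])
    wxt = xm.T * w
    coef = np.linalg.solve(wxt @ xm, wxt @ chi2)
    resid = chi2 - xm @ coef
    dof = x.size - 2
    sigma2 = float((w * resid**2).sum() / dof)
    cov = sigma2 * np.linalg.inv(wxt @ xm)
    se = float(np.sqrt(cov[1, 1]))
    return LdscResult(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        slope_se=se,
        slope_z=float(coef[1] / se) if se > 0 else np.nan,
    )


@dataclass
class HeritabilityEstimate:
    h2: float  # clamped for reporting
    h2_raw: float
    se: float

    @property
    def z(self) -> float:
        return self.h2_raw / self.se if self.se > 0 else np.nan


def _he_slope(a_off: np.ndarray, prod: np.ndarray) -> tuple[float, float]:
    x = a_off - a_off.mean()
    y = prod - prod.mean()
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    se = float(np.sqrt((resid @ resid) / (x.size - 2) / sxx))
    return slope, se


def _grm_offdiag(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = panel.standardized(ddof=1)
    a = z @ z.T / panel.n_variants
    iu = np.triu_indices(panel.n_samples, k=1)
    return a[iu], iu[0], iu[1]


def he_regression_h2(panel: GenotypePanel, trait: np.ndarray) -> HeritabilityEstimate:
    """SNP-heritability by Haseman-Elston regression.

    Regresses standardized-phenotype cross-products ``y_i * y_j`` (i < j) on
    genomic-relationship entries ``A_ij``; the slope estimates h2.  The SE is
    the OLS one and ignores the dependence between pairs sharing a sample,
    so it is mildly optimistic; it is adequate for the parameter-recovery
    checks this package performs.  Reported h2 is clamped to [-0.05, 1.05]
    with the raw value retained.
    """
    n = panel.n_samples
    if n < 50:
        raise ValueError("need n >= 50 for Haseman-Elston regression")
    y = np.asarray(trait, dtype=float)
    y = (y - y.mean()) / y.std()
    a_off, i_idx, j_idx = _grm_offdiag(panel)
    slope, se = _he_slope(a_off, y[i_idx] * y[j_idx])
    return HeritabilityEstimate(
        h2=float(np.clip(slope, -0.05, 1.05)), h2_raw=slope, se=se
    )


def he_genetic_correlation(
    panel: GenotypePanel, trait1: np.ndarray, trait2: np.ndarray
) -> float:
    """Genetic correlation from bivariate Haseman-Elston regression:
    cross-trait slope over the geometric mean of the per-trait slopes."""
    n = panel.n_samples
    if n < 50:
        raise ValueError("need n >= 50 for Haseman-Elston regression")
    y1 = np.asarray(trait1, dtype=float)
    y2 = np.asarray(trait2, dtype=float)
    if np.array_equal(y1, y2):
        return 1.0
    y1 = (y1 - y1.mean()) / y1.std()
    y2 = (y2 - y2.mean()) / y2.std()
    a_off, i_idx, j_idx = _grm_offdiag(panel)
    s11, _ = _he_slope(a_off, y1[i_idx] * y1[j_idx])
    s22, _ = _he_slope(a_off, y2[i_idx] * y2[j_idx])
    cross = 0.5 * (y1[i_idx] * y2[j_idx] + y1[j_idx] * y2[i_idx])
    s12, _ = _he_slope(a_off, cross)
    denom = np.sqrt(max(s11, 1e-12) * max(s22, 1e-12))
    return float(s12 / denom)
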