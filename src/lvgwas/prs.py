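"""Polygenic scoring and its downstream epidemiology.

A polygenic score is the weighted sum of effect-allele dosages over the lead
SNPs of one trait's association scan.  The score is then tested against:

* many binary phenotypes by logistic regression (PheWAS), with a 200-case
  floor and Bonferroni thresholds over scores x phenotypes;
* incident disease by a Cox proportional-hazards model (Efron ties) adjusted
  for sex, genotyping array, five ancestry PCs and a natural cubic spline of
  age at enrollment, reporting the hazard ratio per SD of score;
* cumulative incidence (1 - Kaplan-Meier) stratified by score decile groups,
  with confidence bands from the standard error of the cumulative hazard;
* continuous LV traits within rare truncating-variant carriers, by linear
  regression restricted to carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .panel import GenotypePanel
from .synthetic import OutcomeTable

log = logging.getLogger(__name__)


@dataclass
class PrsResult:
    raw: np.ndarray
    standardized: np.ndarray
    n_snps_used: int
    n_snps_requested: int


def compute_prs(
    panel: GenotypePanel, weights: pd.DataFrame, allow_missing: bool = False
) -> PrsResult:
    """Weighted effect-allele dosage sum over the weight SNPs.

    ``weights`` needs columns ``id, effect_allele, beta``.  When the effect
    allele is the panel's other (ref) allele the dosage is flipped to
    ``2 - d``; an effect allele matching neither panel allele raises.  A SNP
    absent from the panel raises unless ``allow_missing``, in which case the
    raw score is rescaled by requested/used SNP counts (and the gap logged).
    The standardized score has mean 0, SD 1 in the scored cohort.
    """
    if weights["id"].duplicated().any():
        raise ValueError("duplicate SNP ids in weights")
    if not np.all(np.isfinite(weights["beta"].to_numpy(dtype=float))):
        raise ValueError("non-finite betas in weights")
    index = {vid: j for j, vid in enumerate(panel.variants["id"])}
    score = np.zeros(panel.n_samples)
    used = 0
    for _, row in weights.iterrows():
        j = index.get(row["id"])
        if j is None:
            if allow_missing:
                log.warning("PRS weight SNP %s absent from panel; skipped", row["id"])
                continue
            raise KeyError(f"weight SNP {row['id']} not in panel")
        ea = str(row["effect_allele"])
        ref = str(panel.variants.at[j, "ref"])
        alt = str(panel.variants.at[j, "alt"])
        if ea == alt:
            d = panel.dosages[:, j]
        elif ea == ref:
            d = 2.0 - panel.dosages[:, j]
        else:
            raise ValueError(f"effect allele {ea} matches neither allele of {row['id']}")
        score += float(row["beta"]) * d
        used += 1
    if used == 0:
        raise ValueError("no weight SNPs found in panel")
    if used < len(weights):
        score = score * (len(weights) / used)
    sd = score.std()
    z = (score - score.mean()) / (sd if sd > 0 else 1.0)
    return PrsResult(
        raw=score, standardized=z, n_snps_used=used, n_snps_requested=len(weights)
    )


def natural_cubic_spline_basis(
    x: np.ndarray, interior_knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Interior knots default to the quartiles of ``x``; boundary knots are the
    data extremes.  Returns an ``n x (K - 1)`` matrix for K total knots,
    without an intercept column.
    """
    x = np.asarray(x, dtype=float)
    if interior_knots is None:
        interior_knots = np.quantile(x, [0.25, 0.5, 0.75])
    knots = np.unique(np.concatenate([[x.min()], np.asarray(interior_knots), [x.max()]]))
    k = len(knots)
    if k < 3:
        return x[:, None] - x.mean()

    def d(j: int) -> np.ndarray:
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[k - 1], 0, None) ** 3
        return num / (knots[k - 1] - knots[j])

    cols = [x]
    dlast = d(k - 2)
    for j in range(k - 2):
        cols.append(d(j) - dlast)
    basis = np.column_stack(cols)
    return basis - basis.mean(axis=0)


def phewas_bonferroni(n_scores: int, n_phenotypes: int) -> float:
    """Bonferroni significance threshold over a score-by-phenotype grid."""
    return 0.05 / (n_scores * n_phenotypes)


def phewas(
    score: np.ndarray,
    outcomes: OutcomeTable,
    min_cases: int = 200,
    n_scores: int = 7,
) -> pd.DataFrame:
    """Logistic PheWAS of one standardized score against binary phenotypes.

    Phenotypes with fewer than ``min_cases`` cases are excluded before
    testing (mirroring the screened design rather than fit-and-flag).
    Covariates: age at enrollment, sex, genotyping array, five ancestry PCs.
    Non-converged or separated fits are reported with ``converged = False``,
    never dropped silently.
    """
    z = _standardize(score)
    fr = outcomes.frame
    cov = np.column_stack(
        [
            np.ones(len(fr)),
            z,
            fr["age_at_enroll"].to_numpy(dtype=float),
            fr["sex"].to_numpy(dtype=float),
            fr["array_batch"].to_numpy(dtype=float),
            fr[[f"pc{i}" for i in range(1, 6)]].to_numpy(dtype=float),
        ]
    )
    counts = outcomes.case_counts()
    tested = [p for p in outcomes.phenotypes.columns if counts[p] >= min_cases]
    threshold = phewas_bonferroni(n_scores, max(len(tested), 1))
    rows = []
    for phen in tested:
        y = outcomes.phenotypes[phen].to_numpy(dtype=float)
        converged = True
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, cov).fit(disp=0, maxiter=200)
            beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:  # separation / singular designs
            beta, se, p, converged = np.nan, np.nan, np.nan, False
        rows.append(
            {
                "phenotype": phen,
                "n_cases": int(counts[phen]),
                "or_per_sd": float(np.exp(beta)) if np.isfinite(beta) else np.nan,
                "beta": beta,
                "se": se,
                "p": p,
                "significant": bool(p < threshold) if np.isfinite(p) else False,
                "converged": converged,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "phenotype", "n_cases", "or_per_sd", "beta", "se", "p",
            "significant", "converged",
        ],
    )
    out.attrs["bonferroni_threshold"] = threshold
    return out


@dataclass
class CoxResult:
    hr_per_sd: float
    log_hr: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float
    n_events: int
    significance_threshold: float = 0.05 / 7


def cox_incident(
    score: np.ndarray,
    outcomes: OutcomeTable,
    n_traits: int = 7,
) -> CoxResult:
    """Cox proportional-hazards fit of incident disease on the score.

    Efron tie handling; covariates are sex, genotyping array, five ancestry
    PCs and a natural cubic spline of age at enrollment (interior knots at
    the age quartiles).  Reported per-trait significance uses 0.05 / n_traits.
    """
    fr = outcomes.frame
    n_events = int(fr["event"].sum())
    if n_events < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    z = _standardize(score)
    spline = natural_cubic_spline_basis(fr["age_at_enroll"].to_numpy(dtype=float))
    df = pd.DataFrame(
        {
            "follow_up_years": fr["follow_up_years"].to_numpy(dtype=float),
            "event": fr["event"].to_numpy(dtype=int),
            "score": z,
            "sex": fr["sex"].to_numpy(dtype=float),
            "array_batch": fr["array_batch"].to_numpy(dtype=float),
            **{f"pc{i}": fr[f"pc{i}"].to_numpy(dtype=float) for i in range(1, 6)},
            **{f"age_s{j}": spline[:, j] for j in range(spline.shape[1])},
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="follow_up_years", event_col="event")
    if not np.isfinite(cph.log_likelihood_):
        raise ValueError("non-finite Cox partial likelihood")
    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return CoxResult(
        hr_per_sd=float(np.exp(coef)),
        log_hr=coef,
        se=se,
        ci_lower=float(np.exp(coef - 1.959963984540054 * se)),
        ci_upper=float(np.exp(coef + 1.959963984540054 * se)),
        p=float(cph.summary.loc["score", "p"]),
        n_events=n_events,
        significance_threshold=0.05 / n_traits,
    )


def cumulative_incidence_by_stratum(
    score: np.ndarray,
    outcomes: OutcomeTable,
    quantiles: tuple[float, float] = (0.10, 0.90),
    alpha: float = 0.05,
    strata_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative incidence (1 - Kaplan-Meier) per score stratum.

    Strata default to bottom ``quantiles[0]``, middle, and top
    ``1 - quantiles[1]`` of the score; an explicit per-sample label array
    overrides them (e.g. a single whole-cohort stratum).  Confidence bands
    come from the Greenwood-type standard error of the cumulative hazard,
    transformed back to the incidence scale:
    ``1 - exp(-(H +/- z * se(H)))``.  Returns a long-format table with
    columns ``stratum, time, incidence, ci_lower, ci_upper``.
    """
    z = _standardize(score)
    if strata_labels is None:
        lo, hi = np.quantile(z, quantiles)
        labels = np.where(z <= lo, "bottom", np.where(z > hi, "top", "middle"))
        strata = ("bottom", "middle", "top")
    else:
        labels = np.asarray(strata_labels)
        strata = tuple(pd.unique(labels))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    fr = outcomes.frame
    rows = []
    for stratum in strata:
        mask = labels == stratum
        if not mask.any():
            raise ValueError(f"empty stratum {stratum!r}")
        t = fr.loc[mask, "follow_up_years"].to_numpy(dtype=float)
        e = fr.loc[mask, "event"].to_numpy(dtype=int)
        if e.sum() == 0:
            tmax = float(t.max())
            for tt in (0.0, tmax):
                rows.append((stratum, tt, 0.0, 0.0, 0.0))
            continue
        km = KaplanMeierFitter()
        km.fit(t, event_observed=e)
        surv = km.survival_function_.iloc[:, 0]
        times = surv.index.to_numpy(dtype=float)
        # Greenwood-type variance of the cumulative hazard at each event time
        order = np.argsort(t)
        ts, es = t[order], e[order]
        at_risk0 = len(ts)
        var_h = {}
        acc = 0.0
        for tt in np.unique(ts[es == 1]):
            n_risk = at_risk0 - np.searchsorted(ts, tt, side="left")
            d = int(((ts == tt) & (es == 1)).sum())
            if n_risk > d:
                acc += d / (n_risk * (n_risk - d))
            var_h[tt] = acc
        acc_at = np.zeros_like(times)
        running = 0.0
        for i, tt in enumerate(times):
            if tt in var_h:
                running = var_h[tt]
            acc_at[i] = running
        s = surv.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            h = -np.log(np.clip(s, 1e-300, 1.0))
        se_h = np.sqrt(acc_at)
        inc = 1.0 - s
        lo_b = 1.0 - np.exp(-(h - zcrit * se_h))
        hi_b = 1.0 - np.exp(-(h + zcrit * se_h))
        lo_b = np.clip(lo_b, 0.0, 1.0)
        hi_b = np.clip(hi_b, 0.0, 1.0)
        for tt, i_, l_, u_ in zip(times, inc, lo_b, hi_b):
            rows.append((stratum, float(tt), float(i_), float(l_), float(u_)))
    return pd.DataFrame(
        rows, columns=["stratum", "time", "incidence", "ci_lower", "ci_upper"]
    )


def carrier_modifier_regression(
    score: np.ndarray,
    carrier_flags: np.ndarray,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    trait_cols: tuple[str, ...] = ("lvesv", "lvedv", "lvef"),
    min_carriers: int = 20,
) -> pd.DataFrame:
    """Linear regression of LV traits on the score within rare-variant
    carriers, Bonferroni-corrected over the tested traits (0.05 / n_traits).

    The score is used exactly as passed: callers supply the cohort-
    standardized score so effects are per full-cohort SD, and the carrier
    subset does not re-scale the exposure (the fitted beta is equivariant to
    the score's scale).
    """
    flags = np.asarray(carrier_flags, dtype=bool)
    n_car = int(flags.sum())
    if n_car < min_carriers:
        raise ValueError(f"need >= {min_carriers} carriers, got {n_car}")
    z = np.asarray(score, dtype=float)[flags]
    cov = covariates.to_numpy(dtype=float)[flags]
    design = np.column_stack([np.ones(n_car), z, cov])
    if n_car <= design.shape[1]:
        raise ValueError("fewer carriers than regression parameters")
    threshold = 0.05 / len(trait_cols)
    rows = []
    for col in trait_cols:
        y = traits[col].to_numpy(dtype=float)[flags]
        fit = sm.OLS(y, design).fit()
        rows.append(
            {
                "trait": col,
                "beta_per_sd": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]),
                "significant": bool(fit.pvalues[1] < threshold),
                "n_carriers": n_car,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)
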