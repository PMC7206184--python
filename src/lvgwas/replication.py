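"""Cross-cohort replication by effect-direction concordance.

Discovery and replication summary statistics are harmonized to the
discovery effect allele (handling allele swaps, strand flips, and
palindromic SNPs), then two exact binomial tests ask (1) whether the
fraction of same-direction effects exceeds the 50% chance expectation and
(2) whether the fraction of same-direction effects that are also nominally
significant in the replication cohort exceeds 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _comp(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _comp(a1) == a2


def harmonize_alleles(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    palindromic_eaf_margin: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align replication effects to the discovery effect allele.

    Both inputs are summary-statistics tables with columns
    ``ID, EA, NEA, EAF, BETA, P`` (extra columns tolerated).  The replication
    beta is negated when its effect allele matches the discovery other
    allele (directly or after strand complementation).  Palindromic (A/T,
    C/G) SNPs are resolved by allele frequency when both cohorts are clearly
    away from 0.5 (``|EAF - 0.5| > palindromic_eaf_margin``), otherwise
    dropped.  Incompatible allele sets are dropped with a reason.

    Returns the aligned table and a drop log.
    """
    rep = replication.set_index("ID")
    aligned_rows, drops = [], []
    for _, d in discovery.iterrows():
        vid = d["ID"]
        if vid not in rep.index:
            drops.append((vid, "missing_in_replication"))
            continue
        r = rep.loc[vid]
        d_ea, d_nea = str(d["EA"]), str(d["NEA"])
        r_ea, r_nea = str(r["EA"]), str(r["NEA"])
        beta_r = float(r["BETA"])
        if _is_palindromic(d_ea, d_nea):
            d_eaf, r_eaf = float(d["EAF"]), float(r["EAF"])
            if (
                abs(d_eaf - 0.5) <= palindromic_eaf_margin
                or abs(r_eaf - 0.5) <= palindromic_eaf_margin
            ):
                drops.append((vid, "palindromic_ambiguous"))
                continue
            if {r_ea, r_nea} not in ({d_ea, d_nea}, {_comp(d_ea), _comp(d_nea)}):
                drops.append((vid, "incompatible_alleles"))
                continue
            # frequency-based resolution: same minor/major orientation?
            same_orientation = (d_eaf < 0.5) == (r_eaf < 0.5)
            if not same_orientation:
                beta_r = -beta_r
        elif (r_ea, r_nea) == (d_ea, d_nea):
            pass
        elif (r_ea, r_nea) == (d_nea, d_ea):
            beta_r = -beta_r
        elif (r_ea, r_nea) == (_comp(d_ea), _comp(d_nea)):
            pass
        elif (r_ea, r_nea) == (_comp(d_nea), _comp(d_ea)):
            beta_r = -beta_r
        else:
            drops.append((vid, "incompatible_alleles"))
            continue
        aligned_rows.append(
            {
                "ID": vid,
                "beta_discovery": float(d["BETA"]),
                "beta_replication": beta_r,
                "p_replication": float(r["P"]),
            }
        )
    aligned = pd.DataFrame(
        aligned_rows, columns=["ID", "beta_discovery", "beta_replication", "p_replication"]
    )
    drop_log = pd.DataFrame(drops, columns=["ID", "reason"])
    return aligned, drop_log


def binomial_two_tailed(k: int, n: int, p0: float) -> float:
    """Exact two-tailed binomial p-value (minimum-likelihood convention):
    the sum of probabilities of all outcomes no more likely than ``k``
    under Binomial(``n``, ``p0``)."""
    if k != int(k) or n != int(n):
        raise ValueError("k and n must be integers")
    k, n = int(k), int(n)
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)


@dataclass
class ConcordanceReport:
    n_total: int
    n_same_direction: int
    pct_same_direction: float
    p_sign_test: float
    n_sig_same: int
    pct_sig_same: float
    p_sig_test: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def concordance_report(aligned: pd.DataFrame) -> ConcordanceReport:
    """Direction-concordance tests on a harmonized discovery/replication set.

    Test 1: same-direction count against a 50% chance expectation.
    Test 2: count of same-direction effects with replication p < 0.05
    against a 5% expectation, with the full site count as trials.
    Percentages are reported to one decimal.
    """
    if aligned.empty:
        raise ValueError("no aligned SNP-trait pairs")
    bd = aligned["beta_discovery"].to_numpy(dtype=float)
    br = aligned["beta_replication"].to_numpy(dtype=float)
    pr = aligned["p_replication"].to_numpy(dtype=float)
    same = bd * br > 0
    n = len(aligned)
    n_same = int(same.sum())
    n_sig_same = int((same & (pr < 0.05)).sum())
    return ConcordanceReport(
        n_total=n,
        n_same_direction=n_same,
        pct_same_direction=round(100.0 * n_same / n, 1),
        p_sign_test=binomial_two_tailed(n_same, n, 0.5),
        n_sig_same=n_sig_same,
        pct_sig_same=round(100.0 * n_sig_same / n, 1),
        p_sig_test=binomial_two_tailed(n_sig_same, n, 0.05),
    )
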