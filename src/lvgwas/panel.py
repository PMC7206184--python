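"""Genotype dosage panel: the central in-memory container for the pipeline.

A :class:`GenotypePanel` holds an ``n_samples x n_variants`` matrix of diploid
allele dosages (continuous in [0, 2], as produced by genotype imputation)
together with per-variant metadata and sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every variant-metadata table must carry.
VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "maf", "info", "call_rate")


@dataclass
class GenotypePanel:
    """Diploid dosage matrix with aligned variant metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_variants)`` with values in [0, 2].
    variants
        DataFrame with one row per variant; columns per :data:`VARIANT_COLUMNS`.
        ``pos`` is 1-based (VCF convention) and strictly increasing within each
        chromosome.
    samples
        Sample identifiers, length ``n_samples``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage matrix has {m} columns"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        if not self.samples:
            self.samples = [f"S{i:06d}" for i in range(n)]
        if len(self.samples) != n:
            raise ValueError("sample id count does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def realized_maf(self) -> np.ndarray:
        """Empirical minor-allele frequency of each variant (folded at 0.5)."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def standardized(self, ddof: int = 0) -> np.ndarray:
        """Column-standardized dosages (mean 0, SD 1); monomorphic columns -> 0."""
        x = self.dosages - self.dosages.mean(axis=0)
        sd = self.dosages.std(axis=0, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, x / np.where(sd > 0, sd, 1.0), 0.0)
        return z

    def subset_variants(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            dosages=self.dosages[idx, :],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in idx],
        )
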