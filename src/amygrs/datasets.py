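"""In-memory containers shared by every pipeline stage.

A cohort is a dosage matrix (samples x variants, effect-allele counts in
[0, 2], NaN = missing call) together with a variant table and a per-sample
phenotype/covariate table.  Per-variant association output and meta-analytic
output travel between stages as plain :class:`pandas.DataFrame` objects with
fixed column contracts (``SUMMARY_COLUMNS`` / ``META_COLUMNS``), the way GWAS
summary statistics are exchanged between tools in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Column contract for per-variant association summaries (one study).
SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

#: Column contract for meta-analytic summaries.
META_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "q_stat", "tau2", "k", "directions",
]

VARIANT_META_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class CohortDataset:
    """Genotype dosages plus phenotype and covariates for one cohort.

    Parameters
    ----------
    cohort_name : str
        Label for the cohort/modality (e.g. ``"discovery_a"``).
    dosages : ndarray of shape (n_samples, n_variants)
        Effect-allele dosage in [0, 2]; ``NaN`` marks a missing call.
    variants : DataFrame
        One row per variant with columns ``variant_id, chrom, pos,
        effect_allele, other_allele``; ``variant_id`` must be unique.
    samples : DataFrame
        One row per sample; must contain ``sample_id``, ``age`` (years) and
        ``sex`` (0/1).  The primary outcome lives in ``phenotype``; secondary
        outcomes (e.g. ``tangle_density``, ``braak_high``) may be added as
        extra columns.
    phenotype_type : {"quantitative", "binary"}
        Type of the primary outcome.
    truth : dict, optional
        Simulation-only bookkeeping (causal variant ids, true effects,
        attenuation, planted variance fractions).
    """

    cohort_name: str
    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    phenotype_type: str = "quantitative"
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D samples x variants matrix")
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise DataError(
                f"variant table has {len(self.variants)} rows for {m} dosage columns"
            )
        if len(self.samples) != n:
            raise DataError(
                f"sample table has {len(self.samples)} rows for {n} dosage rows"
            )
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants["variant_id"][self.variants["variant_id"].duplicated()]
            raise DataError(f"duplicate variant ids: {sorted(set(dup))[:5]}")
        if (self.variants["effect_allele"] == self.variants["other_allele"]).any():
            raise DataError("effect_allele must differ from other_allele")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise DataError("dosage entries must lie in [0, 2] or be NaN")
        if self.phenotype_type not in ("quantitative", "binary"):
            raise DataError(f"unknown phenotype_type {self.phenotype_type!r}")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy(dtype=float)

    def allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def hard_calls(self) -> np.ndarray:
        """Dosages rounded to the nearest genotype {0, 1, 2}; NaN preserved."""
        out = np.round(self.dosages)
        return np.clip(out, 0, 2, out=out)

    def subset_variants(self, keep: np.ndarray | list[str]) -> "CohortDataset":
        """Return a copy restricted to the given variant ids or boolean mask."""
        if np.asarray(keep).dtype == bool:
            mask = np.asarray(keep)
        else:
            mask = self.variant_ids.isin(keep)
        return CohortDataset(
            cohort_name=self.cohort_name,
            dosages=self.dosages[:, mask],
            variants=self.variants.loc[mask].reset_index(drop=True),
            samples=self.samples.copy(),
            phenotype_type=self.phenotype_type,
            truth=self.truth,
        )

    def subset_samples(self, keep: np.ndarray | list[str]) -> "CohortDataset":
        """Return a copy restricted to the given sample ids or boolean mask."""
        if np.asarray(keep).dtype == bool:
            mask = np.asarray(keep)
        else:
            mask = self.sample_ids.isin(keep)
        return CohortDataset(
            cohort_name=self.cohort_name,
            dosages=self.dosages[mask],
            variants=self.variants.copy(),
            samples=self.samples.loc[mask].reset_index(drop=True),
            phenotype_type=self.phenotype_type,
            truth=self.truth,
        )


def check_summary_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-variant summary-statistics frame against its contract."""
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"summary frame missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise DataError("summary frame contains non-positive standard errors")
    return df
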