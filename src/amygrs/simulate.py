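"""Multi-cohort synthetic genotype/phenotype generator.

The generator emulates the data layout of an endophenotype GWAS + risk-score
study: two discovery cohorts with a quantitative amyloid-PET-like outcome on
a Centiloid-like scale, one independent neuropathology cohort (percent-area
amyloid burden, tangle density, and a binary high-Braak indicator), and one
plasma-biomarker validation cohort (pg/mL-like scale).

Genotypes come from a latent-Gaussian threshold model: within each LD block
the haplotype-level latent variables follow an AR(1) correlation ``ld_rho``;
each haplotype allele is the indicator that its latent value falls below the
allele-frequency quantile, and the dosage is the sum of two independent
haplotypes.  This keeps every variant in Hardy-Weinberg equilibrium within an
ancestry stratum while giving a controllable between-variant r².  Population
structure follows a Balding-Nichols model: per-stratum allele frequencies are
Beta-distributed around the base frequency with drift parameter ``fst``.

A small set of causal variants, one per (distinct, randomly chosen) LD block,
carries true effects shared across cohorts up to a per-cohort attenuation
multiplier, which models the imperfect genetic correlation between amyloid
PET, postmortem burden, and plasma biomarker readouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CohortDataset, DataError

logger = logging.getLogger(__name__)

#: Default cohort sizes: two discovery cohorts, one neuropathology
#: refinement cohort, one plasma validation cohort.
DEFAULT_COHORT_SIZES = {
    "discovery_a": 983,
    "discovery_b": 513,
    "neuropath": 710,
    "plasma": 641,
}

#: Which outcome each default cohort carries.
DEFAULT_MODALITIES = {
    "discovery_a": "amyloid_pet",
    "discovery_b": "amyloid_pet",
    "neuropath": "neuropath_amyloid",
    "plasma": "plasma_ptau",
}

#: Cross-modality attenuation of the causal effects.
DEFAULT_ATTENUATION = {
    "discovery_a": 1.0,
    "discovery_b": 1.0,
    "neuropath": 0.7,
    "plasma": 0.6,
}

#: Affine (location, scale) mapping from the internal standardized phenotype
#: to each modality's reporting units.
MODALITY_SCALES = {
    "amyloid_pet": (35.0, 33.0),        # Centiloid-like
    "neuropath_amyloid": (2.2, 1.8),    # percent-area-like
    "plasma_ptau": (2.34, 1.6),         # pg/mL-like
}

VALID_MODALITIES = tuple(MODALITY_SCALES)


class SimulationError(ValueError):
    """Raised for invalid simulation configuration; names the bad field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    seed : int
        Master seed; identical config (including seed) gives bit-identical
        datasets.
    n_per_cohort : mapping cohort name -> sample count.
    m_variants : int
        Total variant count (split into AR(1) LD blocks).
    ld_block_size : int
        Variants per LD block.
    ld_rho : float in [0, 1)
        Adjacent-variant latent correlation within a block.
    maf_range : (low, high) in (0, 0.5]
        Base allele frequencies are drawn uniformly in this range.
    n_causal : int
        Number of causal variants; each occupies its own LD block.
    h2_target : float in [0, 1)
        Fraction of phenotype variance (covariates aside) explained by the
        causal variants in an unattenuated cohort.
    effect_attenuation : mapping cohort name -> multiplier on causal betas.
    covariate_effects : (age_beta, sex_beta)
        Effects per year of age / for sex=1 on the standardized phenotype.
    n_ancestry_strata : int
        Number of ancestry strata (Balding-Nichols frequency drift).
    fst : float
        Drift parameter of the per-stratum allele-frequency distribution.
    missing_rate : float
        Per-genotype completely-at-random missingness probability.
    braak_threshold : float in (0, 1)
        Quantile of the latent tangle burden defining the binary high-Braak
        outcome.
    stratum_phenotype_shift : float
        Additive per-stratum phenotype offset (standardized units); nonzero
        values create genuine population-stratification confounding that the
        principal-component covariates must absorb.
    tangle_attenuation : float
        Attenuation of causal effects on the latent tangle phenotype.
    """

    seed: int = 0
    n_per_cohort: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    m_variants: int = 20_000
    ld_block_size: int = 20
    ld_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 8
    h2_target: float = 0.24
    effect_attenuation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION))
    covariate_effects: tuple[float, float] = (0.01, 0.15)
    n_ancestry_strata: int = 2
    fst: float = 0.01
    missing_rate: float = 0.002
    braak_threshold: float = 0.8
    stratum_phenotype_shift: float = 0.0
    tangle_attenuation: float = 0.5
    modalities: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MODALITIES))

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise SimulationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        low, high = self.maf_range
        if not 0.0 < low <= high <= 0.5:
            raise SimulationError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_causal > self.m_variants:
            raise SimulationError(f"n_causal ({self.n_causal}) exceeds m_variants ({self.m_variants})")
        if not 0.0 <= self.h2_target < 1.0:
            raise SimulationError(f"h2_target must be in [0, 1), got {self.h2_target}")
        if self.m_variants <= 0:
            raise SimulationError(f"m_variants must be positive, got {self.m_variants}")
        if self.ld_block_size <= 0:
            raise SimulationError(f"ld_block_size must be positive, got {self.ld_block_size}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0.0 < self.braak_threshold < 1.0:
            raise SimulationError(f"braak_threshold must be in (0, 1), got {self.braak_threshold}")
        if self.n_ancestry_strata < 1:
            raise SimulationError(f"n_ancestry_strata must be >= 1, got {self.n_ancestry_strata}")
        if not 0.0 < self.fst < 1.0:
            raise SimulationError(f"fst must be in (0, 1), got {self.fst}")
        for name in self.n_per_cohort:
            if self.n_per_cohort[name] <= 0:
                raise SimulationError(f"n_per_cohort[{name!r}] must be positive")
        n_blocks = -(-self.m_variants // self.ld_block_size)
        if self.n_causal > n_blocks:
            raise SimulationError(
                f"n_causal ({self.n_causal}) exceeds the number of LD blocks ({n_blocks})")

    def cohort_names(self) -> list[str]:
        return list(self.n_per_cohort)

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        d["covariate_effects"] = list(d["covariate_effects"])
        d["n_per_cohort"] = dict(d["n_per_cohort"])
        d["effect_attenuation"] = dict(d["effect_attenuation"])
        d["modalities"] = dict(d["modalities"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("maf_range", "covariate_effects"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Shared variant-level model (identical across cohorts for a given config)
# ---------------------------------------------------------------------------

@dataclass
class _VariantModel:
    """Variant-level randomness shared by all cohorts of one study."""

    variants: pd.DataFrame           # id / chrom / pos / alleles / block
    base_freq: np.ndarray            # (m,) base effect-allele frequency
    stratum_freq: np.ndarray         # (n_strata, m)
    block_index: np.ndarray          # (m,) LD-block id per variant
    causal_idx: np.ndarray           # (n_causal,) column indices
    causal_beta: np.ndarray          # (n_causal,) effects on standardized scale
    dosage_var: np.ndarray           # (m,) theoretical dosage variance
    chol: np.ndarray                 # Cholesky factor of the AR(1) block


def _ar1_cholesky(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def _variant_model(config: SimulationConfig) -> _VariantModel:
    """Draw the study-level variant model deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    m = config.m_variants
    bs = config.ld_block_size
    n_blocks = -(-m // bs)
    block_index = np.repeat(np.arange(n_blocks), bs)[:m]

    low, high = config.maf_range
    base_freq = rng.uniform(low, high, size=m)

    # Balding-Nichols per-stratum frequencies around the base frequency;
    # with a single stratum there is no divergence and the base is used.
    if config.n_ancestry_strata == 1:
        stratum_freq = base_freq[None, :].copy()
    else:
        f = config.fst
        a = base_freq * (1 - f) / f
        b = (1 - base_freq) * (1 - f) / f
        stratum_freq = np.empty((config.n_ancestry_strata, m))
        for s in range(config.n_ancestry_strata):
            stratum_freq[s] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)

    # Theoretical dosage variance under equal stratum mixing: within-stratum
    # binomial variance plus between-stratum variance of the mean dosage.
    mean_d = 2 * stratum_freq
    within = (2 * stratum_freq * (1 - stratum_freq)).mean(axis=0)
    between = mean_d.var(axis=0)
    dosage_var = within + between

    # Causal variants: one per block, in distinct randomly chosen blocks.
    causal_blocks = rng.choice(n_blocks, size=config.n_causal, replace=False)
    causal_idx = np.empty(config.n_causal, dtype=int)
    for i, blk in enumerate(np.sort(causal_blocks)):
        cols = np.flatnonzero(block_index == blk)
        causal_idx[i] = rng.choice(cols)

    # Equal per-variant explained variance summing to h2_target.
    if config.n_causal > 0 and config.h2_target > 0:
        per_var = config.h2_target / config.n_causal
        signs = rng.choice([-1.0, 1.0], size=config.n_causal)
        causal_beta = signs * np.sqrt(per_var / dosage_var[causal_idx])
    else:
        causal_beta = np.zeros(config.n_causal)

    # Variant annotation: blocks laid along 22 chromosomes, 5 kb spacing
    # within a block, 1 Mb between block starts so distinct blocks never
    # fall inside one clumping window.
    chrom = (block_index % 22) + 1
    block_rank = np.zeros(m, dtype=int)
    for blk in range(n_blocks):
        cols = np.flatnonzero(block_index == blk)
        block_rank[cols] = np.arange(cols.size)
    block_on_chrom = block_index // 22
    pos = block_on_chrom * 1_000_000 + block_rank * 5_000 + 10_000
    alleles = np.array(["A", "C", "G", "T"])
    eff = rng.integers(0, 4, size=m)
    oth = (eff + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame({
        "variant_id": [f"snp{i:06d}" for i in range(m)],
        "chrom": chrom.astype(int),
        "pos": pos.astype(int),
        "effect_allele": alleles[eff],
        "other_allele": alleles[oth],
    })

    return _VariantModel(
        variants=variants,
        base_freq=base_freq,
        stratum_freq=stratum_freq,
        block_index=block_index,
        causal_idx=causal_idx,
        causal_beta=causal_beta,
        dosage_var=dosage_var,
        chol=_ar1_cholesky(bs, config.ld_rho),
    )


def _cohort_rng(config: SimulationConfig, cohort: str) -> np.random.Generator:
    names = sorted(config.n_per_cohort)
    try:
        idx = names.index(cohort)
    except ValueError:
        raise SimulationError(
            f"unknown cohort {cohort!r}; configured cohorts: {names}") from None
    return np.random.default_rng(np.random.SeedSequence([config.seed, 101, idx]))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig, cohort: str,
                       _model: _VariantModel | None = None) -> CohortDataset:
    """Simulate the genotype part of one cohort.

    The variant-level model (frequencies, LD blocks, causal placement) is a
    deterministic function of the config seed and therefore identical across
    cohorts; only the sample-level draws differ per cohort.  The returned
    dataset has an empty phenotype column (fill with
    :func:`simulate_phenotypes`) and carries the simulation truth in
    ``dataset.truth``.
    """
    model = _model if _model is not None else _variant_model(config)
    rng = _cohort_rng(config, cohort)
    n = config.n_per_cohort[cohort]
    m = config.m_variants
    bs = config.ld_block_size
    n_blocks = -(-m // bs)

    strata = rng.integers(0, config.n_ancestry_strata, size=n)

    # Latent AR(1) haplotype draws, correlated within each block via the
    # shared Cholesky factor, then thresholded at the per-stratum
    # allele-frequency quantile.  Two independent haplotypes per sample.
    thresholds = stats.norm.ppf(model.stratum_freq)[strata]  # (n, m)
    dosage = np.zeros((n, m), dtype=np.float64)
    pad = n_blocks * bs - m
    for _hap in range(2):
        z = rng.standard_normal((n, n_blocks * bs))
        z = z.reshape(n * n_blocks, bs) @ model.chol.T
        z = z.reshape(n, n_blocks * bs)
        if pad:
            z = z[:, :m]
        dosage += (z < thresholds)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage[miss] = np.nan

    age = rng.normal(74.0, 9.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    samples = pd.DataFrame({
        "sample_id": [f"{cohort}_s{i:05d}" for i in range(n)],
        "phenotype": np.full(n, np.nan),
        "age": age,
        "sex": sex,
        "stratum": strata,
    })

    truth = {
        "causal_ids": model.variants["variant_id"].to_numpy()[model.causal_idx],
        "causal_idx": model.causal_idx.copy(),
        "causal_beta": model.causal_beta.copy(),
        "causal_block": model.block_index[model.causal_idx].copy(),
        "block_index": model.block_index.copy(),
        "dosage_var": model.dosage_var.copy(),
        "h2_target": config.h2_target,
    }
    return CohortDataset(
        cohort_name=cohort,
        dosages=dosage,
        variants=model.variants.copy(),
        samples=samples,
        phenotype_type="quantitative",
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(genotypes: CohortDataset, config: SimulationConfig,
                        modality: str) -> CohortDataset:
    """Fill in the phenotype for a simulated cohort.

    The standardized phenotype is

        y = sum_j a * beta_j * x_j + age_beta * (age - mean) + sex_beta * sex
            + stratum offset + e

    with the noise variance chosen so that the causal variants explain
    ``h2_target * a**2`` of the genetic-plus-noise variance, where ``a`` is
    the cohort's attenuation multiplier.  The result is mapped onto the
    modality's reporting scale (Centiloid-like, percent-area-like, pg/mL-like)
    by a fixed affine transform, which leaves every association statistic
    invariant.  Neuropathology cohorts additionally receive a latent tangle
    density and the binary high-Braak indicator obtained by thresholding it
    at the ``braak_threshold`` quantile.
    """
    if modality not in VALID_MODALITIES:
        raise SimulationError(
            f"unknown modality {modality!r}; valid modalities: {sorted(VALID_MODALITIES)}")
    if genotypes.truth is None:
        raise SimulationError("genotypes must carry simulation truth")
    cohort = genotypes.cohort_name
    atten = dict(config.effect_attenuation).get(cohort, 1.0)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 202,
                                sorted(config.n_per_cohort).index(cohort)]))

    truth = dict(genotypes.truth)
    causal_idx = truth["causal_idx"]
    beta = truth["causal_beta"]
    n = genotypes.n_samples

    # Genetic value from complete(d) dosages: missing entries contribute
    # their expectation so the planted variance bookkeeping stays exact.
    X = genotypes.dosages[:, causal_idx]
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    g = X @ (atten * beta)

    h2 = config.h2_target
    h2_cohort = h2 * atten ** 2
    noise_sd = np.sqrt(1.0 - h2_cohort) if h2 > 0 else 1.0
    e = rng.standard_normal(n) * noise_sd

    age_beta, sex_beta = config.covariate_effects
    age = genotypes.samples["age"].to_numpy()
    sex = genotypes.samples["sex"].to_numpy()
    cov = age_beta * (age - age.mean()) + sex_beta * sex
    strat = config.stratum_phenotype_shift * genotypes.samples["stratum"].to_numpy()

    y_std = g - g.mean() + cov + strat + e
    loc, scale = MODALITY_SCALES[modality]
    samples = genotypes.samples.copy()
    samples["phenotype"] = loc + scale * y_std

    if modality == "neuropath_amyloid":
        ta = config.tangle_attenuation
        g_t = X @ (ta * beta)
        h2_t = h2 * ta ** 2
        e_t = rng.standard_normal(n) * (np.sqrt(1.0 - h2_t) if h2 > 0 else 1.0)
        tangle = g_t - g_t.mean() + cov + strat + e_t
        samples["tangle_density"] = 1.5 + 0.9 * tangle
        cut = np.quantile(samples["tangle_density"], config.braak_threshold)
        samples["braak_high"] = (samples["tangle_density"] > cut).astype(int)

    truth["attenuation"] = atten
    truth["modality"] = modality
    truth["phenotype_scale"] = scale
    # Planted causal variance fraction of the genetic+noise part.
    truth["h2_cohort"] = h2_cohort
    return CohortDataset(
        cohort_name=cohort,
        dosages=genotypes.dosages,
        variants=genotypes.variants,
        samples=samples,
        phenotype_type=genotypes.phenotype_type,
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig, cohort: str,
                    _model: _VariantModel | None = None) -> CohortDataset:
    """Genotypes plus phenotype for one cohort in one call."""
    modality = dict(config.modalities).get(cohort, "amyloid_pet")
    geno = simulate_genotypes(config, cohort, _model=_model)
    return simulate_phenotypes(geno, config, modality)


def count_recovered_blocks(data: CohortDataset, variant_ids) -> int:
    """How many planted causal LD blocks contain at least one of the given
    variants (simulation truth required)."""
    if data.truth is None:
        raise SimulationError("dataset carries no simulation truth")
    block_of = dict(zip(data.variants["variant_id"], data.truth["block_index"]))
    hit = {block_of[v] for v in variant_ids if v in block_of}
    return len(hit & set(data.truth["causal_block"]))


def true_genetic_value(data: CohortDataset) -> np.ndarray:
    """Attenuated true genetic value per sample (simulation truth required).

    Missing causal dosages contribute their cohort mean, matching the
    phenotype generator's bookkeeping.
    """
    if data.truth is None:
        raise SimulationError("dataset carries no simulation truth")
    X = data.dosages[:, data.truth["causal_idx"]]
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    return X @ (data.truth.get("attenuation", 1.0) * data.truth["causal_beta"])


def simulate_study(config: SimulationConfig) -> dict[str, CohortDataset]:
    """Simulate every configured cohort over a shared variant model."""
    model = _variant_model(config)
    return {name: simulate_cohort(config, name, _model=model)
            for name in config.n_per_cohort}
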