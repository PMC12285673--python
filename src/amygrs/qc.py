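"""Variant- and sample-level genotype quality control.

Filters follow standard array-QC practice: variants are dropped for low call
rate, Hardy-Weinberg disequilibrium (exact test), or low minor allele
frequency, in that documented order; samples are dropped for low call rate or
relatedness (method-of-moments PI_HAT on identity-by-state counts, the PLINK
convention).  Each unit is attributed to the first filter it fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datasets import CohortDataset, DataError

logger = logging.getLogger(__name__)

VARIANT_FILTER_ORDER = ["call_rate", "hwe", "maf"]
SAMPLE_FILTER_ORDER = ["call_rate", "relatedness"]


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for genotype QC.

    ``maf_min_array`` is the raw-array floor (MAF < 1% excluded at array QC);
    ``maf_min_analysis`` is the stricter analysis floor (common variants only,
    MAF >= 5%) actually applied by :func:`apply_variant_qc`.
    """

    variant_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-5
    maf_min_array: float = 0.01
    maf_min_analysis: float = 0.05
    sample_call_rate_min: float = 0.98
    pi_hat_max: float = 0.25

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"QC threshold {name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-filter accounting for one QC pass."""

    stage: str                               # "variant" or "sample"
    n_in: int = 0
    n_out: int = 0
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed.items()}

    def check(self) -> None:
        if self.n_in - self.n_out != sum(self.counts.values()):
            raise DataError("QC report counts are inconsistent")

    def to_text(self) -> str:
        lines = [f"{self.stage} QC: {self.n_in} in, {self.n_out} out"]
        for flt, ids in self.removed.items():
            lines.append(f"  {flt}: removed {len(ids)}")
        return "\n".join(lines)

    def to_frame(self):
        """Machine-readable removals: one row per (filter, removed id)."""
        import pandas as pd

        rows = [(self.stage, flt, i) for flt, ids in self.removed.items()
                for i in ids]
        return pd.DataFrame(rows, columns=["stage", "filter", "removed_id"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

_LOG2 = np.log(2.0)
_LFACT_CACHE = gammaln(np.arange(512) + 1.0)


def _log_factorials(n_max: int) -> np.ndarray:
    """Cached table of log k! for k = 0..n_max."""
    global _LFACT_CACHE
    if n_max >= _LFACT_CACHE.size:
        _LFACT_CACHE = gammaln(np.arange(2 * n_max + 2) + 1.0)
    return _LFACT_CACHE


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed count.  A monomorphic site returns 1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise DataError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise DataError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # log P(het = h | n, allele counts) up to a shared constant, for every
    # heterozygote count h compatible with the allele-count parity.
    lfact = _log_factorials(n_A + n_a)
    h = np.arange(rare % 2, rare + 1, 2)
    logp = (h * _LOG2
            - lfact[(n_A - h) // 2] - lfact[h] - lfact[(n_a - h) // 2])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[h == n_Aa][0]
    # Relative tolerance guards against float noise at exact ties.
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-9)].sum()))


def _hwe_pvalues(hard_calls: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per variant column of a hard-call matrix.

    Same statistic as :func:`hwe_exact_test`, with the log-factorials taken
    from a shared lookup table so a 20k-variant scan stays fast.
    """
    n_aa = np.nansum(hard_calls == 2, axis=0).astype(int)
    n_Aa = np.nansum(hard_calls == 1, axis=0).astype(int)
    n_AA = np.nansum(hard_calls == 0, axis=0).astype(int)
    n_max = int((n_AA + n_Aa + n_aa).max(initial=0))
    lfact = gammaln(np.arange(2 * n_max + 2) + 1.0)
    log2 = np.log(2.0)

    out = np.empty(hard_calls.shape[1])
    for j in range(hard_calls.shape[1]):
        na = 2 * n_aa[j] + n_Aa[j]
        nA = 2 * n_AA[j] + n_Aa[j]
        if na + nA == 0:
            out[j] = 1.0
            continue
        rare = min(na, nA)
        if rare == 0:
            out[j] = 1.0
            continue
        h = np.arange(rare % 2, rare + 1, 2)
        logp = h * log2 - lfact[(nA - h) // 2] - lfact[h] - lfact[(na - h) // 2]
        logp -= logp.max()
        probs = np.exp(logp)
        probs /= probs.sum()
        obs = probs[(h == n_Aa[j])][0]
        out[j] = min(1.0, float(probs[probs <= obs * (1.0 + 1e-9)].sum()))
    return out


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def apply_variant_qc(data: CohortDataset,
                     th: QCThresholds = QCThresholds()
                     ) -> tuple[CohortDataset, QCReport]:
    """Remove variants failing call rate, HWE, or MAF (in that order).

    HWE is computed on hard calls (fractional dosages rounded); association
    downstream keeps the fractional values.  MAF uses the folded allele
    frequency against the analysis floor.
    """
    if data.n_variants == 0:
        raise DataError("dataset has no variants")
    report = QCReport(stage="variant", n_in=data.n_variants)
    ids = data.variants["variant_id"].to_numpy()

    call_rate = 1.0 - np.isnan(data.dosages).mean(axis=0)
    fail_cr = call_rate < th.variant_call_rate_min

    hard = data.hard_calls()
    todo = ~fail_cr
    hwe_p = np.ones(data.n_variants)
    hwe_p[todo] = _hwe_pvalues(hard[:, todo])
    fail_hwe = (hwe_p < th.hwe_p_min) & ~fail_cr

    af = data.allele_freq()
    maf = np.minimum(af, 1.0 - af)
    fail_maf = (maf < th.maf_min_analysis) & ~fail_cr & ~fail_hwe

    report.removed["call_rate"] = list(ids[fail_cr])
    report.removed["hwe"] = list(ids[fail_hwe])
    report.removed["maf"] = list(ids[fail_maf])
    keep = ~(fail_cr | fail_hwe | fail_maf)
    report.n_out = int(keep.sum())
    report.check()
    if report.n_out == 0:
        raise DataError(
            "variant QC removed every variant; review thresholds "
            f"(call_rate_min={th.variant_call_rate_min}, hwe_p_min={th.hwe_p_min}, "
            f"maf_min={th.maf_min_analysis})")
    logger.info(report.to_text())
    return data.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Relatedness (IBS -> method-of-moments IBD)
# ---------------------------------------------------------------------------

def _ibs_expectations(freq: np.ndarray) -> tuple[float, float, float, float]:
    """Per-variant-mean IBS expectations under IBD 0/1 given allele freqs."""
    p = freq
    q = 1.0 - p
    e0_ibd0 = float(np.mean(2 * p**2 * q**2))
    e1_ibd0 = float(np.mean(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.mean(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.mean(2 * p * q))
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1


def _pi_hat_from_ibs(n0: float, n1: float, n2: float, m: float,
                     exp: tuple[float, float, float, float]) -> float:
    """Solve the method-of-moments IBD decomposition for one pair."""
    e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1 = exp
    p0 = n0 / (m * e0_ibd0) if e0_ibd0 > 0 else 0.0
    p1 = (n1 - p0 * m * e1_ibd0) / (m * e1_ibd1) if e1_ibd1 > 0 else 0.0
    p0 = min(max(p0, 0.0), 1.0)
    p1 = min(max(p1, 0.0), 1.0)
    p2 = 1.0 - p0 - p1
    p2 = min(max(p2, 0.0), 1.0)
    total = p0 + p1 + p2
    if total > 0:
        p0, p1, p2 = p0 / total, p1 / total, p2 / total
    return min(max(p1 / 2.0 + p2, 0.0), 1.0)


def estimate_pi_hat(data: CohortDataset, pair: tuple[str, str],
                    min_variants: int = 500) -> float:
    """PI_HAT (proportion of genome shared IBD) for one sample pair.

    Method-of-moments decomposition of identity-by-state counts with allele
    frequencies estimated from the full sample; hard calls are used, and the
    estimate is clamped to [0, 1].  Requires at least ``min_variants``
    jointly non-missing variants.
    """
    sid = data.sample_ids
    try:
        i = sid.get_loc(pair[0])
        j = sid.get_loc(pair[1])
    except KeyError as exc:
        raise DataError(f"sample not found: {exc}") from None
    hard = data.hard_calls()
    gi, gj = hard[i], hard[j]
    valid = ~np.isnan(gi) & ~np.isnan(gj)
    m = int(valid.sum())
    if m < min_variants:
        raise DataError(
            f"only {m} jointly non-missing variants for pair {pair}; "
            f"need >= {min_variants} for a stable PI_HAT estimate")
    freq = data.allele_freq()[valid]
    diff = np.abs(gi[valid] - gj[valid])
    n0 = float((diff == 2).sum())
    n1 = float((diff == 1).sum())
    n2 = float((diff == 0).sum())
    return _pi_hat_from_ibs(n0, n1, n2, m, _ibs_expectations(freq))


def pairwise_pi_hat(data: CohortDataset,
                    max_variants: int | None = None) -> np.ndarray:
    """PI_HAT for every sample pair (symmetric matrix, diagonal = 1).

    IBS counts are accumulated with indicator-matrix products so the cost is
    a few BLAS calls rather than an O(n^2 m) Python loop.  If
    ``max_variants`` is given, an evenly spaced variant subset of that size
    is used (adequate for relatedness screening; the per-pair
    :func:`estimate_pi_hat` uses all shared variants).  Expected IBS counts
    are scaled by each pair's jointly non-missing fraction, which is exact
    under completely-at-random missingness.
    """
    hard = data.hard_calls()
    freq = data.allele_freq()
    m_all = hard.shape[1]
    if max_variants is not None and m_all > max_variants:
        idx = np.linspace(0, m_all - 1, max_variants).astype(int)
        hard = hard[:, idx]
        freq = freq[idx]
    n, m = hard.shape
    if m < 500:
        raise DataError(f"need >= 500 variants for relatedness screening, have {m}")

    nonmiss = (~np.isnan(hard)).astype(np.float32)
    ind = [np.where(np.nan_to_num(hard, nan=-1.0) == g, 1.0, 0.0).astype(np.float32)
           for g in (0.0, 1.0, 2.0)]
    valid = nonmiss @ nonmiss.T
    ibs0 = ind[0] @ ind[2].T
    ibs0 = ibs0 + ibs0.T
    ibs2 = sum(a @ a.T for a in ind)
    ibs1 = valid - ibs0 - ibs2

    e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1 = _ibs_expectations(freq)
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0 / (valid * e0_ibd0)
        p1 = (ibs1 - p0 * valid * e1_ibd0) / (valid * e1_ibd1)
    p0 = np.clip(np.nan_to_num(p0), 0.0, 1.0)
    p1 = np.clip(np.nan_to_num(p1), 0.0, 1.0)
    p2 = np.clip(1.0 - p0 - p1, 0.0, 1.0)
    total = p0 + p1 + p2
    total[total == 0] = 1.0
    pi = np.clip((p1 / 2.0 + p2) / total, 0.0, 1.0)
    np.fill_diagonal(pi, 1.0)
    return pi.astype(float)


def apply_sample_qc(data: CohortDataset,
                    th: QCThresholds = QCThresholds(),
                    relatedness_max_variants: int | None = 5000
                    ) -> tuple[CohortDataset, QCReport]:
    """Remove low-call-rate samples, then one member of each related pair.

    For a pair with PI_HAT >= ``th.pi_hat_max`` the member with the lower
    genotype call rate is removed (tie: the later sample in table order).
    """
    if data.n_samples < 2:
        raise DataError("sample QC requires at least 2 samples")
    report = QCReport(stage="sample", n_in=data.n_samples)
    ids = data.samples["sample_id"].to_numpy()

    call_rate = 1.0 - np.isnan(data.dosages).mean(axis=1)
    fail_cr = call_rate < th.sample_call_rate_min
    report.removed["call_rate"] = list(ids[fail_cr])

    kept = data.subset_samples(~fail_cr)
    kept_cr = call_rate[~fail_cr]
    pi = pairwise_pi_hat(kept, max_variants=relatedness_max_variants)
    n_kept = kept.n_samples
    drop = np.zeros(n_kept, dtype=bool)
    ii, jj = np.nonzero(np.triu(pi >= th.pi_hat_max, k=1))
    for a, b in zip(ii, jj):
        if drop[a] or drop[b]:
            continue
        # Lower call rate loses; tie broken against the later sample.
        drop[b if kept_cr[b] <= kept_cr[a] else a] = True
    report.removed["relatedness"] = list(kept.samples["sample_id"].to_numpy()[drop])

    out = kept.subset_samples(~drop)
    report.n_out = out.n_samples
    report.check()
    if report.n_out == 0:
        raise DataError("sample QC removed every sample; review thresholds")
    logger.info(report.to_text())
    return out, report
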