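"""Cross-cohort aggregation and independent-cohort refinement.

Random-effects inverse-variance meta-analysis (DerSimonian-Laird tau^2)
pools the per-cohort GWAS summaries; a suggestive p-value threshold selects
candidate variants; the refinement step keeps only candidates that show a
nominally concordant signal (two-sided p below a lenient cutoff *and* the
same direction of effect) in an independent replication cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DataError, META_COLUMNS, check_summary_frame

logger = logging.getLogger(__name__)

REFINE_REASONS = ("missing_in_replication", "p_fail", "sign_fail", "pass")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(reference: pd.DataFrame,
                      other: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Align ``other``'s effect alleles to ``reference``'s.

    Where the effect/other alleles are swapped relative to the reference the
    beta is negated and the allele frequency complemented; variants whose
    allele pair cannot be reconciled are dropped (count returned).  Variants
    absent from the reference pass through unchanged.
    """
    ref = reference.set_index("variant_id")
    out = other.copy()
    drop = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        vid = row.variant_id
        if vid not in ref.index:
            continue
        r = ref.loc[vid]
        if row.effect_allele == r["effect_allele"] and row.other_allele == r["other_allele"]:
            continue
        if row.effect_allele == r["other_allele"] and row.other_allele == r["effect_allele"]:
            out.iat[i, out.columns.get_loc("beta")] = -row.beta
            if "eaf" in out.columns:
                out.iat[i, out.columns.get_loc("eaf")] = 1.0 - row.eaf
            out.iat[i, out.columns.get_loc("effect_allele")] = r["effect_allele"]
            out.iat[i, out.columns.get_loc("other_allele")] = r["other_allele"]
            continue
        drop[i] = True
    n_dropped = int(drop.sum())
    if n_dropped:
        logger.warning("harmonize_alleles: dropped %d variants with "
                       "irreconcilable allele pairs", n_dropped)
    return out.loc[~drop].reset_index(drop=True), n_dropped


# ---------------------------------------------------------------------------
# DerSimonian-Laird random-effects meta-analysis
# ---------------------------------------------------------------------------

def meta_analyze(per_study: list[pd.DataFrame],
                 method: str = "random") -> pd.DataFrame:
    """Inverse-variance meta-analysis across studies.

    ``method="random"`` (the primary path) uses the DerSimonian-Laird
    moment estimator: with fixed weights ``w_i = 1/se_i^2``, heterogeneity
    ``Q = sum w_i (b_i - b_fixed)^2`` and ``tau2 = max(0, (Q - (k-1)) /
    (sum w - sum w^2 / sum w))``; the pooled effect uses weights
    ``1/(se_i^2 + tau2)`` and a normal two-sided p-value.
    ``method="fixed"`` forces ``tau2 = 0`` (comparison mode).  Variants
    present in a single study carry that study's statistics with ``k=1``
    and ``tau2=0``.  Effect alleles must be harmonized beforehand.
    """
    if method not in ("random", "fixed"):
        raise DataError(f"unknown meta-analysis method {method!r}")
    if not per_study:
        raise DataError("meta_analyze requires at least one study")
    for df in per_study:
        check_summary_frame(df)

    k_max = len(per_study)
    # Union of variants, first-seen order; per-study beta/se matrices.
    order: dict[str, int] = {}
    meta_rows: list[pd.Series] = []
    for df in per_study:
        for row in df.itertuples(index=False):
            if row.variant_id not in order:
                order[row.variant_id] = len(order)
                meta_rows.append(row)
    m = len(order)
    beta = np.full((m, k_max), np.nan)
    se = np.full((m, k_max), np.nan)
    for s, df in enumerate(per_study):
        rows = df["variant_id"].map(order).to_numpy()
        beta[rows, s] = df["beta"].to_numpy(dtype=float)
        se[rows, s] = df["se"].to_numpy(dtype=float)

    present = ~np.isnan(se)
    k = present.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(present, 1.0 / se**2, 0.0)
        sum_w = w.sum(axis=1)
        beta0 = np.where(present, beta, 0.0)
        beta_fixed = (w * beta0).sum(axis=1) / sum_w
        q = (w * (beta0 - beta_fixed[:, None]) ** 2 * present).sum(axis=1)
        denom = sum_w - (w**2).sum(axis=1) / sum_w
        tau2 = np.where(k > 1, np.maximum(0.0, (q - (k - 1)) / denom), 0.0)
        if method == "fixed":
            tau2 = np.zeros_like(tau2)
        w_star = np.where(present, 1.0 / (se**2 + tau2[:, None]), 0.0)
        beta_meta = (w_star * beta0).sum(axis=1) / w_star.sum(axis=1)
        se_meta = 1.0 / np.sqrt(w_star.sum(axis=1))
    p_meta = 2.0 * stats.norm.sf(np.abs(beta_meta / se_meta))

    signs = np.where(~present, None, np.where(beta0 > 0, "+",
                     np.where(beta0 < 0, "-", "0")))
    directions = ["".join("?" if s is None else s for s in row) for row in signs]

    anno = pd.DataFrame({
        "variant_id": [r.variant_id for r in meta_rows],
        "chrom": [r.chrom for r in meta_rows],
        "pos": [r.pos for r in meta_rows],
        "effect_allele": [r.effect_allele for r in meta_rows],
        "other_allele": [r.other_allele for r in meta_rows],
    })
    out = anno.assign(beta=beta_meta, se=se_meta, p=p_meta, q_stat=q,
                      tau2=tau2, k=k, directions=directions)
    return out[META_COLUMNS]


def select_candidates(meta: pd.DataFrame, p_threshold: float = 5e-5) -> pd.DataFrame:
    """Variants with meta-analytic p strictly below the suggestive threshold,
    sorted ascending by p."""
    if meta.empty:
        raise DataError("meta result is empty")
    out = meta.loc[meta["p"] < p_threshold].sort_values(
        ["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
    if out.empty:
        logger.info("select_candidates: no variant below p < %g", p_threshold)
    return out


# ---------------------------------------------------------------------------
# Refinement against the independent replication cohort
# ---------------------------------------------------------------------------

def refine_candidates(candidates: pd.DataFrame, replication: pd.DataFrame,
                      p_max: float = 0.2) -> pd.DataFrame:
    """Filter candidates against an independent replication analysis.

    A candidate is retained iff it is present in the replication summary,
    its two-sided replication p is strictly below ``p_max``, and the
    replication effect has the same sign as the meta-analytic effect
    (alleles must be harmonized beforehand).  Every candidate receives a
    decision record; a failing candidate is attributed to the first failing
    clause in the order missing -> p_fail -> sign_fail.
    """
    rep = replication.set_index("variant_id")
    records = []
    for row in candidates.itertuples(index=False):
        rec = {
            "variant_id": row.variant_id,
            "replication_p": np.nan,
            "replication_sign": "",
            "concordant": False,
            "retained": False,
            "reason": "missing_in_replication",
        }
        if row.variant_id in rep.index:
            r = rep.loc[row.variant_id]
            rp, rb = float(r["p"]), float(r["beta"])
            rec["replication_p"] = rp
            rec["replication_sign"] = "+" if rb > 0 else ("-" if rb < 0 else "0")
            rec["concordant"] = np.sign(rb) == np.sign(row.beta) and rb != 0
            if not rp < p_max:
                rec["reason"] = "p_fail"
            elif not rec["concordant"]:
                rec["reason"] = "sign_fail"
            else:
                rec["reason"] = "pass"
                rec["retained"] = True
        records.append(rec)
    decisions = pd.DataFrame(
        records, columns=["variant_id", "replication_p", "replication_sign",
                          "concordant", "retained", "reason"])
    counts = decisions["reason"].value_counts().to_dict()
    logger.info("refine_candidates: %s", counts)
    return decisions


def retained_candidates(candidates: pd.DataFrame,
                        decisions: pd.DataFrame) -> pd.DataFrame:
    """Subset of the candidate frame whose decision is ``pass``."""
    keep = decisions.loc[decisions["retained"], "variant_id"]
    return candidates.loc[candidates["variant_id"].isin(keep)].reset_index(drop=True)
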