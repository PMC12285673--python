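"""Clumping-and-thresholding genetic risk scores and their evaluation.

The score is built PRSice-style: greedy LD clumping of the refined candidate
list (best p first, removing correlated neighbours with r^2 at or above the
cutoff inside a genomic window), a prespecified p-value entry threshold, and
per-variant weights equal to the meta-analytic regression coefficients.
Scores are evaluated against quantitative outcomes by incremental variance
explained beyond covariates, and against binary outcomes by odds ratio with
a 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CohortDataset, DataError

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "weight"]


class ScoreError(DataError):
    """Raised when a score cannot be built or applied."""


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(data: CohortDataset, a: str, b: str, min_samples: int = 50) -> float:
    """Squared sample correlation between two variants' dosages
    (jointly non-missing samples)."""
    vid = data.variant_ids
    try:
        ia, ib = vid.get_loc(a), vid.get_loc(b)
    except KeyError as exc:
        raise ScoreError(f"variant not found: {exc}") from None
    x, y = data.dosages[:, ia], data.dosages[:, ib]
    use = ~np.isnan(x) & ~np.isnan(y)
    if use.sum() < min_samples:
        raise ScoreError(
            f"only {int(use.sum())} complete pairs for ({a}, {b}); need >= {min_samples}")
    x, y = x[use], y[use]
    if x.std() == 0 or y.std() == 0:
        raise ScoreError(f"zero dosage variance for pair ({a}, {b})")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def clump(candidates: pd.DataFrame, ld_panel: CohortDataset,
          r2_max: float = 0.1, window_kb: float = 250.0,
          min_samples: int = 50) -> pd.DataFrame:
    """Greedy LD clumping: keep the top associated variant of each clump.

    Repeatedly takes the remaining candidate with the smallest p (ties:
    smaller genomic position first) and discards every remaining candidate
    on the same chromosome within ``window_kb`` whose r^2 with it is at
    least ``r2_max``.  Candidates absent from the LD panel are excluded
    with a warning.  Returns the retained rows of ``candidates``.
    """
    panel_ids = set(ld_panel.variant_ids)
    present = candidates["variant_id"].isin(panel_ids)
    if not present.all():
        logger.warning("clump: %d candidates absent from the LD panel; excluded",
                       int((~present).sum()))
    cand = candidates.loc[present].sort_values(
        ["p", "chrom", "pos"], kind="stable").reset_index(drop=True)
    window = window_kb * 1000.0

    active = np.ones(len(cand), dtype=bool)
    retained: list[int] = []
    chrom = cand["chrom"].to_numpy()
    pos = cand["pos"].to_numpy(dtype=float)
    for i in range(len(cand)):
        if not active[i]:
            continue
        retained.append(i)
        near = (active & (chrom == chrom[i])
                & (np.abs(pos - pos[i]) <= window))
        near[i] = False
        for j in np.flatnonzero(near):
            r2 = ld_r2(ld_panel, cand["variant_id"].iat[i],
                       cand["variant_id"].iat[j], min_samples=min_samples)
            if r2 >= r2_max:
                active[j] = False
        active[i] = False
    return cand.iloc[retained].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

@dataclass
class GRSModel:
    """An ordered (variant, effect allele, weight) score definition."""

    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ScoreError(f"GRS entries missing columns {missing}")
        if self.entries["variant_id"].duplicated().any():
            raise ScoreError("GRS entries contain duplicate variant ids")
        w = self.entries["weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all() or (w == 0).any():
            raise ScoreError("GRS weights must be finite and nonzero")

    def __len__(self) -> int:
        return len(self.entries)

    def to_file(self, path: str | Path) -> None:
        self.entries[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path, weight_source: str = "external") -> "GRSModel":
        df = pd.read_csv(path, sep="\t")
        return cls(entries=df, provenance={"weight_source": weight_source,
                                           "path": str(path)})


def build_grs(retained: pd.DataFrame, p_threshold: float = 5e-5,
              clump_r2: float = 0.1, clump_window_kb: float = 250.0,
              weight_source: str = "discovery_meta") -> GRSModel:
    """Build a GRS from clumped candidates below the entry threshold.

    Weights are the meta-analytic betas.  Raises with a diagnostic if no
    variant survives.
    """
    entries = retained.loc[retained["p"] < p_threshold,
                           ["variant_id", "chrom", "pos", "effect_allele", "beta"]]
    entries = entries.rename(columns={"beta": "weight"}).reset_index(drop=True)
    if entries.empty:
        raise ScoreError(
            f"empty GRS: {len(retained)} clumped candidates, none with "
            f"p < {p_threshold} (best p = "
            f"{retained['p'].min() if len(retained) else 'n/a'})")
    return GRSModel(entries=entries, provenance={
        "clump_r2": clump_r2, "clump_window_kb": clump_window_kb,
        "p_threshold": p_threshold, "weight_source": weight_source,
    })


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_samples(model: GRSModel, data: CohortDataset,
                  normalize: str = "mean") -> pd.DataFrame:
    """Per-sample weighted allele score.

    Model variants are matched to the cohort by id and harmonized by allele
    (a swapped effect/other pair contributes ``2 - dosage``); irreconcilable
    or absent variants are logged and skipped.  Missing dosages are imputed
    as twice the scoring cohort's effect-allele frequency.  With
    ``normalize="mean"`` (the PRSice convention) the weighted sum is divided
    by the number of model variants used; ``"sum"`` returns the raw sum.
    """
    if normalize not in ("mean", "sum"):
        raise ScoreError(f"unknown normalization {normalize!r}")
    vid = data.variant_ids
    cols, weights = [], []
    n_absent = n_mismatch = 0
    flip = []
    for row in model.entries.itertuples(index=False):
        if row.variant_id not in vid:
            n_absent += 1
            continue
        j = vid.get_loc(row.variant_id)
        eff = data.variants["effect_allele"].iat[j]
        oth = data.variants["other_allele"].iat[j]
        if eff == row.effect_allele:
            flip.append(False)
        elif oth == row.effect_allele:
            flip.append(True)
        else:
            n_mismatch += 1
            continue
        cols.append(j)
        weights.append(row.weight)
    if n_absent or n_mismatch:
        logger.warning("score_samples: %d model variants absent, %d with "
                       "mismatching alleles", n_absent, n_mismatch)
    if not cols:
        raise ScoreError("no model variant is scoreable in this cohort")

    D = data.dosages[:, cols].copy()
    flip = np.asarray(flip)
    D[:, flip] = 2.0 - D[:, flip]
    eaf = np.nanmean(D, axis=0) / 2.0
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(2.0 * eaf, np.nonzero(nan_mask)[1])

    raw = D @ np.asarray(weights, dtype=float)
    used = len(cols)
    score = raw / used if normalize == "mean" else raw
    return pd.DataFrame({
        "sample_id": data.sample_ids,
        "score": score,
        "n_variants_used": used,
    })


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class AssociationReport:
    """Regression summary for a score-vs-outcome test."""

    outcome: str
    effect_type: str           # "beta" or "OR"
    effect: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    incremental_r2: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def __str__(self) -> str:
        base = (f"{self.outcome}: {self.effect_type}={self.effect:.4g} "
                f"[{self.ci_low:.4g}, {self.ci_high:.4g}], p={self.p:.3g}, n={self.n}")
        if self.incremental_r2 is not None:
            base += f", dR2={self.incremental_r2:.4f}"
        return base


def evaluate_grs(score: np.ndarray | pd.Series | pd.DataFrame,
                 data: CohortDataset,
                 covariates: pd.DataFrame | np.ndarray | None = None,
                 outcome: str = "phenotype",
                 binary: bool | None = None) -> AssociationReport:
    """Regress an outcome on the score, adjusting for covariates.

    Quantitative outcomes: OLS beta/se/p plus the incremental R^2 of the
    score beyond the covariates.  Binary outcomes: logistic regression,
    reported as odds ratio with 95% CI (no pseudo-R^2 is computed).
    """
    import statsmodels.api as sm

    from .gwas import _design_matrix

    if isinstance(score, pd.DataFrame):
        s = score["score"].to_numpy(dtype=float)
    else:
        s = np.asarray(score, dtype=float).reshape(-1)
    y = data.samples[outcome].to_numpy(dtype=float)
    if s.size != y.size:
        raise ScoreError(f"score length {s.size} != sample count {y.size}")
    use = ~np.isnan(y) & ~np.isnan(s)
    if isinstance(covariates, pd.DataFrame):
        cov_use = covariates.loc[use].reset_index(drop=True) if not use.all() else covariates
    elif covariates is not None:
        cov_use = np.asarray(covariates)[use]
    else:
        cov_use = None
    y, s = y[use], s[use]
    C, _ = _design_matrix(cov_use, y.size)

    if binary is None:
        binary = data.phenotype_type == "binary" or (
            outcome != "phenotype" and set(np.unique(y)) <= {0.0, 1.0})

    design = np.column_stack([s, C])
    if binary:
        fit = sm.Logit(y, design).fit(disp=0)
        beta, se = float(fit.params[0]), float(fit.bse[0])
        lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
        return AssociationReport(
            outcome=outcome, effect_type="OR", effect=float(np.exp(beta)),
            se=se, p=float(fit.pvalues[0]), ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)), n=int(y.size), incremental_r2=None)

    full = sm.OLS(y, design).fit()
    null = sm.OLS(y, C).fit()
    beta, se = float(full.params[0]), float(full.bse[0])
    tcrit = stats.t.ppf(0.975, full.df_resid)
    return AssociationReport(
        outcome=outcome, effect_type="beta", effect=beta, se=se,
        p=float(full.pvalues[0]), ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se, n=int(y.size),
        incremental_r2=float(full.rsquared - null.rsquared))


@dataclass
class ScoreComparison:
    """Side-by-side evaluation of two score models on one cohort."""

    report_a: AssociationReport
    report_b: AssociationReport
    delta_incremental_r2: float | None


def compare_scores(model_a: GRSModel, model_b: GRSModel, data: CohortDataset,
                   covariates: pd.DataFrame | np.ndarray | None = None,
                   outcome: str = "phenotype") -> ScoreComparison:
    """Evaluate two score models on the same cohort and difference their
    incremental variance explained."""
    rep_a = evaluate_grs(score_samples(model_a, data), data, covariates, outcome)
    rep_b = evaluate_grs(score_samples(model_b, data), data, covariates, outcome)
    delta = None
    if rep_a.incremental_r2 is not None and rep_b.incremental_r2 is not None:
        delta = rep_a.incremental_r2 - rep_b.incremental_r2
    return ScoreComparison(report_a=rep_a, report_b=rep_b,
                           delta_incremental_r2=delta)
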