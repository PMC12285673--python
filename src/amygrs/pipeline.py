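"""End-to-end orchestration of the four-phase score-building study.

Phase 1: per-cohort QC + GWAS in the discovery cohorts, random-effects
meta-analysis, suggestive-threshold candidate selection.  Phase 2:
refinement of the candidates against an independent neuropathology cohort
(lenient p plus concordant direction).  Phase 3: LD clumping and
thresholding into a weighted score.  Phase 4: evaluation of the score on
discovery and held-out validation outcomes (quantitative, binary, and an
optional comparator score).

The orchestrator follows the model/results idiom: :class:`GRSPipeline` is
built from in-memory cohorts plus a :class:`PipelineConfig`, and ``fit()``
returns a :class:`PipelineResults` carrying the fitted score model, the
per-phase funnel counts, genomic-inflation factors, association reports and
a ``summary()`` table.  :func:`run_pipeline` is the file-based wrapper used
by the command-line interface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import CohortDataset, DataError
from .gwas import compute_pcs, default_covariates, genomic_lambda, gwas_linear, gwas_logistic
from .io import read_cohort, write_cohort
from .meta import (harmonize_alleles, meta_analyze, refine_candidates,
                   retained_candidates, select_candidates)
from .qc import QCReport, QCThresholds, apply_sample_qc, apply_variant_qc
from .score import (AssociationReport, GRSModel, ScoreComparison, build_grs,
                    clump, compare_scores, evaluate_grs, score_samples)
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


class PipelineError(DataError):
    """A phase-level failure; carries the phase name and, when raised from a
    running pipeline, a partial report of the completed phases."""

    def __init__(self, phase: str, message: str,
                 partial_report: "RunReport | None" = None):
        super().__init__(f"[{phase}] {message}")
        self.phase = phase
        self.partial_report = partial_report


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    discovery: list[str] = field(default_factory=lambda: ["discovery_a", "discovery_b"])
    refinement: str = "neuropath"
    validation: list[str] = field(default_factory=lambda: ["plasma"])
    cohort_files: dict[str, dict[str, str]] = field(default_factory=dict)
    qc: QCThresholds = field(default_factory=QCThresholds)
    k_pcs: int = 5
    candidate_p: float = 5e-5
    refine_p: float = 0.2
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    meta_method: str = "random"       # "fixed" available for comparison
    comparator_weights: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.discovery:
            raise PipelineError("config", "at least one discovery cohort is required")
        overlap = set(self.discovery) & ({self.refinement} | set(self.validation))
        if overlap:
            raise PipelineError(
                "config", f"cohort roles must be disjoint; {sorted(overlap)} "
                "appear both in discovery and elsewhere")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    funnel: dict[str, int] = field(default_factory=dict)
    lambdas: dict[str, float] = field(default_factory=dict)
    qc_reports: dict[str, dict] = field(default_factory=dict)
    association_reports: dict[str, dict] = field(default_factory=dict)
    comparator: dict | None = None
    config: dict = field(default_factory=dict)
    version: str = __version__
    seed: int = 0
    completed_phases: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class PipelineResults:
    """Results of a fitted :class:`GRSPipeline`.

    Attributes
    ----------
    grs : GRSModel or None
        The fitted score (None only if the run aborted before phase 3).
    report : RunReport
        Funnel counts, inflation factors, QC and association summaries.
    meta, candidates, decisions, clumped : DataFrame
        The per-phase intermediate tables.
    scores : dict cohort -> DataFrame
        Per-sample scores for every cohort the model was applied to.
    """

    def __init__(self, model: "GRSPipeline", grs: GRSModel | None,
                 report: RunReport, meta: pd.DataFrame,
                 candidates: pd.DataFrame, decisions: pd.DataFrame,
                 clumped: pd.DataFrame, scores: dict[str, pd.DataFrame],
                 association_reports: dict[str, AssociationReport],
                 comparison: ScoreComparison | None,
                 summary_stats: dict[str, pd.DataFrame]):
        self.model = model
        self.grs = grs
        self.report = report
        self.meta = meta
        self.candidates = candidates
        self.decisions = decisions
        self.clumped = clumped
        self.scores = scores
        self.association_reports = association_reports
        self.comparison = comparison
        self.summary_stats = summary_stats

    def summary(self) -> str:
        rep = self.report
        lines = ["Non-APOE amyloid GRS pipeline", "=" * 34]
        lines.append("Funnel:")
        for stage, count in rep.funnel.items():
            lines.append(f"  {stage:<28s} {count}")
        lines.append("Genomic inflation:")
        for cohort, lam in rep.lambdas.items():
            lines.append(f"  lambda[{cohort}] = {lam:.3f}")
        if self.grs is not None:
            lines.append(f"Final model: {len(self.grs)} variants")
        lines.append("Associations:")
        for name, report in self.association_reports.items():
            lines.append(f"  {name}: {report}")
        if self.comparison is not None and self.comparison.delta_incremental_r2 is not None:
            lines.append(f"Comparator dR2 difference: "
                         f"{self.comparison.delta_incremental_r2:+.4f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write every intermediate artifact as delimited text + the report."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cohort, df in self.summary_stats.items():
            df.to_csv(out / f"gwas_{cohort}.tsv", sep="\t", index=False)
        self.meta.to_csv(out / "meta.tsv", sep="\t", index=False)
        self.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        self.decisions.to_csv(out / "refinement_decisions.tsv", sep="\t", index=False)
        self.clumped.to_csv(out / "clumped.tsv", sep="\t", index=False)
        if self.grs is not None:
            self.grs.to_file(out / "grs_weights.tsv")
        for cohort, df in self.scores.items():
            df.to_csv(out / f"scores_{cohort}.tsv", sep="\t", index=False)
        self.report.to_json(out / "report.json")
        (out / "report.txt").write_text(self.summary() + "\n")


class GRSPipeline:
    """Four-phase clumping-and-thresholding score study on in-memory cohorts.

    Parameters
    ----------
    cohorts : mapping cohort name -> CohortDataset
        Must cover every cohort named in ``config``; discovery sample ids
        must be disjoint from refinement and validation sample ids.
    config : PipelineConfig
    """

    def __init__(self, cohorts: dict[str, CohortDataset], config: PipelineConfig):
        config.validate()
        self.config = config
        self.cohorts = cohorts
        missing = [c for c in config.discovery + [config.refinement] + config.validation
                   if c not in cohorts]
        if missing:
            raise PipelineError("config", f"cohorts not provided: {missing}")
        disc_ids = set()
        for c in config.discovery:
            disc_ids |= set(cohorts[c].sample_ids)
        for c in [config.refinement] + list(config.validation):
            shared = disc_ids & set(cohorts[c].sample_ids)
            if shared:
                raise PipelineError(
                    "config", f"cohort {c!r} shares {len(shared)} sample ids with "
                    "discovery; refusing to run (data leakage)")

    # -- phases ------------------------------------------------------------

    def fit(self) -> PipelineResults:
        cfg = self.config
        logger.info(
            "pipeline thresholds: candidate_p=%g refine_p=%g clump_r2=%g "
            "clump_window_kb=%g k_pcs=%d meta=%s qc=%s",
            cfg.candidate_p, cfg.refine_p, cfg.clump_r2, cfg.clump_window_kb,
            cfg.k_pcs, cfg.meta_method, cfg.qc)
        report = RunReport(config=cfg.to_dict(), seed=cfg.seed)
        qc_cohorts: dict[str, CohortDataset] = {}
        pcs = {}

        # Phase 0: QC + PCs per cohort.
        phase = "qc"
        try:
            for name in cfg.discovery + [cfg.refinement] + list(cfg.validation):
                data = self.cohorts[name]
                data, vrep = apply_variant_qc(data, cfg.qc)
                data, srep = apply_sample_qc(data, cfg.qc)
                qc_cohorts[name] = data
                report.qc_reports[name] = {
                    "variant": {"n_in": vrep.n_in, "n_out": vrep.n_out,
                                "counts": vrep.counts},
                    "sample": {"n_in": srep.n_in, "n_out": srep.n_out,
                               "counts": srep.counts},
                }
                pcs[name] = compute_pcs(data, k=cfg.k_pcs)
            report.funnel["variants_after_qc"] = min(
                qc_cohorts[c].n_variants for c in cfg.discovery)
            report.completed_phases.append(phase)
        except DataError as exc:
            raise PipelineError(phase, str(exc), partial_report=report) from exc

        # Phase 1: discovery GWAS + meta-analysis + candidate selection.
        phase = "discovery_gwas"
        summary_stats: dict[str, pd.DataFrame] = {}
        try:
            for name in cfg.discovery:
                data = qc_cohorts[name]
                cov = default_covariates(data, pcs=pcs[name], k_pcs=cfg.k_pcs)
                stats_df = gwas_linear(data, cov)
                summary_stats[name] = stats_df
                report.lambdas[name] = genomic_lambda(stats_df)
            harmonized = [summary_stats[cfg.discovery[0]]]
            for name in cfg.discovery[1:]:
                aligned, _ = harmonize_alleles(harmonized[0], summary_stats[name])
                harmonized.append(aligned)
            meta = meta_analyze(harmonized, method=cfg.meta_method)
            candidates = select_candidates(meta, cfg.candidate_p)
            report.funnel["candidates"] = len(candidates)
            report.completed_phases.append(phase)
        except DataError as exc:
            raise PipelineError(phase, str(exc), partial_report=report) from exc

        # Phase 2: refinement in the independent neuropathology cohort.
        phase = "refinement"
        try:
            ref_data = qc_cohorts[cfg.refinement]
            shared = candidates["variant_id"][
                candidates["variant_id"].isin(ref_data.variant_ids)]
            decisions = pd.DataFrame()
            retained = candidates.iloc[0:0]
            if len(candidates):
                sub = ref_data.subset_variants(list(shared))
                cov = default_covariates(ref_data, pcs=pcs[cfg.refinement],
                                         k_pcs=cfg.k_pcs)
                rep_stats = gwas_linear(sub, cov) if sub.n_variants else \
                    summary_stats[cfg.discovery[0]].iloc[0:0]
                rep_stats, _ = harmonize_alleles(candidates, rep_stats)
                summary_stats[cfg.refinement] = rep_stats
                decisions = refine_candidates(candidates, rep_stats, cfg.refine_p)
                retained = retained_candidates(candidates, decisions)
            report.funnel["available_in_refinement"] = int(len(shared))
            report.funnel["post_refinement"] = len(retained)
            report.completed_phases.append(phase)
        except DataError as exc:
            raise PipelineError(phase, str(exc), partial_report=report) from exc

        # Phase 3: clump + threshold + weights -> score model.
        phase = "clump_build"
        grs = None
        clumped = retained.iloc[0:0]
        try:
            if len(retained):
                panel = _pooled_panel([qc_cohorts[c] for c in cfg.discovery],
                                      list(retained["variant_id"]))
                clumped = clump(retained, panel, r2_max=cfg.clump_r2,
                                window_kb=cfg.clump_window_kb)
                grs = build_grs(clumped, p_threshold=cfg.candidate_p,
                                clump_r2=cfg.clump_r2,
                                clump_window_kb=cfg.clump_window_kb)
            report.funnel["post_clump"] = len(clumped)
            report.funnel["final_model"] = 0 if grs is None else len(grs)
            report.completed_phases.append(phase)
        except DataError as exc:
            raise PipelineError(phase, str(exc), partial_report=report) from exc

        # Phase 4: score + evaluate everywhere.
        phase = "validation"
        scores: dict[str, pd.DataFrame] = {}
        assoc_reports: dict[str, AssociationReport] = {}
        comparison = None
        try:
            if grs is not None:
                for name in cfg.discovery:
                    data = qc_cohorts[name]
                    cov = default_covariates(data, pcs=pcs[name], k_pcs=cfg.k_pcs)
                    scores[name] = score_samples(grs, data)
                    assoc_reports[f"{name}:phenotype"] = evaluate_grs(
                        scores[name], data, cov)
                ref_data = qc_cohorts[cfg.refinement]
                cov = default_covariates(ref_data, pcs=pcs[cfg.refinement],
                                         k_pcs=cfg.k_pcs)
                scores[cfg.refinement] = score_samples(grs, ref_data)
                assoc_reports[f"{cfg.refinement}:phenotype"] = evaluate_grs(
                    scores[cfg.refinement], ref_data, cov)
                for extra, is_binary in (("tangle_density", False), ("braak_high", True)):
                    if extra in ref_data.samples.columns:
                        assoc_reports[f"{cfg.refinement}:{extra}"] = evaluate_grs(
                            scores[cfg.refinement], ref_data, cov,
                            outcome=extra, binary=is_binary)
                for name in cfg.validation:
                    data = qc_cohorts[name]
                    cov = default_covariates(data, pcs=pcs[name], k_pcs=cfg.k_pcs)
                    scores[name] = score_samples(grs, data)
                    assoc_reports[f"{name}:phenotype"] = evaluate_grs(
                        scores[name], data, cov)
                if cfg.comparator_weights:
                    comp_model = GRSModel.from_file(cfg.comparator_weights)
                    target = cfg.discovery[0]
                    data = qc_cohorts[target]
                    cov = default_covariates(data, pcs=pcs[target], k_pcs=cfg.k_pcs)
                    comparison = compare_scores(grs, comp_model, data, cov)
                    report.comparator = {
                        "cohort": target,
                        "grs": comparison.report_a.to_dict(),
                        "comparator": comparison.report_b.to_dict(),
                        "delta_incremental_r2": comparison.delta_incremental_r2,
                    }
            report.association_reports = {k: v.to_dict()
                                          for k, v in assoc_reports.items()}
            report.completed_phases.append(phase)
        except DataError as exc:
            raise PipelineError(phase, str(exc), partial_report=report) from exc

        return PipelineResults(
            model=self, grs=grs, report=report, meta=meta,
            candidates=candidates, decisions=decisions, clumped=clumped,
            scores=scores, association_reports=assoc_reports,
            comparison=comparison, summary_stats=summary_stats)


def _pooled_panel(cohorts: list[CohortDataset], variant_ids: list[str]) -> CohortDataset:
    """Pool discovery genotypes (shared variants only) as the LD panel."""
    subs = [c.subset_variants(variant_ids) for c in cohorts]
    base = subs[0]
    keep = base.variant_ids
    for s in subs[1:]:
        keep = keep.intersection(s.variant_ids)
    subs = [s.subset_variants(list(keep)) for s in subs]
    dosages = np.vstack([
        s.dosages[:, [s.variant_ids.get_loc(v) for v in keep]] for s in subs])
    samples = pd.concat([s.samples for s in subs], ignore_index=True)
    return CohortDataset(
        cohort_name="pooled_discovery",
        dosages=dosages,
        variants=subs[0].variants.set_index("variant_id").loc[keep].reset_index(),
        samples=samples,
        phenotype_type="quantitative",
    )


# ---------------------------------------------------------------------------
# File-based entry points
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResults:
    """Load the configured cohort files, fit the pipeline, save artifacts."""
    cohorts = {}
    for name, paths in config.cohort_files.items():
        cohorts[name] = read_cohort(
            paths["genotypes"], paths["phenotypes"],
            fmt=paths.get("format", "traw"), cohort_name=name)
    results = GRSPipeline(cohorts, config).fit()
    if out_dir is not None:
        results.save(out_dir)
    return results


SCALES = {
    "tiny": dict(m_variants=2_000, n_per_cohort={
        "discovery_a": 200, "discovery_b": 200, "neuropath": 150, "plasma": 150}),
    "full": dict(m_variants=20_000, n_per_cohort={
        "discovery_a": 983, "discovery_b": 513, "neuropath": 710, "plasma": 641}),
}


def make_demo_data(out_dir: str | Path, scale: str = "tiny",
                   seed: int = 0) -> PipelineConfig:
    """Write a four-cohort synthetic dataset plus a matching pipeline config.

    ``tiny`` (n=200/cohort-ish, m=2,000) runs the full pipeline in well
    under a minute; ``full`` mirrors the cohort sizes of the study
    design the generator emulates (983/513 discovery, 710 refinement,
    641 validation; m=20,000).
    """
    if scale not in SCALES:
        raise PipelineError("demo", f"unknown scale {scale!r}; use {sorted(SCALES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(seed=seed, **SCALES[scale])
    cohorts = simulate_study(sim)
    files = {}
    for name, data in cohorts.items():
        gpath = out / f"{name}.traw"
        ppath = out / f"{name}.pheno.tsv"
        write_cohort(data, gpath, ppath, fmt="traw")
        files[name] = {"genotypes": str(gpath), "phenotypes": str(ppath),
                       "format": "traw"}
    config = PipelineConfig(cohort_files=files, seed=seed)
    config.to_yaml(out / "pipeline.yaml")
    return config
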