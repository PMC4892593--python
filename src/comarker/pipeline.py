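"""End-to-end orchestration: harmonize → marginal → joint → consensus.

One call runs the whole screen on a list of probe-level cohorts:

1. collapse probes to genes, resolve scale, intersect panels;
2. per cohort: fold change, t-test, BH; three marginal selections;
3. per cohort: cross-validated lasso selection;
4. vote counting, m-of-n filtering per method, pool union and
   intersection, marker report.

A single top-level seed is forked deterministically per (stage,
cohort); only the lasso fold assignment consumes randomness, so
identical inputs + config + seed give byte-identical outputs.  When an
output directory is given, every intermediate the analysis tabulates
(per-cohort statistics, per-method selections, the consensus, the
report) is written there together with a manifest recording the
configuration, the seed, and a checksum per input matrix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize
from .consensus import (
    ConsensusResult,
    combine,
    count_votes,
    m_of_n_filter,
    marker_report,
    format_report,
)
from .io_formats import ExpressionDataset, ProbeMap, write_json
from .joint_selection import LassoConfig, lasso_fit
from .marginal_selection import (
    FDR_ALPHA_DEFAULT,
    MARGINAL_METHODS,
    METHOD_LASSO,
    TOP_K_DEFAULT,
    MarginalStats,
    SelectionSet,
    compute_marginal_stats,
    select_fdr,
    select_top_k,
    write_marginal_stats,
)

logger = logging.getLogger("comarker")


@dataclass
class AnalysisConfig:
    """Everything the consensus screen can be tuned by."""

    top_k: int = TOP_K_DEFAULT
    fdr_alpha: float = FDR_ALPHA_DEFAULT
    m_required: int = 3
    fc_rank_mode: str = "magnitude"  # or "ratio"
    t_variant: str = "welch"  # or "student"
    collapse_rule: str = "max_mean_probe"
    joint_consensus: str = "pooled"  # or "m_of_n" (same vote as marginal arm)
    lasso: LassoConfig = field(default_factory=lambda: LassoConfig(lambda_rule="one_se"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (0 < self.fdr_alpha <= 1):
            raise ValueError("fdr_alpha must be in (0, 1]")
        if self.m_required < 1:
            raise ValueError("m_required must be >= 1")
        if self.joint_consensus not in ("m_of_n", "pooled"):
            raise ValueError(f"unknown joint_consensus {self.joint_consensus!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Consensus plus every intermediate a run produces."""

    consensus: ConsensusResult
    common_genes: list[str]
    stats_by_dataset: dict[str, MarginalStats]
    selections: list
    report: pd.DataFrame
    fc_ranges: dict[str, tuple[float, float]]


def _stage_seed(seed: int, stage: str, index: int) -> int:
    """Deterministic per-(stage, cohort) seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(ds: ExpressionDataset) -> str:
    h = hashlib.sha256()
    h.update("\t".join(ds.probe_ids).encode())
    h.update("\t".join(ds.sample_ids).encode())
    h.update(np.ascontiguousarray(ds.values).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    datasets: list[ExpressionDataset],
    probe_maps: list[ProbeMap],
    cfg: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full cross-cohort consensus screen.

    ``probe_maps`` are matched to datasets by platform id (a map with
    an empty platform id applies to datasets with an empty platform
    id).  Configuration errors (e.g. ``m_required`` exceeding the
    cohort count) are raised before any computation starts.
    """
    cfg = cfg or AnalysisConfig()
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    if cfg.m_required > len(datasets):
        raise ValueError(
            f"m_required={cfg.m_required} exceeds the number of datasets "
            f"({len(datasets)})"
        )
    maps_by_platform = {pm.platform_id: pm for pm in probe_maps}

    # --- harmonize ---------------------------------------------------------
    matrices = []
    for ds in datasets:
        pm = maps_by_platform.get(ds.platform_id)
        if pm is None:
            raise ValueError(f"no probe map for platform {ds.platform_id!r}")
        try:
            gm = harmonize.collapse_probes(ds, pm, rule=cfg.collapse_rule)
            gm = harmonize.ensure_log_scale(gm)
        except ValueError as exc:
            raise ValueError(f"[harmonize:{ds.dataset_id}] {exc}") from exc
        logger.info(
            "harmonize %s: %d probes -> %d genes (log transform: %s)",
            ds.dataset_id, len(ds.probe_ids), gm.n_genes, gm.log_transform_applied,
        )
        matrices.append(gm)
    matrices, common_genes = harmonize.intersect_genes(matrices)
    logger.info("commonly profiled genes across %d cohorts: %d",
                len(matrices), len(common_genes))

    # --- marginal selection ------------------------------------------------
    stats_by_dataset: dict[str, MarginalStats] = {}
    selections = []
    for gm in matrices:
        try:
            stats = compute_marginal_stats(gm, t_variant=cfg.t_variant)
        except ValueError as exc:
            raise ValueError(f"[marginal:{gm.dataset_id}] {exc}") from exc
        stats_by_dataset[gm.dataset_id] = stats
        sel_fc = select_top_k(stats, "fc", k=cfg.top_k, fc_mode=cfg.fc_rank_mode)
        sel_t = select_top_k(stats, "t_p", k=cfg.top_k)
        sel_q = select_fdr(stats, alpha=cfg.fdr_alpha)
        selections += [sel_fc, sel_t, sel_q]
        logger.info(
            "marginal %s: |fc_top_k|=%d |t_top_k|=%d |fdr<=%g|=%d",
            gm.dataset_id, len(sel_fc.genes), len(sel_t.genes),
            cfg.fdr_alpha, len(sel_q.genes),
        )

    # --- joint selection ---------------------------------------------------
    for i, gm in enumerate(matrices):
        lcfg = LassoConfig(**{**asdict(cfg.lasso),
                              "seed": _stage_seed(cfg.seed, "lasso", i)})
        try:
            fit = lasso_fit(gm, lcfg)
        except ValueError as exc:
            raise ValueError(f"[joint:{gm.dataset_id}] {exc}") from exc
        sel = SelectionSet(
            dataset_id=gm.dataset_id,
            method=METHOD_LASSO,
            parameters={
                "lambda": fit.chosen_lambda,
                "lambda_rule": lcfg.lambda_rule,
                "n_folds": fit.n_folds_used,
                "seed": lcfg.seed,
                "coefficients": fit.coefficients(),
            },
            genes=fit.selected_genes,
        )
        selections.append(sel)
        logger.info(
            "joint %s: lambda=%.4g -> %d genes",
            gm.dataset_id, sel.parameters["lambda"], len(sel.genes),
        )

    # --- consensus ---------------------------------------------------------
    votes = count_votes(selections)
    marginal_sets = {
        m: m_of_n_filter(votes, m, cfg.m_required) for m in MARGINAL_METHODS
    }
    joint_m = 1 if cfg.joint_consensus == "pooled" else cfg.m_required
    joint_pool = m_of_n_filter(votes, METHOD_LASSO, joint_m)
    result = combine(marginal_sets, joint_pool, votes=votes)
    logger.info("consensus: %s", result.summary_counts())

    report, fc_ranges = marker_report(
        result.common_markers, stats_by_dataset, selections=selections
    )
    result.per_gene_stats = report
    result.fc_ranges = fc_ranges

    if out_dir is not None:
        _write_run(Path(out_dir), datasets, cfg, stats_by_dataset,
                   selections, result, report)
    return PipelineResult(
        consensus=result,
        common_genes=common_genes,
        stats_by_dataset=stats_by_dataset,
        selections=selections,
        report=report,
        fc_ranges=fc_ranges,
    )


def _write_run(out, datasets, cfg, stats_by_dataset, selections, result, report):
    out.mkdir(parents=True, exist_ok=True)
    for ds_id, stats in stats_by_dataset.items():
        write_marginal_stats(stats, out / f"stats_{ds_id}.tsv")
    sel_records = [
        {
            "dataset_id": s.dataset_id,
            "method": s.method,
            "parameters": s.parameters,
            "genes": sorted(s.genes),
        }
        for s in selections
    ]
    write_json(sel_records, out / "selections.json")
    write_json(result.to_jsonable(), out / "consensus.json")
    report.to_csv(out / "marker_report_full.tsv", sep="\t", index=False)
    format_report(report).to_csv(out / "marker_report.tsv", sep="\t", index=False)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "inputs": {ds.dataset_id: _checksum(ds) for ds in datasets},
        "counts": result.summary_counts(),
    }
    write_json(manifest, out / "manifest.json")
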