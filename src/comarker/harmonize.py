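"""Probe-to-gene collapse and restriction to commonly profiled genes.

Cohorts arrive on different platforms with different probe sets, so a
cross-cohort analysis needs two harmonization steps: map probes to
official gene symbols and collapse multi-probe genes to one row, then
cut every cohort down to the genes profiled on all platforms.  The
collapse happens first and the intersection is taken on symbols — the
only order under which "commonly profiled" is well defined across
platforms.

The probe-collapse rule is configurable because no single convention
dominates: ``max_mean_probe`` (default) keeps the probe with the
highest mean intensity across all samples, the common microarray
heuristic for picking the best-hybridizing probe; ``mean_of_probes``
averages the probe rows.  Ties on mean intensity break by probe id,
lexicographically, so the collapse is deterministic and invariant to
input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionDataset, ProbeMap

COLLAPSE_RULES = ("max_mean_probe", "mean_of_probes")

#: above this max value a matrix is assumed to be on the linear
#: intensity scale; log2 microarray data rarely exceeds ~16 while
#: linear intensities run into the thousands
LOG_SCALE_THRESHOLD = 50.0


@dataclass
class GeneMatrix:
    """Gene x sample matrix for one cohort, guaranteed log2 scale."""

    dataset_id: str
    sample_type: str
    gene_symbols: list[str]
    sample_ids: list[str]
    labels: list[str]
    values: np.ndarray
    log2: bool = True
    log_transform_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with gene/sample lists")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbol")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([lab == "case" for lab in self.labels])

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def restrict_to(self, genes: list[str]) -> "GeneMatrix":
        """New matrix with rows for ``genes``, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_symbols)}
        rows = [index[g] for g in genes]
        return GeneMatrix(
            dataset_id=self.dataset_id,
            sample_type=self.sample_type,
            gene_symbols=list(genes),
            sample_ids=self.sample_ids,
            labels=self.labels,
            values=self.values[rows],
            log2=self.log2,
            log_transform_applied=self.log_transform_applied,
        )


def collapse_probes(
    ds: ExpressionDataset, pmap: ProbeMap, rule: str = "max_mean_probe"
) -> GeneMatrix:
    """Collapse probe rows to one row per annotated gene.

    Unannotated probes are dropped.  Output gene order is
    lexicographic, making the result canonical regardless of input
    probe order.
    """
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {rule!r}; use one of {COLLAPSE_RULES}")
    if pmap.platform_id and ds.platform_id and pmap.platform_id != ds.platform_id:
        raise ValueError(
            f"probe map platform {pmap.platform_id!r} does not match "
            f"dataset platform {ds.platform_id!r}"
        )
    by_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(ds.probe_ids):
        sym = pmap.entries.get(probe)
        if sym is not None:
            by_gene.setdefault(sym, []).append(i)
    if not by_gene:
        raise ValueError(
            f"{ds.dataset_id}: no probe in the dataset is annotated by the map"
        )
    genes = sorted(by_gene)
    out = np.empty((len(genes), len(ds.sample_ids)))
    for gi, gene in enumerate(genes):
        rows = by_gene[gene]
        if len(rows) == 1:
            out[gi] = ds.values[rows[0]]
        elif rule == "mean_of_probes":
            out[gi] = ds.values[rows].mean(axis=0)
        else:  # max_mean_probe; tie -> lexicographically smallest probe id
            means = ds.values[rows].mean(axis=1)
            best = min(
                range(len(rows)),
                key=lambda r: (-means[r], ds.probe_ids[rows[r]]),
            )
            out[gi] = ds.values[rows[best]]
    return GeneMatrix(
        dataset_id=ds.dataset_id,
        sample_type=ds.sample_type,
        gene_symbols=genes,
        sample_ids=list(ds.sample_ids),
        labels=list(ds.labels),
        values=out,
        log2=False,  # scale unknown until ensure_log_scale runs
    )


def ensure_log_scale(gm: GeneMatrix) -> GeneMatrix:
    """Heuristically bring a matrix onto the log2 scale.

    Deposited matrices do not declare their scale.  If the maximum
    value exceeds ``LOG_SCALE_THRESHOLD`` the matrix is treated as
    linear intensities and replaced by ``log2(value + 1)``; otherwise
    it passes through unchanged.  Negative values alongside a large
    maximum are contradictory (neither scale fits) and raise.
    """
    vmax = float(gm.values.max()) if gm.values.size else 0.0
    if vmax <= LOG_SCALE_THRESHOLD:
        return GeneMatrix(
            dataset_id=gm.dataset_id,
            sample_type=gm.sample_type,
            gene_symbols=gm.gene_symbols,
            sample_ids=gm.sample_ids,
            labels=gm.labels,
            values=gm.values,
            log2=True,
            log_transform_applied=False,
        )
    if float(gm.values.min()) < 0:
        raise ValueError(
            f"{gm.dataset_id}: ambiguous scale — negative values together "
            f"with max {vmax:.3g} > {LOG_SCALE_THRESHOLD}"
        )
    return GeneMatrix(
        dataset_id=gm.dataset_id,
        sample_type=gm.sample_type,
        gene_symbols=gm.gene_symbols,
        sample_ids=gm.sample_ids,
        labels=gm.labels,
        values=np.log2(gm.values + 1.0),
        log2=True,
        log_transform_applied=True,
    )


def intersect_genes(
    matrices: list[GeneMatrix],
) -> tuple[list[GeneMatrix], list[str]]:
    """Restrict every cohort to the genes profiled in all of them.

    Rows come out in identical lexicographic order across cohorts, so
    downstream per-gene statistics align positionally.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to intersect")
    common: set[str] = set(matrices[0].gene_symbols)
    for gm in matrices[1:]:
        common &= set(gm.gene_symbols)
    if not common:
        raise ValueError("gene panels have an empty intersection")
    ordered = sorted(common)
    return [gm.restrict_to(ordered) for gm in matrices], ordered
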