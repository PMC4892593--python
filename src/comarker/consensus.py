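"""Cross-cohort vote counting, set algebra, and the marker report.

A gene earns one vote per (method, cohort) pair that selected it.  The
m-of-n rule (default: at least 3 of the 4 cohorts) turns each method's
votes into a cross-cohort consensus set.  The three marginal methods'
consensus sets are then pooled by union; the lasso consensus set forms
the joint pool; and the genes appearing in **both** pools are the
common markers — genes whose association is robust across cohorts,
sample types, and analytical strategies.

The report mirrors the usual presentation of such screens: one row per
marker per cohort with fold change, t-test p, BH q, and which methods
selected it there, plus min-max fold-change ranges per sample type
(the summary that exposes the monocyte > PBMC > whole-blood signal
dilution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marginal_selection import (
    MARGINAL_METHODS,
    METHOD_FC,
    METHOD_FDR,
    METHOD_LASSO,
    METHOD_T,
    MarginalStats,
    SelectionSet,
)


@dataclass
class VoteTable:
    """Per-gene, per-method counts of cohorts that selected the gene."""

    #: gene -> method -> number of distinct cohorts selecting it
    votes: dict[str, dict[str, int]]
    #: method -> number of cohorts contributing selections
    n_datasets: dict[str, int]

    def count(self, gene: str, method: str) -> int:
        return self.votes.get(gene, {}).get(method, 0)


@dataclass
class ConsensusResult:
    """Everything the cross-cohort consensus produces."""

    votes: VoteTable
    marginal_sets: dict[str, frozenset[str]]
    marginal_pool: frozenset[str]
    joint_pool: frozenset[str]
    common_markers: frozenset[str]
    per_gene_stats: pd.DataFrame | None = None
    fc_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return len(self.marginal_pool | self.joint_pool)

    def summary_counts(self) -> dict[str, int]:
        """The selection accounting every run logs."""
        out = {f"marginal_{m}": len(s) for m, s in self.marginal_sets.items()}
        out["marginal_pool"] = len(self.marginal_pool)
        out["joint_pool"] = len(self.joint_pool)
        out["union"] = self.union_size
        out["common_markers"] = len(self.common_markers)
        return out

    def to_jsonable(self) -> dict:
        return {
            "marginal_sets": {m: sorted(s) for m, s in self.marginal_sets.items()},
            "marginal_pool": sorted(self.marginal_pool),
            "joint_pool": sorted(self.joint_pool),
            "common_markers": sorted(self.common_markers),
            "counts": self.summary_counts(),
            "fc_ranges": {st: list(r) for st, r in self.fc_ranges.items()},
            "votes": {
                g: dict(ms) for g, ms in sorted(self.votes.votes.items())
            },
        }


def count_votes(selections: list[SelectionSet]) -> VoteTable:
    """Count, per gene and method, the distinct cohorts selecting it.

    Two selections with the same (method, dataset) pair indicate a
    pipeline wiring bug and raise.
    """
    seen: set[tuple[str, str]] = set()
    votes: dict[str, dict[str, int]] = {}
    datasets_by_method: dict[str, set[str]] = {}
    for sel in selections:
        key = (sel.method, sel.dataset_id)
        if key in seen:
            raise ValueError(
                f"duplicate selection for method={sel.method!r} "
                f"dataset={sel.dataset_id!r}"
            )
        seen.add(key)
        datasets_by_method.setdefault(sel.method, set()).add(sel.dataset_id)
        for gene in sel.genes:
            votes.setdefault(gene, {})
            votes[gene][sel.method] = votes[gene].get(sel.method, 0) + 1
    return VoteTable(
        votes=votes,
        n_datasets={m: len(d) for m, d in datasets_by_method.items()},
    )


def m_of_n_filter(votes: VoteTable, method: str, m: int = 3) -> frozenset[str]:
    """Genes selected by ``method`` in at least ``m`` cohorts."""
    if m < 1:
        raise ValueError("m must be >= 1")
    n = votes.n_datasets.get(method, 0)
    if m > n:
        raise ValueError(
            f"m={m} exceeds the {n} dataset(s) with {method!r} selections"
        )
    return frozenset(
        g for g, ms in votes.votes.items() if ms.get(method, 0) >= m
    )


def combine(
    marginal_sets: dict[str, frozenset[str]],
    joint_pool: frozenset[str],
    votes: VoteTable | None = None,
) -> ConsensusResult:
    """Pool the marginal consensus sets and intersect with the joint pool.

    The marginal pool is the union over the marginal methods' post-
    filter sets; the common markers are its intersection with the
    joint pool.  The inclusion-exclusion identity
    ``|A ∪ B| = |A| + |B| - |A ∩ B|`` is asserted on every call as a
    cheap self-check of the set algebra.
    """
    marginal_pool = frozenset().union(*marginal_sets.values()) if marginal_sets else frozenset()
    joint_pool = frozenset(joint_pool)
    common = marginal_pool & joint_pool
    union = marginal_pool | joint_pool
    assert len(union) == len(marginal_pool) + len(joint_pool) - len(common)
    return ConsensusResult(
        votes=votes if votes is not None else VoteTable({}, {}),
        marginal_sets={m: frozenset(s) for m, s in marginal_sets.items()},
        marginal_pool=marginal_pool,
        joint_pool=joint_pool,
        common_markers=common,
    )


def marker_report(
    common_markers,
    stats_by_dataset: dict[str, MarginalStats],
    selections: list[SelectionSet] | None = None,
    range_genes=None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-marker, per-cohort statistics table plus FC ranges by sample type.

    ``range_genes`` restricts the min-max fold-change summary to a gene
    subset (e.g. the consistently up-regulated interferon genes);
    default is all markers.  Every marker must be present in every
    cohort's statistics — a missing one means harmonization went wrong
    upstream, so it raises rather than emitting a partial row.
    """
    markers = sorted(common_markers)
    selected_by: dict[tuple[str, str], set[str]] = {}
    for sel in selections or []:
        for gene in sel.genes:
            selected_by.setdefault((gene, sel.dataset_id), set()).add(sel.method)
    rows = []
    for gene in markers:
        for ds_id, stats in stats_by_dataset.items():
            if gene not in stats.table.index:
                raise ValueError(
                    f"marker {gene!r} missing from statistics of dataset {ds_id!r}"
                )
            rec = stats.table.loc[gene]
            methods = selected_by.get((gene, ds_id), set())
            rows.append(
                {
                    "gene": gene,
                    "dataset_id": ds_id,
                    "sample_type": stats.sample_type,
                    "fc": float(rec["fc_ratio"]),
                    "p": float(rec["p_value"]),
                    "q": float(rec["q_value"]),
                    "by_fc": METHOD_FC in methods,
                    "by_t": METHOD_T in methods,
                    "by_fdr": METHOD_FDR in methods,
                    "by_lasso": METHOD_LASSO in methods,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "dataset_id", "sample_type", "fc", "p", "q",
            "by_fc", "by_t", "by_fdr", "by_lasso",
        ],
    )
    subset = set(range_genes) if range_genes is not None else set(markers)
    ranges: dict[str, tuple[float, float]] = {}
    if len(table):
        in_subset = table[table["gene"].isin(subset)]
        for st, grp in in_subset.groupby("sample_type"):
            ranges[st] = (float(grp["fc"].min()), float(grp["fc"].max()))
    return table, ranges


def format_report(table: pd.DataFrame) -> pd.DataFrame:
    """Display formatting: FC to 2 decimals, p/q to 2 significant figures.

    Full precision stays in the unformatted table; this variant is for
    the human-readable TSV.
    """
    out = table.copy()
    out["fc"] = out["fc"].map(lambda v: f"{v:.2f}")
    out["p"] = out["p"].map(lambda v: f"{v:.1E}")
    out["q"] = out["q"].map(lambda v: f"{v:.1E}")
    return out
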