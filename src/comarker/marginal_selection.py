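"""Per-dataset marginal statistics and the three marginal selection rules.

Marginal analysis treats each gene separately within one cohort: the
linear-scale fold change between case and control group means, a
two-sample t-test on log2 values, and Benjamini-Hochberg adjustment of
the t-test p-values across genes.  Three selection rules turn those
statistics into per-cohort gene sets:

* top-k by fold change (k = 100 by default),
* top-k by t-test p-value,
* all genes with BH-adjusted q at or below a fixed level (0.001).

The t-test defaults to Welch's unequal-variance form because cohort
class sizes here are grossly unbalanced (e.g. 157 cases vs 20
controls); the pooled-variance Student form is available via
``variant="student"``.

Fold-change ranking defaults to magnitude ``max(r, 1/r)`` so down- and
up-regulation compete on equal footing; ``mode="ratio"`` ranks the raw
case/control ratio descending, i.e. up-regulated genes only, which is
the convention some published marker screens use.

All rankings break ties by gene symbol (ascending), making every
selection a deterministic function of the statistics alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TOP_K_DEFAULT = 100
FDR_ALPHA_DEFAULT = 0.001

METHOD_FC = "fc_top_k"
METHOD_T = "t_top_k"
METHOD_FDR = "fdr_threshold"
METHOD_LASSO = "lasso"
MARGINAL_METHODS = (METHOD_FC, METHOD_T, METHOD_FDR)


@dataclass
class MarginalStats:
    """Per-gene marginal statistics for one cohort.

    ``table`` is indexed by gene symbol with columns ``fc_ratio``,
    ``fc_magnitude``, ``direction``, ``t_stat``, ``p_value``,
    ``q_value``.
    """

    dataset_id: str
    sample_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"fc_ratio", "fc_magnitude", "direction", "t_stat", "p_value", "q_value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"stats table missing columns {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SelectionSet:
    """The genes one method selected from one cohort."""

    dataset_id: str
    method: str
    parameters: dict = field(default_factory=dict)
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def fold_change(gm) -> pd.DataFrame:
    """Linear-scale fold change per gene from a log2 matrix.

    ``fc_ratio = 2 ** (mean_case - mean_control)``;
    ``fc_magnitude = max(ratio, 1/ratio)``; direction is ``up`` iff the
    ratio is at least 1.  Because means are taken on the log2 scale,
    the ratio is the ratio of geometric means of intensities.
    """
    if not gm.log2:
        raise ValueError(f"{gm.dataset_id}: matrix not on log2 scale")
    case = gm.case_mask
    if case.sum() == 0 or (~case).sum() == 0:
        raise ValueError(f"{gm.dataset_id}: a group has zero samples")
    diff = gm.values[:, case].mean(axis=1) - gm.values[:, ~case].mean(axis=1)
    ratio = np.exp2(diff)
    frame = pd.DataFrame(
        {
            "fc_ratio": ratio,
            "fc_magnitude": np.maximum(ratio, 1.0 / ratio),
            "direction": np.where(ratio >= 1.0, "up", "down"),
        },
        index=pd.Index(gm.gene_symbols, name="gene"),
    )
    return frame


def t_test(gm, variant: str = "welch") -> pd.DataFrame:
    """Two-sample t-test per gene on log2 values.

    Welch (default) uses the Welch-Satterthwaite degrees of freedom;
    ``variant="student"`` pools variances.  Genes with zero variance in
    both groups get ``t = 0, p = 1`` when the means agree (no evidence
    either way) and ``p = 0`` with infinite t when they differ
    (separation without noise); this keeps the vectors total instead of
    propagating NaNs.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    case = gm.case_mask
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"{gm.dataset_id}: t-test needs >=2 samples per group (got {n1}/{n0})"
        )
    a, b = gm.values[:, case], gm.values[:, ~case]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant-within-group genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        same = degenerate & (a.mean(axis=1) == b.mean(axis=1))
        sep = degenerate & ~same
        t[same], p[same] = 0.0, 1.0
        t[sep] = np.sign(a.mean(axis=1)[sep] - b.mean(axis=1)[sep]) * np.inf
        p[sep] = 0.0
    return pd.DataFrame(
        {"t_stat": t, "p_value": p},
        index=pd.Index(gm.gene_symbols, name="gene"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_marginal_stats(gm, t_variant: str = "welch") -> MarginalStats:
    """FC + t-test + BH for one cohort, as a single stats table."""
    frame = fold_change(gm).join(t_test(gm, variant=t_variant))
    frame["q_value"] = bh_adjust(frame["p_value"].to_numpy())
    return MarginalStats(dataset_id=gm.dataset_id, sample_type=gm.sample_type, table=frame)


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------


def select_top_k(
    stats: MarginalStats,
    key: str,
    k: int = TOP_K_DEFAULT,
    fc_mode: str = "magnitude",
) -> SelectionSet:
    """Top-k genes by fold change (``key="fc"``) or t-test p (``key="t_p"``).

    Returns exactly ``min(k, n_genes)`` genes; ties break by gene
    symbol ascending so the selection does not depend on input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = stats.table
    if key == "fc":
        if fc_mode == "magnitude":
            order = sorted(t.index, key=lambda g: (-t.at[g, "fc_magnitude"], g))
        elif fc_mode == "ratio":
            order = sorted(t.index, key=lambda g: (-t.at[g, "fc_ratio"], g))
        else:
            raise ValueError(f"unknown fc_mode {fc_mode!r}")
        method = METHOD_FC
        params = {"k": k, "fc_mode": fc_mode}
    elif key == "t_p":
        order = sorted(t.index, key=lambda g: (t.at[g, "p_value"], g))
        method = METHOD_T
        params = {"k": k}
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    return SelectionSet(
        dataset_id=stats.dataset_id,
        method=method,
        parameters=params,
        genes=frozenset(order[: min(k, len(order))]),
    )


def select_fdr(stats: MarginalStats, alpha: float = FDR_ALPHA_DEFAULT) -> SelectionSet:
    """All genes with BH-adjusted q <= alpha (a level, hence inclusive)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    q = stats.table["q_value"]
    return SelectionSet(
        dataset_id=stats.dataset_id,
        method=METHOD_FDR,
        parameters={"alpha": alpha},
        genes=frozenset(q.index[q <= alpha]),
    )


def write_marginal_stats(stats: MarginalStats, path) -> None:
    """Write the per-gene stats table as TSV (gene, fc, t, p, q)."""
    out = stats.table.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")
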