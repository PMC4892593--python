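"""Local functional annotation: over-representation and PPI cross-set summary.

Both analyses run entirely offline against user-supplied files: a GMT
gene-set collection for enrichment and a TSV edge list for
protein-protein interactions.  No ontology-graph propagation and no
web queries — the results are a deterministic function of the supplied
annotation snapshot.

Enrichment is the one-sided hypergeometric (Fisher) test: drawing the
n study genes from a universe of N, the p-value for a term with K
members in the universe and k members in the study is
P(X >= k), X ~ Hypergeometric(N, K, n).  The universe should be the
set of genes the screen could have selected from (here: the commonly
profiled genes), not the whole genome — using the genome inflates
significance of anything array-biased.  BH adjustment runs across the
tested terms.

The cross-set interaction summary classifies edges relative to a study
set A (the common markers) and a reference set B (e.g. GWAS
susceptibility genes): edges within A, edges from A to B, and the
members of A that are isolated — no edge at all inside the subgraph
induced by A ∪ B.  Genes absent from the interaction graph simply have
degree 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneSetCollection, PPIGraph
from .marginal_selection import bh_adjust


@dataclass
class EnrichmentResult:
    """Per-term over-representation statistics.

    ``table`` columns: term_id, term_name, k (overlap), K (term size in
    universe), n (study size), N (universe size), overlap_genes,
    p_value, q_value; sorted by p ascending.
    """

    table: pd.DataFrame
    universe_size: int
    study_size: int

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.DataFrame:
        col = "q_value" if adjusted else "p_value"
        return self.table[self.table[col] <= alpha]


@dataclass
class CrossSetReport:
    """Edges of a PPI graph classified against sets A and B."""

    within_a: list[tuple[str, str]]
    a_to_b: list[tuple[str, str]]
    isolated_a: frozenset[str]

    def to_jsonable(self) -> dict:
        return {
            "within_a": sorted(map(list, self.within_a)),
            "a_to_b": sorted(map(list, self.a_to_b)),
            "isolated_a": sorted(self.isolated_a),
        }


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); 1.0 when k == 0."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study, universe, gsc: GeneSetCollection
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``study`` in each term.

    Term memberships are intersected with the universe before testing;
    terms with no member in the universe are not tested at all (they
    could never overlap).  Terms with members in the universe but none
    in the study are reported with p = 1.
    """
    study = frozenset(g.upper() for g in study)
    universe = frozenset(g.upper() for g in universe)
    if not universe:
        raise ValueError("empty universe")
    stray = study - universe
    if stray:
        raise ValueError(
            f"study genes outside the universe: {sorted(stray)[:5]}"
        )
    N, n = len(universe), len(study)
    rows = []
    for term_id, (name, members) in gsc.items():
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = in_universe & study
        K, k = len(in_universe), len(overlap)
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "overlap_genes": ",".join(sorted(overlap)),
                "p_value": hypergeom_upper_tail(N, K, n, k),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "K", "n", "N", "overlap_genes", "p_value"],
    )
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(
            ["p_value", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["q_value"] = []
    return EnrichmentResult(table=table, universe_size=N, study_size=n)


def cross_set_interactions(g: PPIGraph, set_a, set_b) -> CrossSetReport:
    """Classify the graph's edges against study set A and reference set B.

    ``isolated_a`` lists members of A with no edge inside the subgraph
    induced by A ∪ B — the markers with no interaction evidence linking
    them to the rest of either set.
    """
    a = frozenset(s.upper() for s in set_a)
    b = frozenset(s.upper() for s in set_b)
    within_a: list[tuple[str, str]] = []
    a_to_b: list[tuple[str, str]] = []
    connected: set[str] = set()
    for u, v, _data in g.edges():
        in_a = (u in a, v in a)
        in_ab = (u in a or u in b, v in a or v in b)
        if all(in_ab):
            connected.update(x for x in (u, v) if x in a)
        if all(in_a):
            within_a.append(tuple(sorted((u, v))))
        elif (in_a[0] and v in b) or (in_a[1] and u in b):
            edge = (u, v) if in_a[0] else (v, u)
            a_to_b.append(edge)
    return CrossSetReport(
        within_a=sorted(within_a),
        a_to_b=sorted(a_to_b),
        isolated_a=frozenset(a - connected),
    )


def write_enrichment(result: EnrichmentResult, path) -> None:
    """Enrichment TSV: term, process name, p, q, overlapping genes."""
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
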