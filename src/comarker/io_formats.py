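"""Readers and writers for every external file the pipeline touches.

All downstream modules consume only the domain types defined here (plus
:class:`~comarker.harmonize.GeneMatrix` and friends); no other module
opens files.  The canonical on-disk dialect is plain TSV with a header
row.  Expression tables may carry a GEO series-matrix-style preamble of
``!``-prefixed metadata lines, which is skipped on read so that
deposited matrices can be ingested directly.  Sample labels live in a
separate two-column TSV (sample id, ``case``/``control``) because
series-matrix metadata fields are free text and dataset specific.

Gene symbols are upper-cased everywhere: cross-platform joins are done
on official symbols and case is the most common source of silent
mismatches.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

SAMPLE_TYPES = ("monocyte", "pbmc", "whole_blood", "other")
LABELS = ("case", "control")


class FormatError(ValueError):
    """Raised when an input file violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Probe-level expression matrix for one case-control cohort.

    ``values`` is probes x samples on whatever intensity scale the file
    was deposited in (scale is resolved later by
    :func:`comarker.harmonize.ensure_log_scale`).
    """

    dataset_id: str
    platform_id: str
    sample_type: str
    probe_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample_type {self.sample_type!r} not in {SAMPLE_TYPES}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample id")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        if len(set(self.labels)) < 2:
            raise FormatError("need both classes (case and control)")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([lab == "case" for lab in self.labels])

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return len(self.labels) - self.n_case


@dataclass
class ProbeMap:
    """Probe id -> official gene symbol for one platform.

    Probes without an annotation are simply absent from ``entries``.
    """

    platform_id: str
    entries: dict[str, str]

    def __post_init__(self) -> None:
        for probe, sym in self.entries.items():
            if not sym:
                raise ValueError(f"empty gene symbol for probe {probe!r}")
        self.entries = {p: s.upper() for p, s in self.entries.items()}


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, frozenset of upper-case gene symbols)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (name, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"empty gene set for term {tid!r}")
            self.terms[tid] = (name, frozenset(g.upper() for g in genes))

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> tuple[str, frozenset[str]]:
        return self.terms[term_id]

    def items(self):
        return self.terms.items()


@dataclass
class PPIGraph:
    """Undirected protein-protein interaction graph over gene symbols.

    Backed by a :class:`networkx.Graph`; edges may carry an evidence tag
    and a confidence score in [0, 1].  Self-loops are dropped on
    construction (their count is kept in ``n_self_loops_dropped``) and
    duplicate edges are merged ignoring orientation.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    n_self_loops_dropped: int = 0

    def add_edge(self, a: str, b: str, evidence: str = "", score: float | None = None) -> None:
        a, b = a.upper(), b.upper()
        if a == b:
            self.n_self_loops_dropped += 1
            return
        if score is not None and not (0.0 <= score <= 1.0):
            raise FormatError(f"score {score} outside [0, 1] for edge {a}-{b}")
        self.graph.add_edge(a, b, evidence=evidence, score=score)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges(data=True)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a.upper(), b.upper())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table_text(path: str | Path) -> str:
    """Return file contents with GEO series-matrix '!' preamble removed."""
    lines = Path(path).read_text().splitlines()
    kept = [ln for ln in lines if not ln.startswith("!")]
    return "\n".join(kept)


def read_expression_table(
    path: str | Path,
    dataset_id: str,
    sample_type: str,
    label_assignment: Mapping[str, str],
) -> ExpressionDataset:
    """Read a probes x samples TSV into an :class:`ExpressionDataset`.

    First column holds probe ids, the header row holds sample ids.
    ``label_assignment`` must map every sample id in the file to
    ``"case"`` or ``"control"``.  Row and column order are preserved.
    """
    text = _read_table_text(path)
    if not text.strip():
        raise FormatError(f"{path}: empty expression table")
    header, *rows = text.splitlines()
    sample_ids = header.split("\t")[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample id in header")
    missing = [s for s in sample_ids if s not in label_assignment]
    if missing:
        raise FormatError(
            f"{path}: samples missing from label assignment: {missing[:5]}"
        )
    frame = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    probe_ids = [str(p) for p in frame.index]
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"{path}: duplicate probe id")
    labels = [label_assignment[s] for s in sample_ids]
    for s, lab in zip(sample_ids, labels):
        if lab not in LABELS:
            raise FormatError(f"{path}: label {lab!r} for sample {s!r} invalid")
    if len(set(labels)) < 2:
        raise FormatError(f"{path}: need both classes (case and control)")
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform_id="",
        sample_type=sample_type,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        labels=labels,
        values=frame.to_numpy(dtype=float),
    )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, case|control) into a dict."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        sample, lab = parts[0].strip(), parts[1].strip().lower()
        if lab not in LABELS:
            raise FormatError(f"{path}:{i}: label {lab!r} not case/control")
        if sample in out:
            raise FormatError(f"{path}:{i}: duplicate sample id {sample!r}")
        out[sample] = lab
    return out


def read_probe_map(path: str | Path, platform_id: str) -> ProbeMap:
    """Read a two-column probe_id -> gene_symbol TSV.

    Rows with a blank or ``NA`` symbol are skipped (unannotated probes).
    A probe listed twice with conflicting symbols is an error; a repeat
    with the same symbol is tolerated.
    """
    entries: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "!")):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected 2 columns")
        probe, sym = parts[0].strip(), parts[1].strip()
        if not sym or sym.upper() in ("NA", "NAN", "---"):
            continue
        sym = sym.upper()
        if probe in entries and entries[probe] != sym:
            raise FormatError(
                f"{path}:{i}: conflicting annotation for probe {probe!r}: "
                f"{entries[probe]} vs {sym}"
            )
        entries[probe] = sym
    return ProbeMap(platform_id=platform_id, entries=entries)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, member genes...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs >=3 columns")
        term_id, name = parts[0], parts[1]
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path}:{i}: term {term_id!r} has no genes")
        terms[term_id] = (name, genes)
    return GeneSetCollection(terms=terms)


def read_edge_list(path: str | Path) -> PPIGraph:
    """Read a TSV edge list (geneA, geneB[, evidence[, score]])."""
    g = PPIGraph()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: edge needs >=2 columns")
        a, b = parts[0].strip(), parts[1].strip()
        evidence = parts[2].strip() if len(parts) > 2 else ""
        score = None
        if len(parts) > 3 and parts[3].strip():
            try:
                score = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: bad score {parts[3]!r}") from exc
        try:
            g.add_edge(a, b, evidence=evidence, score=score)
        except FormatError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    if g.n_self_loops_dropped:
        warnings.warn(
            f"{path}: dropped {g.n_self_loops_dropped} self-loop(s)",
            stacklevel=2,
        )
    return g


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    frame = pd.DataFrame(ds.values, index=ds.probe_ids, columns=ds.sample_ids)
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, lab in labels.items():
            fh.write(f"{sample}\t{lab}\n")


def write_probe_map(pmap: ProbeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for probe, sym in pmap.entries.items():
            fh.write(f"{probe}\t{sym}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def load_reference_marker_table() -> pd.DataFrame:
    """Published per-dataset statistics for the ten common lupus marker genes.

    Long-format table with one row per (gene, cohort): linear-scale
    fold change, two-sided t-test p, and BH-adjusted q, as printed for
    the four blood-borne cohorts (one monocyte, one PBMC, two whole
    blood).  Used as a worked input for the report-summarization code.
    """
    path = Path(__file__).parent / "data" / "common_marker_stats.tsv"
    return pd.read_csv(path, sep="\t")
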