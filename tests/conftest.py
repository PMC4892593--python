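"""Shared fixtures: tiny handcrafted cohorts and on-disk fixtures.

Everything is generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from comarker import ExpressionDataset, GeneMatrix, ProbeMap


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 probes x 4 samples, 2 cases + 2 controls."""
    return ExpressionDataset(
        dataset_id="D1",
        platform_id="P1",
        sample_type="pbmc",
        probe_ids=["p1", "p2", "p3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=["case", "case", "control", "control"],
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.0, 2.0, 2.0, 2.0]]
        ),
    )


@pytest.fixture
def tiny_probe_map() -> ProbeMap:
    return ProbeMap(platform_id="P1", entries={"p1": "GA", "p2": "GA", "p3": "GB"})


def make_gene_matrix(
    values, labels, genes=None, dataset_id="D1", sample_type="pbmc"
) -> GeneMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return GeneMatrix(
        dataset_id=dataset_id,
        sample_type=sample_type,
        gene_symbols=list(genes),
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        labels=list(labels),
        values=values,
        log2=True,
    )


@pytest.fixture
def gene_matrix_factory():
    return make_gene_matrix
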