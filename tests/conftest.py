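import numpy as np
import pandas as pd
import pytest

from shfgrn.expression import ExpressionDataset
from shfgrn.genome import Gene, GenomeModel


@pytest.fixture
def tiny_genome():
    """Two chromosomes, four genes with family labels."""
    return GenomeModel(
        chromosomes={"chr1": 1_000_000, "chr2": 500_000},
        genes=[
            Gene("gA", "chr1", 100_000, "+", frozenset({"TF"})),
            Gene("gB", "chr1", 300_000, "-", frozenset()),
            Gene("gC", "chr1", 600_000, "+", frozenset({"TF", "FOX"})),
            Gene("gD", "chr2", 250_000, "-", frozenset()),
        ],
    )


def make_dataset(values, gene_map=None, n_case=None, qc=None, scale="raw"):
    """Build an ExpressionDataset from a plain matrix.

    ``values`` is probes x samples; the first ``n_case`` columns
    (default half) are cases.
    """
    values = np.asarray(values, dtype=float)
    n_probe, n_samp = values.shape
    if n_case is None:
        n_case = n_samp // 2
    probes = [f"p{i}" for i in range(n_probe)]
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_samp - n_case)
    ]
    if gene_map is None:
        gene_map = {p: f"g{i}" for i, p in enumerate(probes)}
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    df = pd.DataFrame(values, index=probes, columns=samples)
    qc_df = None
    if qc is not None:
        qc_df = pd.DataFrame(qc, index=probes, columns=samples)
    return ExpressionDataset(
        values=df, probe_map=gene_map, groups=groups, qc_flags=qc_df, scale=scale
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
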