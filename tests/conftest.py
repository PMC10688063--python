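import numpy as np
import pandas as pd
import pytest

from epimut.inheritance import EpimutationRun
from epimut.model import CountMatrix, SampleMeta


def make_samples(lineages=("C1",), generations=(0, 2, 4), conditions=None):
    conditions = conditions or {lin: "control" for lin in lineages}
    return [
        SampleMeta(f"{lin}_g{g}", lin, conditions[lin], g)
        for lin in lineages
        for g in generations
    ]


def make_count_matrix(values, lineages=("C1",), generations=(0, 2, 4), loci=None,
                      conditions=None, locus_class="gene"):
    samples = make_samples(lineages, generations, conditions)
    values = np.asarray(values)
    loci = loci or [f"g{i}" for i in range(values.shape[0])]
    counts = pd.DataFrame(values, index=pd.Index(loci, name="locus"),
                          columns=[s.sample_id for s in samples])
    return CountMatrix(counts, samples, locus_class=locus_class)


def make_run(locus="g0", lineage="C1", direction=1, start=2, end=2, n=1,
             censored=False):
    return EpimutationRun(locus, lineage, direction, start, end, n, censored)


def make_calls(rows, lineages=("C1",), generations=(2, 4, 6, 8, 10)):
    """Ternary call matrix from per-locus row vectors (single lineage) or
    a dict lineage -> rows."""
    if not isinstance(rows, dict):
        rows = {lineages[0]: rows}
    pieces = {}
    for lineage, mat in rows.items():
        mat = np.asarray(mat)
        for j, g in enumerate(generations[: mat.shape[1]]):
            pieces[(lineage, g)] = mat[:, j]
    n_loci = next(iter(rows.values())).__len__()
    df = pd.DataFrame(pieces, index=pd.Index([f"g{i}" for i in range(n_loci)],
                                             name="locus"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["lineage", "generation"])
    return df


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    return make_count_matrix(rng.integers(10, 1000, size=(50, 6)),
                             lineages=("C1", "C2"), generations=(0, 2, 4),
                             conditions={"C1": "control", "C2": "control"})
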