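import numpy as np
import pandas as pd
import pytest

from coexnet import ingest, modules, netcore, simulate
from coexnet.types import CountMatrix, ExpressionMatrix


def make_expression(values: np.ndarray, condition: str = "c", batch: str = "b") -> ExpressionMatrix:
    """Wrap a raw value array as an ExpressionMatrix with trivial metadata."""
    n_genes, n_samples = values.shape
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_meta=pd.DataFrame(
            {"condition": condition, "batch": batch}, index=samples
        ),
        size_factors=pd.Series(1.0, index=samples),
    )


def make_counts(counts: np.ndarray, conditions=None, batches=None) -> CountMatrix:
    n_genes, n_samples = counts.shape
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["c"] * n_samples,
            "batch": batches if batches is not None else ["b"] * n_samples,
        },
        index=samples,
    )
    return CountMatrix(
        counts=pd.DataFrame(counts.astype("int64"), index=genes, columns=samples),
        sample_meta=meta,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Default-scale synthetic dataset with its planted truth."""
    cfg = simulate.GeneratorConfig(seed=7)
    cm, truth = simulate.generate_expression(cfg)
    return cm, truth


@pytest.fixture(scope="session")
def planted_network(planted_dataset):
    """Full network + module detection on the default synthetic dataset."""
    cm, truth = planted_dataset
    em = ingest.normalize(cm)
    r = netcore.correlation_matrix(em)
    a = netcore.adjacency(r, beta=12, mode="unsigned")
    t = netcore.tom(a)
    dend = modules.average_linkage(t.diss)
    part0 = modules.dynamic_tree_cut(dend, t.diss)
    merged, eigengenes = modules.merge_modules(part0, em)
    return {
        "truth": truth,
        "em": em,
        "r": r,
        "a": a,
        "tom": t,
        "dend": dend,
        "unmerged": part0,
        "merged": merged,
        "eigengenes": eigengenes,
    }
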