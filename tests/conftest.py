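import numpy as np
import pandas as pd
import pytest

from contextnet.geneset_io import Category, FoldChangeMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_collections():
    """Three TFBS sets (two sharing a TF) and two functional sets."""
    tfbs = GeneSetCollection(
        [
            GeneSet("V$AAA_01", frozenset(f"G{i}" for i in range(12)), Category.TFBS, tf_label="AAA"),
            GeneSet("V$AAA_02", frozenset(f"G{i}" for i in range(6, 20)), Category.TFBS, tf_label="AAA"),
            GeneSet("V$BBB_01", frozenset(f"G{i}" for i in range(15, 30)), Category.TFBS, tf_label="BBB"),
        ]
    )
    funcs = GeneSetCollection(
        [
            GeneSet("FN1", frozenset(f"G{i}" for i in range(10)), Category.GO_BP),
            GeneSet("FN2", frozenset(f"G{i}" for i in range(20, 32)), Category.KEGG),
        ]
    )
    return tfbs, funcs


@pytest.fixture
def gmt_file(tmp_path):
    """A well-formed GMT file with a duplicated gene inside one line."""
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SETA\tdesc a\tg1\tG2\tg2\tG3\n"
        "SETB\tdesc b\tG4\tG5\tG6\n"
    )
    return path


def make_matrix(values, genes=None, conditions=None) -> FoldChangeMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    conditions = conditions or [f"C{j}" for j in range(values.shape[1])]
    return FoldChangeMatrix(pd.DataFrame(values, index=genes, columns=conditions))


@pytest.fixture
def matrix_factory():
    return make_matrix
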