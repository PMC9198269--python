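import numpy as np
import pytest

from cellscreen.datastore import ExpressionMatrix
from cellscreen.response import ResponseLabeling


@pytest.fixture
def labeling_factory():
    """Build a ResponseLabeling directly from a cell_line -> label mapping."""

    def make(labels, dataset="DS1", compound="DRUG1", metric="audrc",
             scheme="tertile", lower=0.0, upper=1.0):
        return ResponseLabeling(dataset, compound, metric, scheme, lower, upper,
                                dict(labels))

    return make


@pytest.fixture
def matrix_factory():
    def make(values, genes=None, cell_lines=None, state="prenormalized"):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"G{i}" for i in range(values.shape[0])]
        cell_lines = cell_lines or [f"CL{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(genes, cell_lines, values, state)

    return make


def write_tsv(path, text):
    path.write_text(text)
    return str(path)
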