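import numpy as np
import pytest

from scstyle.data import ExpressionSet
from scstyle.io_prep import log_tpm_transform, qc_filter
from scstyle.simulate import default_benchmark_design, simulate


def make_set(matrix, batches=None, celltypes=None, units="raw_counts"):
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    return ExpressionSet(
        matrix=matrix,
        cell_ids=np.array([f"c{i}" for i in range(n)], object),
        gene_ids=np.array([f"g{j}" for j in range(d)], object),
        batch_labels=np.array(batches if batches is not None else ["b0"] * n, object),
        celltype_labels=None if celltypes is None else np.array(celltypes, object),
        units=units,
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """Simulated tiny two-batch dataset with ground truth."""
    return simulate(default_benchmark_design("tiny", seed=11))


@pytest.fixture(scope="session")
def tiny_logged(tiny_sim):
    es, truth = tiny_sim
    return log_tpm_transform(qc_filter(es)), truth
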