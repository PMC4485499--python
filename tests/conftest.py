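import numpy as np
import pytest

from nmrfactor.datasets import BinnedDataset, SampleMetadata


def make_dataset(matrix, groups=None, bin_width=0.01, centers=None, biofluid="urine"):
    """BinnedDataset from a raw matrix plus optional (disease, ea) tuples."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if groups is None:
        groups = [("control", "none")] * n
    if centers is None:
        centers = 0.5 + (np.arange(p) + 0.5) * bin_width
    metadata = [
        SampleMetadata(f"S{i:03d}", d, e, biofluid) for i, (d, e) in enumerate(groups)
    ]
    return BinnedDataset(
        matrix=matrix, bin_centers=np.asarray(centers, float), bin_width=bin_width,
        metadata=metadata,
    )


def two_group_labels(n_a, n_b, cell_a=("control", "none"), cell_b=("GML", "none")):
    return [cell_a] * n_a + [cell_b] * n_b


@pytest.fixture(scope="session")
def paper_design():
    from nmrfactor.synth import PAPER_GROUP_SIZES, generate_design

    return generate_design(PAPER_GROUP_SIZES, biofluid="urine", seed=0)


@pytest.fixture(scope="session")
def default_dataset(paper_design):
    """Coarse-binned default simulation shared by read-only tests."""
    from nmrfactor.synth import simulate_dataset

    dataset, truth = simulate_dataset(paper_design, bin_width=0.01, seed=11)
    return dataset, truth
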