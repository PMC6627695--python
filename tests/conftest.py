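import numpy as np
import pandas as pd
import pytest

from rgstab import CtMatrix, GroupDesign


def make_matrix(values, genes=None, samples=None) -> CtMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return CtMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture
def toy_matrix() -> CtMatrix:
    """The worked 3-gene example: g1 constant, g2 rising, g3 falling."""
    return make_matrix([[20, 20, 20], [20, 21, 22], [20, 19, 18]])


@pytest.fixture
def toy_design() -> GroupDesign:
    return GroupDesign.from_mapping(
        {"s1": ("d1", "A"), "s2": ("d2", "A"), "s3": ("d3", "B")}
    )


@pytest.fixture
def random_matrix():
    """Factory for seeded random Ct matrices around a 13-26 cycle range."""

    def _make(n_genes=10, n_samples=12, seed=0, noise_sd=1.0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(13, 26, n_genes)[:, None]
        return make_matrix(base + rng.normal(0, noise_sd, (n_genes, n_samples)))

    return _make


@pytest.fixture
def grouped_design():
    """Factory for a design splitting n samples into labelled groups."""

    def _make(sizes: dict, sample_ids=None):
        mapping = {}
        i = 0
        for group, n in sizes.items():
            for d in range(n):
                sid = sample_ids[i] if sample_ids else f"s{i + 1}"
                mapping[sid] = (f"d{d + 1}", group)
                i += 1
        return GroupDesign.from_mapping(mapping)

    return _make
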