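"""Shared fixtures: scaled-down simulated datasets and their superimpositions."""

from dataclasses import replace

import numpy as np
import pytest

import morphomod as mm
from morphomod.simulate import default_params, simulate_dataset, with_overrides


def scaled_strain_table(max_mice: int):
    """The packaged study design with per-strain sample sizes capped (keeps
    unit tests fast while preserving the 19-strain structure)."""
    return [replace(r, n_mice=min(r.n_mice, max_mice)) for r in mm.load_strain_table()]


def two_strain_table(n_ref=12, n_test=12, seg_mb=60.0, n_segments=2):
    ref = mm.StrainRecord("REF", n_ref, is_reference=True)
    test = mm.StrainRecord("T1", n_test, seg_mb=seg_mb, n_segments=n_segments, n_genes=100)
    return [ref, test]


@pytest.fixture(scope="session")
def small_dataset():
    """19-strain design, at most 4 mice per strain, default parameters."""
    return simulate_dataset(default_params(seed=99), scaled_strain_table(4))


@pytest.fixture(scope="session")
def small_symmetrized(small_dataset):
    decomp, gpa_res, meta = mm.matching_symmetry(small_dataset)
    tangent = mm.tangent_project(gpa_res)
    return {
        "dataset": small_dataset,
        "decomp": decomp,
        "gpa": gpa_res,
        "meta": meta,
        "tangent": tangent,
        "k": small_dataset.landmark_count,
    }


@pytest.fixture(scope="session")
def hypothesis_partition():
    graph = mm.load_adjacency(16)
    return mm.PartitionHypothesis(
        frozenset([1, 2, 3, 4, 13, 14, 15, 16]), frozenset(range(5, 13)), graph
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20121001)
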