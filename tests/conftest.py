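"""Shared fixtures: small deterministic datasets and fingerprint factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from persig import synthetic
from persig.io_formats import MatrixTable
from persig.profiles import BinaryFingerprint


@pytest.fixture(scope="session")
def sim_default():
    """One default coupled simulation, shared across tests (seed 1)."""
    return synthetic.simulate(synthetic.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_small():
    """A reduced simulation for fast pipeline-level tests."""
    cfg = synthetic.SimulationConfig(
        seed=7, n_compounds=60, n_scaffolds=12, n_kinases=24, n_groups=4,
        n_pathways=6, n_genes=80, n_cell_lines=3,
    )
    return synthetic.simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fingerprints(rng, n, space="chem", n_features=64, density=0.2):
    """Random fingerprint collection for oracle-equivalence tests."""
    features = [f"f{j:03d}" for j in range(n_features)]
    out = {}
    for i in range(n):
        mask = rng.random(n_features) < density
        out[f"C{i:03d}"] = BinaryFingerprint(
            space_id=space, bits=frozenset(np.array(features, dtype=object)[mask])
        )
    return out


def make_matrix(values, row_ids, col_ids, value_kind="inhibition") -> MatrixTable:
    return MatrixTable(
        values=pd.DataFrame(np.asarray(values, dtype=float), index=row_ids, columns=col_ids),
        value_kind=value_kind,
    )
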