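import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from coalescekit.data_io import OtuTable, TaxonomyMap
from coalescekit.synthetic import SimConfig, simulate_cohort


@pytest.fixture
def star_tree():
    """Three unit branches hanging off the root."""
    return TreeNode.read(io.StringIO("(t1:1,t2:1,t3:1):0;"))


@pytest.fixture
def tiny_table():
    """Two samples (one oral, one stool) over three OTUs."""
    meta = pd.DataFrame(
        {"patient_id": ["p1", "p1"], "site": ["oral", "stool"], "day": [0, 0]},
        index=["s1", "s2"],
    )
    return OtuTable(
        counts=np.array([[1, 1, 0], [0, 1, 1]]),
        sample_ids=["s1", "s2"],
        otu_ids=["t1", "t2", "t3"],
        meta=meta,
    )


def make_table(counts, sites, patients=None, days=None, otu_ids=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "patient_id": patients or ["p1"] * n,
            "site": sites,
            "day": days if days is not None else list(range(n)),
        },
        index=sample_ids,
    )
    return OtuTable(
        counts=counts,
        sample_ids=sample_ids,
        otu_ids=otu_ids or [f"o{j}" for j in range(counts.shape[1])],
        meta=meta,
    )


@pytest.fixture
def taxonomy_two_genera():
    return TaxonomyMap({"o0": "Bacteria;F;B;L;S;GenusA", "o1": "Bacteria;F;B;L;S;GenusB"})


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient synthetic cohort shared across tests (read-only)."""
    config = SimConfig(n_patients=30, depth_mean=800, seed=7)
    return config, simulate_cohort(config)
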