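import numpy as np
import pytest

import blendevol as bv
from blendevol.io_peaktables import annotate_peaks


@pytest.fixture(scope="session")
def clean_dataset() -> bv.SimulatedDataset:
    """Small clean synthetic study used across module tests."""
    config = bv.SimulationConfig(n_tips=12, n_compounds=15, seed=11)
    return bv.simulate_dataset(config)


@pytest.fixture(scope="session")
def clean_pipeline(clean_dataset):
    """Annotated peaks, clusters and blend matrix for the clean dataset."""
    ds = clean_dataset
    ladders = {
        b: bv.AlkaneLadder(b, dict(zip(g["carbon_number"], g["rt_min"])))
        for b, g in ds.ladders.groupby("batch_id")
    }
    ann = annotate_peaks(ds.peaks, ladders)
    clusters = bv.cluster_peaks(ann.peaks)
    matrix = bv.build_matrix(clusters, ann.peaks)
    return ds, ann, clusters, matrix


@pytest.fixture(scope="session")
def balanced_tree() -> bv.Phylogeny:
    """Ultrametric 4-tip balanced tree with hand-checkable covariance."""
    newick = "((a:2,b:2):3,(c:4,d:4):1);"
    return bv.Phylogeny.from_newick(newick, is_path=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
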