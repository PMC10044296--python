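import numpy as np
import pandas as pd
import pytest

import phenoclust as pc


def make_binary(array, pids=None, cols=None) -> pc.BinaryMatrix:
    """Small helper: BinaryMatrix from a plain nested list / array."""
    arr = np.asarray(array, dtype=np.int8)
    pids = pids or [f"p{i}" for i in range(arr.shape[0])]
    cols = cols or [f"x{j}" for j in range(arr.shape[1])]
    return pc.BinaryMatrix(pd.DataFrame(arr, index=pids, columns=cols))


def assignment(ids, labels=None) -> pc.ClusterAssignment:
    ids = np.asarray(ids, dtype=int)
    labels = labels or [f"p{i}" for i in range(len(ids))]
    from phenoclust.hierarchy import relabel_by_first_appearance

    return relabel_by_first_appearance(ids, labels)


@pytest.fixture(scope="session")
def discovery_small():
    """Moderate planted cohort shared by recovery-style unit tests."""
    cfg = pc.preset("discovery_like", n_participants=700)
    rm, truth = pc.generate_cohort(cfg, seed=42)
    rm = pc.impute_mode_of_m(rm, m=5, seed=43)
    bm = pc.binarize(rm)
    return bm, truth


@pytest.fixture(scope="session")
def discovery_small_inputs(discovery_small):
    bm, truth = discovery_small
    return pc.prepare_inputs(bm), truth
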