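import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabolodiv.feature_io import FeatureTable, SampleMeta, meta_frame

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def make_table(values, sample_metas, mode="positive", mz0=100.0, rt0=1.0):
    """Small FeatureTable from a 2-D array (features x samples)."""
    values = np.asarray(values, dtype=float)
    idx = pd.MultiIndex.from_tuples(
        [(mz0 + 10.0 * i, rt0 + 0.5 * i, mode) for i in range(values.shape[0])],
        names=["mz", "rt", "esi_mode"],
    )
    meta = meta_frame(sample_metas)
    data = pd.DataFrame(values, index=idx, columns=list(meta.index))
    return FeatureTable(data, meta, allow_empty_samples=True)


def simple_metas(n, genotype="WT", n_conc=4.0, time=15, organ="rosette"):
    return [
        SampleMeta(f"s{i+1}", genotype, n_conc, time, organ, i + 1) for i in range(n)
    ]


@pytest.fixture
def two_group_metas():
    """Four samples: two at 4 mM, two at 0.2 mM nitrate."""
    return [
        SampleMeta("a1", "WT", 4.0, 15, "rosette", 1),
        SampleMeta("a2", "WT", 4.0, 15, "rosette", 2),
        SampleMeta("b1", "WT", 0.2, 15, "rosette", 1),
        SampleMeta("b2", "WT", 0.2, 15, "rosette", 2),
    ]


@pytest.fixture
def tiny_table(two_group_metas):
    return make_table(
        [[10.0, 10.0, 5.0, 5.0], [4.0, 4.0, 8.0, 8.0], [1.0, 0.0, 1.0, 2.0]],
        two_group_metas,
    )
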