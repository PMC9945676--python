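import numpy as np
import pandas as pd
import pytest

from dmrseg.io import DesignMatrix, MethylationDataset
from dmrseg.simulate import default_design


def make_dataset(chrom, pos, nbs, nc, sample_ids=None):
    nbs = np.asarray(nbs)
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(nbs.shape[1])]
    sites = pd.DataFrame({"chrom": chrom, "pos": pos})
    return MethylationDataset(sample_ids=list(sample_ids), sites=sites,
                              nbs=nbs, nc=np.asarray(nc))


@pytest.fixture
def design6() -> DesignMatrix:
    """The default 6-sample confounded design (intercept, case/control, binary, continuous)."""
    return default_design()


@pytest.fixture
def two_group_design() -> DesignMatrix:
    return DesignMatrix(
        matrix=np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]]),
        covariate_names=["intercept", "group"],
        interest_index=1,
        sample_ids=[f"s{j + 1}" for j in range(6)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
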