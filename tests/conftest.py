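import numpy as np
import pytest

from her2ith import CloneProfile, TumorSpec, histogram_from_cells, paper97
from her2ith.synth import simulate_tumor

# canonical two-clone recovery fixture: pi=(0.4, 0.6), mu=(1.5, 6.0),
# sigma=(0.4, 1.0), 2000 nuclei
BIMODAL_SPEC = TumorSpec(
    clones=(CloneProfile(mean_her2=1.5, sd_her2=0.4),
            CloneProfile(mean_her2=6.0, sd_her2=1.0)),
    weights=(0.4, 0.6),
    n_cells=2000,
    true_label="HH",
)


@pytest.fixture(scope="session")
def bimodal_hist():
    sample = simulate_tumor(BIMODAL_SPEC, np.random.default_rng(20240901))
    return histogram_from_cells(sample.cells)


@pytest.fixture(scope="session")
def unimodal_hist():
    spec = TumorSpec(clones=(CloneProfile(mean_her2=5.0, sd_her2=1.0),),
                     weights=(1.0,), n_cells=2000, true_label="LH")
    sample = simulate_tumor(spec, np.random.default_rng(20240902))
    return histogram_from_cells(sample.cells)


@pytest.fixture(scope="session")
def paper97_cohort():
    return paper97(seed=0)
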