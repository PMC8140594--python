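import numpy as np
import pytest

from spmlmi import (
    SyntheticConfig,
    build_bilayer,
    generate_dataset,
    pearson_similarity,
    standardize,
)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Small group-structured dataset: fast but with clear planted signal."""
    return SyntheticConfig(
        n_lnc=36,
        n_mi=12,
        n_conditions=12,
        n_groups=3,
        noise_sd=0.3,
        affinity=np.diag([0.7, 0.7, 0.7]),
        background_p=0.03,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_bilayer(small_dataset):
    lnc_em, mi_em, lm, _ = small_dataset
    ls = pearson_similarity(standardize(lnc_em))
    ms = pearson_similarity(standardize(mi_em))
    return build_bilayer(ls, ms, lm)
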