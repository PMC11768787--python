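import numpy as np
import pytest

import protonet as pn


@pytest.fixture(scope="session")
def easy_cohort():
    """Reduced easy-preset cohort: strong tremor, no N5 confusers."""
    cfg = pn.difficulty_presets("easy")
    cfg.n_tremor, cfg.n_pd_no_tremor, cfg.n_controls = 3, 2, 2
    cfg.duration_s = 300.0
    return pn.generate_cohort(cfg, 1)


@pytest.fixture(scope="session")
def easy_table(easy_cohort):
    return pn.build_feature_table(easy_cohort)


@pytest.fixture(scope="session")
def easy_table_z(easy_table):
    return pn.zscore_fit_apply(easy_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def planted_clusters(seed, n_per=100, sep=10.0, d=2):
    """Three spherical Gaussian clusters at pairwise separation ``sep``."""
    r = np.random.default_rng(seed)
    centers = np.zeros((3, d))
    centers[1, 0] = sep
    centers[2, 1] = sep
    z = np.repeat(np.arange(3), n_per)
    X = centers[z] + r.standard_normal((3 * n_per, d))
    return X, z
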