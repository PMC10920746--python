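import numpy as np
import pytest
from scipy.stats import norm

from realness_ssvep import synthetic_data as sd
from realness_ssvep.synthetic_data import GenerativeParams

#: small montage subset used by fast simulation tests
CH4 = ["PO7", "POz", "Oz", "PO8"]


@pytest.fixture(scope="session")
def small_design():
    return sd.make_design(n_subjects=1, n_sessions=3, seed=11)


@pytest.fixture(scope="session")
def default_epochs(small_design):
    """One subject, three sessions of default synthetic epochs (cluster9)."""
    params = GenerativeParams(seed=11)
    ep, truth = sd.simulate_epochs(small_design, params)
    return ep, truth


@pytest.fixture(scope="session")
def noisefree_epochs(small_design):
    params = GenerativeParams(seed=5, noise_sd=0.0, alpha_sd=0.0,
                              subject_sd=0.0)
    ep, truth = sd.simulate_epochs(small_design, params)
    return ep, truth


def gaussian_window_mean(lo_ms, hi_ms, components):
    """Closed-form mean of a sum of Gaussians over [lo, hi) ms."""
    total = 0.0
    for mu, a, w in components:
        total += a * w * np.sqrt(2 * np.pi) * (
            norm.cdf((hi_ms - mu) / w) - norm.cdf((lo_ms - mu) / w))
    return total / (hi_ms - lo_ms)


def permute_within_session(labels, rng):
    """Shuffle realness labels among trials within each subject x session."""
    labels = labels.copy()
    for _, grp in labels.groupby(["subject", "session"]):
        rows = grp.index.to_numpy()
        labels.loc[rows, "realness"] = (
            labels.loc[rng.permutation(rows), "realness"].to_numpy())
    return labels
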