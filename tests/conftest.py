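import numpy as np
import pandas as pd
import pytest

from qtnvar.panel import build_design_matrix, make_full_factorial_panel
from qtnvar.simulate import default_sample_table


@pytest.fixture(scope="session")
def panel():
    return make_full_factorial_panel()


@pytest.fixture(scope="session")
def samples(panel):
    """The emulated 63-sample design: 4 replicate days, one dropped library."""
    return default_sample_table(panel)


@pytest.fixture(scope="session")
def design(panel):
    return build_design_matrix(panel)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def nested_refit_sequential_ss(design: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Independent sequential-SS oracle: difference residual SS of prefix refits.

    Fits every prefix model with numpy.linalg.lstsq and attributes to each
    term the drop in residual sum of squares when it is appended.
    """
    X = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)

    def rss(k):
        if k == 0:
            return float(y @ y)
        beta, *_ = np.linalg.lstsq(X[:, :k], y, rcond=None)
        r = y - X[:, :k] @ beta
        return float(r @ r)

    drops = [rss(k) - rss(k + 1) for k in range(X.shape[1])]
    return pd.Series(drops, index=design.columns)
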