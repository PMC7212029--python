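import numpy as np
import pandas as pd
import pytest

from wntstrat import ExpressionMatrix, SimulationConfig, simulate_cohort
from wntstrat.config import replace_config


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort (n=80) with reads, shared across read-only tests."""
    cfg = replace_config(SimulationConfig(), n_samples=80, seed=5)
    return simulate_cohort(cfg), cfg


def make_norm(values: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    """Build a log-space expression matrix from per-gene value lists."""
    frame = pd.DataFrame(values, index=samples).T
    frame.columns = samples
    return ExpressionMatrix(values=frame.astype(float), space="log_cpm")


def welch_oracle(a, b):
    """Textbook Welch t, df and two-sided p for two 1-D samples."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Step-up BH adjusted p-values, straight from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
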