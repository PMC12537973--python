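import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")

from depscreen import CellLineGrouping, DependencyMatrix


@pytest.fixture
def tiny_dependency():
    """3 target + 3 background lines, one clearly selective gene."""
    scores = pd.DataFrame(
        {
            "T1": [-0.9, -0.2, 0.05],
            "T2": [-0.8, -0.2, -0.02],
            "T3": [-1.0, -0.2, 0.01],
            "B1": [0.0, -0.2, 0.03],
            "B2": [0.1, -0.2, -0.01],
            "B3": [-0.1, -0.2, 0.02],
        },
        index=["SEL1", "FLAT1", "NULL1"],
    )
    dep = DependencyMatrix(scores=scores)
    grouping = CellLineGrouping(
        mapping={c: ("AML" if c.startswith("T") else "OTHER") for c in scores.columns},
        target_label="AML",
    )
    return dep, grouping


def welch_oracle(a, b):
    """Closed-form Welch t and Satterthwaite df, independent of the package."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p
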