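import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scnkit.simulate import CohortSpec, generate_cohort, uniform_correlation


@pytest.fixture
def small_cohort():
    """60 controls + 60 cases, 6 regions, one implanted edge, two sites."""
    labels = [f"R{i}" for i in range(6)]
    spec = CohortSpec(
        n_control=60,
        n_case=60,
        region_labels=labels,
        base_covariance=uniform_correlation(6, 0.3),
        case_edge_effects=[(0, 1, 0.2)],
        site_labels=["siteA", "siteB"],
        site_effects={"siteA": (0.0, 1.0), "siteB": (20.0, 1.0)},
        covariate_effects={"age": 0.5},
        severity_link=(0, 1, 0.3, float(np.sqrt(1 - 0.09))),
        seed=11,
    )
    table, truth = generate_cohort(spec)
    return table, truth, spec


@pytest.fixture
def toy_residuals():
    """Deterministic 6-subject x 4-region residual-style table."""
    import pandas as pd

    rng = np.random.default_rng(7)
    data = rng.normal(size=(6, 4)).round(3)
    df = pd.DataFrame(data, columns=["a", "b", "c", "d"])
    df.insert(0, "group", ["control"] * 3 + ["case"] * 3)
    return df
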