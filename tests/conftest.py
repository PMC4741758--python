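import numpy as np
import pandas as pd
import pytest

from immfocus import derive_ings, normalize
from immfocus.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at the generator's default study conditions."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    """(raw, normalized, clinical, truth, ings) for the default cohort."""
    expr, clin, truth = default_cohort
    ings = derive_ings(expr)
    norm = normalize(expr, ings)
    return expr, norm, clin, truth, ings


@pytest.fixture()
def tiny_expr():
    """A 4-gene x 4-sample matrix with exact, hand-checkable structure."""
    return pd.DataFrame(
        {
            "s1": [2.0, 4.0, 3.0, 5.0],
            "s2": [4.0, 8.0, 6.0, 1.0],
            "s3": [6.0, 12.0, 9.0, 2.0],
            "s4": [8.0, 16.0, 12.0, 7.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


@pytest.fixture()
def small_clinical():
    rng = np.random.default_rng(7)
    n = 30
    return pd.DataFrame(
        {
            "os_time": rng.exponential(1000, n).round(1),
            "event": rng.integers(0, 2, n),
            "age": rng.normal(60, 8, n).round(1),
            "gender": np.where(rng.random(n) < 0.5, "male", "female"),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
        },
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"),
    )
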