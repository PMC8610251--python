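import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SPHERE_VOLUME_07 = 4.0 / 3.0 * np.pi * 0.7 ** 3   # ≈ 1.4368 μm³


@pytest.fixture
def ideal_volume():
    """Closed-form volume of a 0.7 μm-radius sphere."""
    return SPHERE_VOLUME_07


def tidy_table(groups: dict, metric: str = "m",
               n_experiments: int | None = None) -> pd.DataFrame:
    """Build a tidy measurement table from {condition: values}.

    Values are spread across experiments round-robin unless
    ``n_experiments`` is 1.
    """
    rows = []
    for condition, values in groups.items():
        for i, value in enumerate(values):
            exp = 0 if n_experiments == 1 else i
            rows.append({"experiment_id": f"exp_{exp}", "condition": condition,
                         "cell_id": f"cell_{i}", "metric_name": metric,
                         "value": float(value)})
    return pd.DataFrame(rows)
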