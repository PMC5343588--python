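import numpy as np
import pandas as pd
import pytest

from cdnorm import ExperimentDesign


@pytest.fixture
def design6():
    """Two conditions with three replicates each, one treatment pair."""
    return ExperimentDesign(
        condition_of={
            "s1": "ctl", "s2": "ctl", "s3": "ctl",
            "s4": "trt", "s5": "trt", "s6": "trt",
        },
        control_of={"trt": "ctl"},
    )


@pytest.fixture
def matrix6(design6):
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(60)]
    values = rng.normal(8.0, 1.0, size=(60, 6))
    return pd.DataFrame(values, index=genes, columns=list(design6.condition_of))


def make_design(n_conditions: int, n_replicates: int) -> ExperimentDesign:
    condition_of = {
        f"c{k}_r{r}": f"c{k}"
        for k in range(n_conditions)
        for r in range(n_replicates)
    }
    return ExperimentDesign(condition_of=condition_of)
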