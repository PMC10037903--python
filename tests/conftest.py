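import numpy as np
import pandas as pd
import pytest

from pfasmeth.exposures import ExposureTable
from pfasmeth.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject, 200-site null cohort reused across tests."""
    cfg = CohortConfig(n_subjects=60, n_paired=30, n_sites=200, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def toy_exposure_table():
    rng = np.random.default_rng(5)
    subjects = [f"S{i}" for i in range(8)]
    vals = pd.DataFrame({
        "A": rng.lognormal(1.0, 0.5, 8),
        "B": rng.lognormal(-2.0, 0.5, 8),
    }, index=subjects)
    flags = pd.DataFrame(False, index=subjects, columns=["A", "B"])
    flags.loc[subjects[:3], "B"] = True
    vals = vals.where(~flags)
    return ExposureTable(values=vals, below_lod=flags,
                         lod=pd.Series({"A": 0.1, "B": 0.1}))
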