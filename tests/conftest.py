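import numpy as np
import pandas as pd
import pytest

from pkdprog import prep, synthetic
from pkdprog.workflows import simulate_processed_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 60-patient cohort with interventions (session-cached)."""
    cfg = synthetic.CohortConfig(n_patients=60, seed=7)
    clinical, creatinine, interventions, truth = synthetic.generate_cohort(cfg)
    return cfg, clinical, creatinine, interventions, truth


@pytest.fixture(scope="session")
def processed_cohort():
    """Full simulate -> slopes -> preprocess chain, 200 patients (cached)."""
    ccfg = synthetic.CohortConfig(n_patients=200, seed=11)
    pcfg = synthetic.ProteomeSimConfig(n_proteins=120, seed=12)
    matrix, slopes, truth, extras = simulate_processed_cohort(ccfg, pcfg)
    return matrix, slopes, truth, extras


@pytest.fixture()
def tiny_report():
    """2-run x 2-protein long-format DIA report."""
    return pd.DataFrame(
        {
            "Run": ["r1", "r1", "r2", "r2"],
            "Protein.Group": ["PG_A", "PG_B", "PG_A", "PG_B"],
            "Genes": ["A", "B", "A", "B"],
            "Q.Value": [0.001, 0.02, 0.005, 0.01],
            "Intensity": [100.0, 200.0, 110.0, 190.0],
        }
    )


def make_matrix(values, samples=None, columns=None, batch=None):
    """Build a ProteomeMatrix from a dense array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    columns = columns or [f"g{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=samples, columns=columns)
    m = prep.ProteomeMatrix(data=data, observed=data.notna())
    if batch is not None:
        m.batch = pd.Series(batch, index=samples)
    return m
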