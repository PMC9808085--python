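import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import omiqc as oq

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort reused across modules (120 metabolites, 90 proteins)."""
    params = oq.SimulationParams(n_metabolites=120, n_proteins=90, seed=11)
    metab, prot, metadata, truth = oq.generate_cohort(params)
    return params, metab, prot, metadata, truth


@pytest.fixture(scope="session")
def small_imputed(small_cohort):
    """Preprocessed (imputed) metabolome of the small cohort."""
    _, metab, _, metadata, truth = small_cohort
    filtered, _ = oq.filter_low_abundance(metab)
    return oq.impute_min_det(oq.glog_transform(filtered)), metadata, truth


def toy_matrix(values, stage="imputed", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return oq.OmicsMatrix(pd.DataFrame(values, index=features, columns=samples),
                          stage=stage)
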