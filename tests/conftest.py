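import numpy as np
import pandas as pd
import pytest

from spatialcv import SampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample_set(coords, response, covariates=None, qc=None,
                    allow_duplicate_coordinates=False) -> SampleSet:
    coords = np.asarray(coords, dtype=float)
    frame = pd.DataFrame({
        "id": np.arange(len(coords)),
        "x_km": coords[:, 0],
        "y_km": coords[:, 1],
        "response": np.asarray(response, dtype=float),
    })
    for name, vals in (covariates or {}).items():
        frame[name] = vals
    qc_columns = ()
    if qc:
        for name, vals in qc.items():
            frame[name] = vals
        qc_columns = tuple(qc)
    return SampleSet(frame, qc_columns=qc_columns,
                     allow_duplicate_coordinates=allow_duplicate_coordinates)


@pytest.fixture
def toy_sample_set(rng):
    """20 scattered points with one informative covariate."""
    coords = rng.uniform(0, 100, size=(20, 2))
    cov = rng.normal(size=20)
    return make_sample_set(coords, response=2.0 * cov + rng.normal(0, 0.1, 20),
                           covariates={"cov1": cov})
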