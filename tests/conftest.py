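import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from merostab import (
    QuadraticSurfaceRegressor,
    SynthConfig,
    cross_validate_poly,
    fit_ols,
    generate,
    load_table1,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def fitted_model(table1):
    return fit_ols(table1)


@pytest.fixture(scope="session")
def poly_cv(table1):
    return cross_validate_poly(table1)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Exact quadratic-surface data: the model class contains the truth."""
    dataset, truth = generate(SynthConfig(noise_cv=0.0))
    return dataset, truth


@pytest.fixture
def constant_model():
    """A degenerate surface predicting 0.8 remaining everywhere."""
    return QuadraticSurfaceRegressor.from_dict(
        {
            "denominator_convention": "population",
            "coefficients": [0.8, 0, 0, 0, 0, 0],
            "coef_covariance": np.zeros((6, 6)).tolist(),
            "residual_variance": 0.0,
            "df_residual": 10,
            "f_statistic": 0.0,
            "f_pvalue": 1.0,
            "r_squared": 1.0,
            "n_obs": 16,
            "standardizer_mean": [100.0, 10.0],
            "standardizer_scale": [50.0, 5.0],
            "time_range": [0.0, 364.0],
            "conc_range": [0.3, 86.9],
        }
    )
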