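import numpy as np
import pytest

import extractopt as eo


@pytest.fixture(scope="session")
def table1():
    return eo.load_fixture("table1")


@pytest.fixture(scope="session")
def table5():
    return eo.load_fixture("table5")


@pytest.fixture(scope="session")
def fitted_models(table1):
    """One fitted quadratic per response of the 20-run study."""
    design, responses = table1
    return {
        name: eo.fit_quadratic(design, responses.column(name), name)
        for name in responses.names
    }


@pytest.fixture(scope="session")
def anova_reports(table1, fitted_models):
    design, responses = table1
    return {
        name: eo.anova(model, design, responses.column(name))
        for name, model in fitted_models.items()
    }


@pytest.fixture(scope="session")
def best_ann(table1):
    """Best-of-20 Levenberg-Marquardt MLP on the 20-run study (seed 0)."""
    design, responses = table1
    config = eo.TrainConfig(seed=0)
    model, history, _ = eo.train_best_of(design, responses, config, n_restarts=20)
    return model, history


def random_ccd_response(seed: int, k: int = 3, n_center: int = 4):
    """A small random CCD dataset for oracle comparisons."""
    rng = np.random.default_rng(seed)
    factors = tuple(
        eo.FactorSpec(f"f{i}", center=rng.uniform(-5, 5), step=rng.uniform(0.5, 3))
        for i in range(k)
    )
    design = eo.build_ccd(factors, n_center)
    y = rng.normal(size=design.n_runs)
    return design, y
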