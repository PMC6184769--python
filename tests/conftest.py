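import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reggae import ExpressionMatrix, RTICollection, SimulationConfig, simulate

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """5 genes x 6 samples (3 case / 3 control) with known structure."""
    rng = np.random.default_rng(7)
    values = rng.normal(0, 1, size=(5, 6))
    values[0, :3] += 3.0  # gA clearly up in case
    values[1, :3] -= 3.0  # gB clearly down
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC", "gD", "gE"],
        sample_ids=[f"s{i}" for i in range(1, 7)],
        values=values,
        groups={f"s{i}": ("case" if i <= 3 else "control") for i in range(1, 7)},
        case_group="case",
    )


@pytest.fixture
def small_rti() -> RTICollection:
    return RTICollection.from_pairs(
        [("TF1", "gA"), ("TF1", "gB"), ("TF2", "gA"), ("TF2", "gC"), ("TF3", "gD")]
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small planted-regulator dataset shared across tests."""
    config = SimulationConfig(
        n_genes=400, n_regulators=20, targets_per_regulator=10,
        n_case=8, n_control=8, beta=2.0, gamma=2.0, noise_sd=1.0, seed=11,
    )
    expr, rti, truth = simulate(config)
    return config, expr, rti, truth
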