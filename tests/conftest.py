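import pytest

from micronet import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """One small, fully ground-truthed synthetic experiment shared by tests."""
    cfg = SimulationConfig(
        n_mrna=80,
        n_mirna=12,
        n_de_mrna=12,
        n_de_mirna=2,
        de_log2fc_range=(1.5, 2.0),
        n_targets_per_de_mirna=3,
        utr_length_range=(80, 200),
        rng_seed=42,
    )
    return cfg, simulate_experiment(cfg)
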