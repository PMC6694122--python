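import pytest

from scsomatic.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def clean_simulation(tmp_path_factory):
    """Zero-error, duplicate-free simulation: pileup must recover truth exactly."""
    cfg = SimulationConfig(
        seed=11,
        n_cells=800,
        error_rate=0.0,
        duplicate_fraction=0.0,
        inject_discordance=0.0,
        low_quality_fraction=0.0,
    )
    out = tmp_path_factory.mktemp("clean_sim")
    truth, paths = simulate(cfg, str(out))
    return truth, paths


@pytest.fixture(scope="session")
def noisy_simulation(tmp_path_factory):
    """Simulation with sequencing error, duplicates and quality-0 reads."""
    cfg = SimulationConfig(
        seed=23,
        n_cells=600,
        error_rate=0.005,
        duplicate_fraction=0.3,
        low_quality_fraction=0.05,
        untagged_fraction=0.05,
    )
    out = tmp_path_factory.mktemp("noisy_sim")
    truth, paths = simulate(cfg, str(out))
    return truth, paths
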