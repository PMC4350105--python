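import pytest

from ncmeth.sim import SimulationConfig, SpikeSpec, simulate_annotation, simulate_methylome


def tiny_spikes() -> list[SpikeSpec]:
    """One spike per pattern, mixing directions and couplings."""
    return [
        SpikeSpec("hyper", 1, coupling="silencing"),
        SpikeSpec("hypo", 2, coupling="activating"),
        SpikeSpec("hyper", 3, coupling="none"),
        SpikeSpec("hypo", 4, coupling="none"),
        SpikeSpec("hypo", 5, coupling="activating"),
    ]


def tiny_config(**overrides) -> SimulationConfig:
    """A seconds-scale cohort: 1 chromosome x 400 kb, 20 genes."""
    params = dict(
        n_chrom=1,
        chrom_length=400_000,
        n_coding=8,
        n_lncrna=8,
        n_mirna=4,
        n_tumor=12,
        n_normal=12,
        spikes=tiny_spikes(),
        seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale simulated cohort shared across tests."""
    config = SimulationConfig(seed=11)
    annotation = simulate_annotation(config)
    tracks, truth = simulate_methylome(annotation, config)
    return config, annotation, tracks, truth
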