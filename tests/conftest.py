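import pytest

from nagpipe.synthetic import SimulationConfig, simulate_cohort


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: small genome, short proteins, few patients."""
    defaults = dict(
        n_patients=60,
        n_genes=40,
        n_panel_genes=8,
        alteration_rate_background=0.08,
        alteration_rate_panel=(0.25, 0.75),
        beta_per_alteration=-0.2,
        baseline_hazard=0.4,
        censoring_rate=0.05,
        followup_horizon=5.0,
        n_signature_genes=8,
        signature_shift=1.2,
        noise_sd=0.5,
        n_immunogenic_patients=3,
        protein_length_range=(30, 60),
        seed=42,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort(small_config())
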