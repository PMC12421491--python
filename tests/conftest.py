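import numpy as np
import pytest

from zwscan import ArtifactSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def six_pop_cohort():
    """Six populations of 9 males + 9 females with one artifact of each
    regime — the balanced design of the male-vs-female genome scan."""
    cfg = SimConfig(
        populations=[(f"pop{i}", 9, 9) for i in range(6)],
        L_auto=300,
        L_z=100,
        artifact_loci=[
            ArtifactSpec("5", 10662578, "split_call", coverage_multiplier=6.0),
            ArtifactSpec("5", 10700000, "het_call", coverage_multiplier=6.0),
        ],
        seed=42,
    )
    return (cfg,) + simulate_cohort(cfg)


@pytest.fixture(scope="session")
def twelve_twelve_pools():
    """Two populations of 12 males + 12 females each, with both artifact
    regimes planted — the sex-ratio subsampling design."""
    cfg = SimConfig(
        populations=[("Harja", 12, 12), ("Wytham", 12, 12)],
        L_auto=60,
        L_z=20,
        artifact_loci=[
            ArtifactSpec("5", 10662578, "split_call"),
            ArtifactSpec("5", 10700000, "het_call"),
        ],
        seed=7,
    )
    return (cfg,) + simulate_cohort(cfg)
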