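import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_config():
    from fluxprot.synthetic import SimulationConfig

    return SimulationConfig(proteins_per_cluster=6, n_genes=500)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_sim_config):
    """A small noisy study bundle shared across tests (seed 7)."""
    from fluxprot.synthetic import simulate_study_bundle

    out = tmp_path_factory.mktemp("bundle")
    truth = simulate_study_bundle(small_sim_config, out, seed=7)
    return out, truth


@pytest.fixture(scope="session")
def noise_free_bundle(tmp_path_factory):
    """A noise-free bundle: planted kinetics must round-trip exactly."""
    from fluxprot.synthetic import SimulationConfig, simulate_study_bundle

    cfg = SimulationConfig(
        proteins_per_cluster=3,
        n_genes=200,
        envelope_noise_sd=0.0,
        body_water_sd=0.0,
        replicate_log_sd=0.05,
    )
    out = tmp_path_factory.mktemp("noise_free")
    truth = simulate_study_bundle(cfg, out, seed=11)
    return out, truth


@pytest.fixture()
def toy_peptide_kinetics():
    """Hand-built peptide kinetics exercising both roll-up filters."""
    rows = []

    def add(acc, pep, animal, fsr, limb="injured", stage="Differentiation"):
        rows.append(
            {
                "peptide": pep,
                "protein_accession": acc,
                "animal_id": animal,
                "limb": limb,
                "stage": stage,
                "fsr_pct_per_day": fsr,
            }
        )

    # PASS: 2 peptides in each of 2 animals
    add("PASS", "AAK", "a1", 2.0)
    add("PASS", "GGK", "a1", 4.0)
    add("PASS", "AAK", "a2", 3.0)
    add("PASS", "GGK", "a2", 5.0)
    # ONEPEP: a single peptide measurement everywhere -> peptide filter
    add("ONEPEP", "LLK", "a1", 6.0)
    add("ONEPEP", "LLK", "a2", 6.5)
    # ONEANIMAL: 2 peptides but only one animal -> animal filter
    add("ONEANIMAL", "VVK", "a1", 1.0)
    add("ONEANIMAL", "WWK", "a1", 2.0)
    return pd.DataFrame(rows)
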