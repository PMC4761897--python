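import numpy as np
import pytest

from hybridase.sim import PlantSpec, SimConfig, random_motif, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A 300-gene, 4-strain study with 10% cis genes, reused across tests."""
    cfg = SimConfig(n_genes=300, frac_cis=0.1, cis_log2_effect=1.0, seed=101)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def planted_study():
    """A study with one disrupted-site activator motif and one trans-active TF."""
    rng = np.random.default_rng(7)
    motifs = [random_motif(f"TF{i:02d}", 8, rng) for i in range(4)]
    plants = [
        PlantSpec(motifs[0], 40, disrupt_in_strain="S2", couple_cis_log2=1.0),
        PlantSpec(motifs[1], 40),
    ]
    cfg = SimConfig(n_genes=400, seed=23, tf_activities={"TF01": {"S3": 2.0}})
    study = simulate_study(cfg, plants)
    study.motif_models = motifs
    return study
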