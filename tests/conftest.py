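import pytest
from hypothesis import HealthCheck, settings

from arbattery.synthetic_data import GeneratorConfig, generate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset: 300 chemicals, 12 clusters, short fingerprints."""
    cfg = GeneratorConfig(
        n_chemicals=300,
        n_clusters=12,
        agonist_cluster_fraction=0.2,
        fingerprint_length=128,
        # at 300 chemicals the paper-scale agonist prevalence would leave the
        # rare classes nearly empty; scale them up so every class is populated
        prevalence_agonist=0.05,
        prevalence_both=0.01,
    )
    return generate(cfg, seed=11)


@pytest.fixture(scope="session")
def small_summaries(small_dataset):
    """Per-mode model summaries over all 16,368 subset models of the small dataset."""
    from arbattery.pipeline import evaluate_dataset

    return {mode: evaluate_dataset(small_dataset, mode) for mode in ("agonist", "antagonist")}
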