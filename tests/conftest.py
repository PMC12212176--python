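import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from sleepfactor.rasch import PcmItem, pcm_probability
from sleepfactor.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort (seed fixed)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def complete_cohort():
    """A cohort with no attrition or missingness, n = 300."""
    return generate_cohort(
        GeneratorConfig(
            n_patients=300, n_questionnaire_complete=300, n_biomarker_complete=300, seed=7
        )
    )


def sample_pcm_scores(beta: np.ndarray, items, rng: np.random.Generator) -> np.ndarray:
    """Category scores 0..m drawn from the partial credit model."""
    cols = []
    for it in items:
        p = pcm_probability(beta, it)
        u = rng.random(beta.shape[0])
        cols.append((np.cumsum(p, axis=-1) < u[:, None]).sum(axis=1))
    return np.column_stack(cols)


def make_items(rng: np.random.Generator, k: int = 6, m: int = 4) -> list[PcmItem]:
    """K items with mean-zero locations and ordered jittered thresholds."""
    deltas = np.linspace(-1.0, 1.0, k)
    items = []
    for j in range(k):
        tau = np.linspace(-1.2, 1.2, m) + rng.normal(0, 0.15, m)
        tau = np.sort(tau)
        items.append(PcmItem(j, m, float(deltas[j]), tau - tau.mean()))
    return items
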