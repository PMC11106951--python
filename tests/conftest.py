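import numpy as np
import pytest
from hypothesis import settings

import chromstate as cs

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> cs.SimulationConfig:
    """A compact study: 2 x 400 kb chromosomes, 30 genes."""
    return cs.SimulationConfig(seed=7, n_chroms=2, chrom_length=400_000,
                               n_genes=30)


@pytest.fixture(scope="session")
def small_study(small_config) -> cs.StudyBundle:
    return cs.simulate_study(small_config)


@pytest.fixture(scope="session")
def toy_model() -> cs.HMMModel:
    """A 2-state, 1-mark chain with well-separated emissions."""
    return cs.HMMModel(
        2,
        ["H3K4me3"],
        np.array([0.5, 0.5]),
        np.array([[0.9, 0.1], [0.1, 0.9]]),
        np.array([[0.8], [0.2]]),
    )


def random_hmm(rng: np.random.Generator, K: int, M: int) -> cs.HMMModel:
    """A random valid model for oracle comparisons."""
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    E = rng.uniform(0.05, 0.95, size=(K, M))
    marks = [f"m{i}" for i in range(M)]
    return cs.HMMModel(K, marks, pi, A, E)


def enumerate_loglik(model: cs.HMMModel, obs: np.ndarray) -> float:
    """Brute-force likelihood by summing over all K^T state paths.

    Per-bin emission probabilities are tabulated once; the enumeration itself
    touches every path explicitly.
    """
    import itertools

    from chromstate.hmm_segmentation import emission_prob

    T = len(obs)
    B = np.array(
        [
            [emission_prob(model.emissionprob[k], obs[t])
             for k in range(model.n_states)]
            for t in range(T)
        ]
    )
    total = 0.0
    for path in itertools.product(range(model.n_states), repeat=T):
        p = model.startprob[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= model.transmat[path[t - 1], path[t]] * B[t, path[t]]
        total += p
    return float(np.log(total)) if total > 0 else -np.inf
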