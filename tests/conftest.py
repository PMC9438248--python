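import numpy as np
import pytest

from mirth import RawDataset, SimulationConfig, simulate


@pytest.fixture
def tiny_batch() -> RawDataset:
    """3 samples x 2 features with one censored cell."""
    values = np.array([[5.0, 1.0], [3.0, np.nan], [8.0, 2.0]])
    censored = np.array([[False, False], [False, True], [False, False]])
    return RawDataset("b1", ["s1", "s2", "s3"], ["lactate", "glucose"], values, censored)


@pytest.fixture
def three_batches():
    """Three overlapping rank-2 batches with mild noise and light censoring."""
    cfg = SimulationConfig(n_batches=3, samples_per_batch=16, n_features=24,
                           measured_fraction=0.75, true_rank=2, noise_sd=0.05,
                           censor_quantile=0.05, seed=12)
    datasets, truth = simulate(cfg)
    return datasets, truth


def random_raw(rng: np.random.Generator, n: int = 8, p: int = 5,
               censor_frac: float = 0.0, batch_id: str = "r") -> RawDataset:
    """Helper: random positive batch with optional random censoring."""
    values = rng.lognormal(0.0, 1.0, size=(n, p))
    censored = rng.random((n, p)) < censor_frac
    # keep at least one uncensored entry per column so ranks stay informative
    for j in range(p):
        if censored[:, j].all():
            censored[rng.integers(n), j] = False
    vals = np.where(censored, np.nan, values)
    return RawDataset(batch_id, [f"s{i}" for i in range(n)],
                      [f"f{j}" for j in range(p)], vals, censored)
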