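import pytest

from stepcue.families import ModelSpec, SupportBounds, sample


@pytest.fixture(scope="session")
def exp_steps_10k():
    """10^4 seeded draws from a truncated exponential, lam = 2."""
    model = ModelSpec("EXP", {"lam": 2.0})
    bounds = SupportBounds(0.01, 50.0)
    return sample(model, bounds, 10_000, seed=42), bounds


@pytest.fixture(scope="session")
def gse_steps_small():
    """Small (n=30) sample from the constrained GSE, for oracle comparisons."""
    model = ModelSpec("GSE_CONSTRAINED", {"lam": 1.5, "D": 1.6})
    bounds = SupportBounds(0.05, 12.0)
    return sample(model, bounds, 30, seed=7), bounds
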