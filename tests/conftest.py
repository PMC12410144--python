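import numpy as np
import pytest

from survtopic.corpus import CountsCorpus, EventDescriptor


@pytest.fixture(scope="session")
def small_corpus() -> CountsCorpus:
    """A tiny deterministic corpus for structural tests."""
    rng = np.random.default_rng(42)
    n, d = 40, 6
    X = rng.integers(0, 5, size=(n, d))
    X[:, 0] += 1  # no zero rows
    vocab = [EventDescriptor(f"v{j // 2}", f"bin{j % 2 + 1}", j % 2 + 1) for j in range(d)]
    return CountsCorpus(
        X=X,
        vocab=vocab,
        times=rng.exponential(2.0, n) + 0.1,
        events=rng.integers(0, 2, n),
        subject_ids=np.arange(n),
    )


# deterministic hypothesis runs across environments
from hypothesis import settings as _settings

_settings.register_profile("deterministic", derandomize=True)
_settings.load_profile("deterministic")
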