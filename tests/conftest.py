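import numpy as np
import pytest

from tacitus.types import ExpressionMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(n_probes, n_samples, rng, prefix="p", sample_prefix="S",
                scale="log2_intensity"):
    values = rng.normal(7.0, 1.5, size=(n_probes, n_samples))
    return ExpressionMatrix(
        probe_ids=[f"{prefix}{i + 1}" for i in range(n_probes)],
        sample_ids=[f"{sample_prefix}{j + 1}" for j in range(n_samples)],
        values=values,
        scale=scale,
    )


_WORDS = ["lung", "cancer", "h460", "h125", "cell", "line", "non-small",
          "treated", "control", "tissue", "liver", "brain"]


def make_metadata(sample_ids, rng, n_attributes=3):
    attributes = [f"attr{k + 1}" for k in range(n_attributes)]
    table = {}
    for sid in sample_ids:
        table[sid] = {
            a: " ".join(rng.choice(_WORDS, size=rng.integers(1, 4)))
            for a in attributes
        }
    return SampleMetadata(list(sample_ids), attributes, table)


@pytest.fixture
def toy_matrix(rng):
    return make_matrix(10, 4, rng)


@pytest.fixture
def toy_metadata(toy_matrix, rng):
    return make_metadata(toy_matrix.sample_ids, rng)
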