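import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circpred.features import encode
from circpred.sequence_io import ProteinRecord
from circpred.synthetic import SyntheticSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def separable_dataset():
    """Encoded synthetic dataset with strong compositional class separation."""
    pos, neg = generate(SyntheticSpec(n_pos=100, n_neg=100, effect=0.2, seed=11))
    X = np.array([encode(r).values for r in pos + neg])
    y = np.array([1] * len(pos) + [-1] * len(neg))
    return X, y


@pytest.fixture(scope="session")
def null_dataset():
    """Encoded synthetic dataset with identically distributed classes."""
    pos, neg = generate(SyntheticSpec(n_pos=100, n_neg=100, effect=0.0, seed=12))
    X = np.array([encode(r).values for r in pos + neg])
    y = np.array([1] * len(pos) + [-1] * len(neg))
    return X, y


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (header, sequence) pairs."""

    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


def record_of_length(n: int, ident: str = "r") -> ProteinRecord:
    seq = ("ACDEFGHIKLMNPQRSTVWY" * (n // 20 + 1))[:n]
    return ProteinRecord(id=ident, sequence=seq)
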