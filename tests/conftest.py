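import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def write_fasta(tmp_path):
    """Write (header, sequence) pairs to a FASTA file and return its path."""

    def _write(entries, name="input.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


def random_counts(rng, families, max_count=50):
    """Random codon counts over the given synonymous families."""
    from codonatlas.genetic_code import AA_TO_CODONS
    from codonatlas.sequence_io import CodonCounts

    counts = {}
    for aa in families:
        for codon in AA_TO_CODONS[aa]:
            counts[codon] = int(rng.integers(0, max_count))
    total = sum(counts.values())
    return CodonCounts(counts=counts, total=total)
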