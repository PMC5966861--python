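import numpy as np
import pytest

from svmeta import CallSet, SVCall


def dcall(id, chrom, start, end, support=5, sources=("X",), sample="s"):
    return SVCall.deletion(id, chrom, start, end, support=support,
                           sources=sources, sample=sample)


def icall(id, chrom, pos, length, support=5, sources=("X",), sample="s"):
    return SVCall.insertion(id, chrom, pos, length, support=support,
                            sources=sources, sample=sample)


def make_set(caller, *calls, sample="s"):
    return CallSet(sample, caller, tuple(calls))


def random_callset(rng, label, max_calls=30, span=5000, sample="s"):
    """A deliberately crowded random call set: many overlapping/ambiguous
    candidates, to stress one-to-one matching."""
    n = int(rng.integers(0, max_calls + 1))
    calls = []
    for i in range(n):
        chrom = str(rng.integers(1, 3))
        support = int(rng.integers(0, 30))
        if rng.random() < 0.5:
            start = int(rng.integers(1, span))
            length = int(rng.integers(50, 1500))
            calls.append(dcall(f"{label}{i}", chrom, start, start + length - 1,
                               support=support, sources=(label,), sample=sample))
        else:
            calls.append(icall(f"{label}{i}", chrom, int(rng.integers(1, span)),
                               int(rng.integers(50, 1500)), support=support,
                               sources=(label,), sample=sample))
    return CallSet(sample, label, tuple(calls))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
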