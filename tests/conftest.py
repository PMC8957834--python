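import numpy as np
import pytest

from corepanel.vcf_io import GenotypeMatrix, Locus


def build_gm(calls, chroms=None, positions=None, samples=None):
    """GenotypeMatrix from a nested list of call states with auto metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chroms = chroms or ["1"] * m
    positions = positions or list(range(1, m + 1))
    loci = [
        Locus(str(c), int(p), f"{c}_{p}") for c, p in zip(chroms, positions)
    ]
    samples = samples or [f"S{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


@pytest.fixture
def gm_factory():
    return build_gm


class StubRng:
    """Deterministic stand-in for numpy Generator with injectable draws."""

    def __init__(self, randoms=(), integers=(), seed=0):
        self._randoms = list(randoms)
        self._integers = list(integers)
        self._rng = np.random.default_rng(seed)

    def random(self, *args, **kwargs):
        if self._randoms:
            return self._randoms.pop(0)
        return self._rng.random(*args, **kwargs)

    def integers(self, *args, **kwargs):
        if self._integers:
            return self._integers.pop(0)
        return self._rng.integers(*args, **kwargs)

    def choice(self, *args, **kwargs):
        return self._rng.choice(*args, **kwargs)

    def shuffle(self, x):
        return self._rng.shuffle(x)

    def binomial(self, *args, **kwargs):
        return self._rng.binomial(*args, **kwargs)


@pytest.fixture
def stub_rng():
    return StubRng
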