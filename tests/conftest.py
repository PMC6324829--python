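"""Shared fixtures: random tiny pairs and random valid parameter sets."""

import numpy as np
import pytest

from jemge.evo_models import (
    EvoParams,
    IndelParams,
    LocalEquilibria,
    MarkParams,
    NucleotideDistribution,
)
from jemge.likelihood import HomologousPair, MarkTrack


def random_pair(rng: np.random.Generator, sA: int, sB: int, H: int = 1,
                identifier: str = "pair") -> HomologousPair:
    seqA = "".join(rng.choice(list("ACGT"), sA))
    seqB = "".join(rng.choice(list("ACGT"), sB))
    return HomologousPair(
        identifier, seqA, seqB,
        tuple(MarkTrack(h + 1, rng.integers(0, 2, sA)) for h in range(H)),
        tuple(MarkTrack(h + 1, rng.integers(0, 2, sB)) for h in range(H)),
        phi=LocalEquilibria(tuple(rng.uniform(0, 1, H)),
                            tuple(rng.uniform(0, 1, H))),
    )


def random_params(rng: np.random.Generator, H: int = 1) -> EvoParams:
    mu = rng.uniform(0.01, 1.0)
    lam = mu * rng.uniform(0.3, 0.99)
    freqs = rng.dirichlet([5.0] * 4)
    return EvoParams(
        nuc=NucleotideDistribution(*freqs),
        marks=tuple(MarkParams(h + 1, rng.uniform(0.05, 0.95),
                               rng.uniform(0.01, 2.0)) for h in range(H)),
        indel=IndelParams(lam, mu),
        s=rng.uniform(0.0, 1.5),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def pair_factory():
    return random_pair


@pytest.fixture
def params_factory():
    return random_params
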