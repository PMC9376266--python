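from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from san import Dataset, DatasetSchema, Memory, SetSchema

# Table of per-set distinct-feature counts for the reference 8-set dataset.
REF_TARGET_M = (328, 190, 29, 22, 24, 117, 9, 59)
REF_U_FACTORS = (0.469, 0.271, 0.041, 0.031, 0.034, 0.167, 0.013, 0.084)
REF_I_TOT = 700


def make_schema(sizes: tuple[int, ...], names: tuple[str, ...] | None = None) -> DatasetSchema:
    names = names or tuple(f"s{i}" for i in range(len(sizes)))
    return DatasetSchema(
        sets=tuple(
            SetSchema(name=names[i], features=tuple(f"{names[i]}v{j}" for j in range(m)))
            for i, m in enumerate(sizes)
        )
    )


def make_dataset(codes) -> Dataset:
    """Dataset from a code matrix; schema sized to fit the max index per column."""
    codes = np.asarray(codes, dtype=np.int64)
    sizes = tuple(int(codes[:, i].max()) + 1 for i in range(codes.shape[1]))
    schema = make_schema(sizes)
    return Dataset(schema, [Memory(tuple(int(v) for v in row)) for row in codes])


def disjoint_dataset(n_memories: int, n_sets: int = 8) -> Dataset:
    """Pairwise feature-disjoint memories: memory i uses feature i everywhere."""
    codes = np.tile(np.arange(n_memories)[:, None], (1, n_sets))
    return make_dataset(codes)


def random_small_dataset(rng: np.random.Generator) -> Dataset:
    """A random instance with <= 4 sets and <= 12 memories (oracle scale)."""
    n_sets = int(rng.integers(2, 5))
    sizes = rng.integers(1, 5, size=n_sets)
    i_tot = int(rng.integers(1, 13))
    codes = np.column_stack([rng.integers(0, s, size=i_tot) for s in sizes])
    return make_dataset(codes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_set_schema() -> DatasetSchema:
    return make_schema((1, 1))


@pytest.fixture
def eight_set_memory_net():
    """A fresh network over an 8-set schema holding exactly one memory."""
    from san import associate, init_network

    schema = make_schema((3, 3, 3, 3, 3, 3, 3, 3))
    state = init_network(schema)
    m = Memory((0, 1, 2, 0, 1, 2, 0, 1))
    associate(state, m)
    return state, m
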