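"""Categorical data model: sets, features, memories, and dataset statistics.

A dataset is a table of *memories* (rows); each column is a *set* of
categorical information, and each distinct value within a set is a
*feature*.  Features are identified by integer indices assigned in order
of first appearance in the file, which makes loading deterministic and
CSV round-trips lossless.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DatasetError",
    "SetSchema",
    "DatasetSchema",
    "Memory",
    "Dataset",
    "load_dataset",
    "save_dataset",
    "dataset_u_factors",
    "mean_hamming",
]


class DatasetError(ValueError):
    """Raised for malformed dataset files or inconsistent dataset objects."""


@dataclass(frozen=True)
class SetSchema:
    """One category of information and its ordered feature vocabulary."""

    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise DatasetError(f"set {self.name!r} has no features")
        if len(set(self.features)) != len(self.features):
            raise DatasetError(f"set {self.name!r} has duplicate feature labels")
        object.__setattr__(self, "_index", {f: i for i, f in enumerate(self.features)})

    @property
    def size(self) -> int:
        """Number of distinct features M_i."""
        return len(self.features)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise DatasetError(f"unknown feature {label!r} in set {self.name!r}") from None


@dataclass(frozen=True)
class DatasetSchema:
    """Ordered collection of sets; fixes the neuron layout of the network."""

    sets: tuple[SetSchema, ...]

    def __post_init__(self) -> None:
        if len(self.sets) < 2:
            raise DatasetError("a dataset schema needs at least 2 sets")
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise DatasetError("set names must be unique")

    @property
    def n(self) -> int:
        """Number of sets."""
        return len(self.sets)

    @property
    def set_sizes(self) -> np.ndarray:
        """Per-set distinct-feature counts M_i, shape ``(n,)``."""
        return np.array([s.size for s in self.sets], dtype=np.int64)

    @property
    def neuron_count(self) -> int:
        """Total neuron count N = sum of M_i (one neuron per feature)."""
        return int(self.set_sizes.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative neuron offsets, shape ``(n + 1,)``; set i owns
        neurons ``offsets[i]:offsets[i+1]``."""
        return np.concatenate([[0], np.cumsum(self.set_sizes)])

    @property
    def set_of_neuron(self) -> np.ndarray:
        """Map neuron id -> set index, shape ``(N,)``."""
        return np.repeat(np.arange(self.n), self.set_sizes)

    def set_index(self, name: str) -> int:
        for i, s in enumerate(self.sets):
            if s.name == name:
                return i
        raise DatasetError(f"unknown set {name!r}")


@dataclass(frozen=True)
class Memory:
    """One feature per set, by index."""

    feature_indices: tuple[int, ...]

    def validate(self, schema: DatasetSchema) -> None:
        if len(self.feature_indices) != schema.n:
            raise DatasetError(
                f"memory has {len(self.feature_indices)} entries, schema has {schema.n} sets"
            )
        for s, j in zip(schema.sets, self.feature_indices):
            if not 0 <= j < s.size:
                raise DatasetError(f"feature index {j} out of range for set {s.name!r}")

    def labels(self, schema: DatasetSchema) -> tuple[str, ...]:
        return tuple(s.features[j] for s, j in zip(schema.sets, self.feature_indices))


class Dataset:
    """A schema plus an ordered list of memories."""

    def __init__(self, schema: DatasetSchema, memories: Sequence[Memory]):
        if len(memories) < 1:
            raise DatasetError("a dataset needs at least one memory")
        for m in memories:
            m.validate(schema)
        self.schema = schema
        self.memories: tuple[Memory, ...] = tuple(memories)
        self._codes = np.array(
            [m.feature_indices for m in self.memories], dtype=np.int64
        )

    @property
    def i_tot(self) -> int:
        """Number of memories."""
        return len(self.memories)

    @property
    def codes(self) -> np.ndarray:
        """Feature-index matrix, shape ``(I_tot, n)`` (read-only view)."""
        v = self._codes.view()
        v.flags.writeable = False
        return v

    def __len__(self) -> int:
        return self.i_tot

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.schema == other.schema and self.memories == other.memories


def load_dataset(path: str | Path, column_order: Iterable[str] | None = None) -> Dataset:
    """Read a dataset CSV (UTF-8, one header row, one memory per row).

    Feature indices are assigned per column in order of first appearance.
    Cell values are stripped of surrounding whitespace and compared
    case-sensitively.  ``column_order`` optionally reorders the columns by
    header name before sets are built.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise DatasetError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DatasetError(f"{path}: duplicate header names {dupes}")
    if len(header) < 2:
        raise DatasetError(f"{path}: need at least 2 columns, found {len(header)}")

    if column_order is not None:
        order = list(column_order)
        if sorted(order) != sorted(header):
            raise DatasetError(
                f"{path}: column_order {order} does not match header {header}"
            )
        col_idx = [header.index(name) for name in order]
        header = order
    else:
        col_idx = list(range(len(header)))

    n = len(header)
    vocab: list[dict[str, int]] = [dict() for _ in range(n)]
    mem_rows: list[tuple[int, ...]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(rows[0]):
            raise DatasetError(f"{path}: row {r} has {len(row)} cells, expected {len(rows[0])}")
        indices = []
        for c, src in enumerate(col_idx):
            value = row[src].strip()
            if not value:
                raise DatasetError(f"{path}: row {r}, column {header[c]!r}: empty value")
            d = vocab[c]
            if value not in d:
                d[value] = len(d)
            indices.append(d[value])
        mem_rows.append(tuple(indices))
    if not mem_rows:
        raise DatasetError(f"{path}: no data rows")

    sets = tuple(
        SetSchema(name=header[c], features=tuple(vocab[c])) for c in range(n)
    )
    schema = DatasetSchema(sets=sets)
    return Dataset(schema, [Memory(ix) for ix in mem_rows])


def save_dataset(d: Dataset, path: str | Path) -> None:
    """Write a dataset back to CSV (inverse of :func:`load_dataset`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([s.name for s in d.schema.sets])
        for m in d.memories:
            writer.writerow(m.labels(d.schema))


def dataset_u_factors(d: Dataset) -> np.ndarray:
    """Per-set uniqueness factors U_i = M_i / I_tot, shape ``(n,)``."""
    return d.schema.set_sizes / float(d.i_tot)


def mean_hamming(d: Dataset) -> float:
    """Mean number of differing sets over all unordered memory pairs.

    Computed per set from feature frequencies (O(I*n)) rather than over
    all pairs explicitly.
    """
    if d.i_tot < 2:
        raise DatasetError("mean_hamming needs at least 2 memories")
    codes = d.codes
    n_pairs = d.i_tot * (d.i_tot - 1) / 2.0
    equal_pairs = 0.0
    for i in range(d.schema.n):
        counts = np.bincount(codes[:, i])
        equal_pairs += float((counts * (counts - 1) // 2).sum())
    return d.schema.n - equal_pairs / n_pairs
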