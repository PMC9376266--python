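"""Synthetic dataset generator with exact per-set uniqueness control.

Generates categorical datasets whose realized distinct-feature counts
match a target profile exactly, with optional *planted* common features
occurring at an exact frequency — the statistical knobs the recall
experiments depend on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import Dataset, DatasetSchema, Memory, SetSchema

__all__ = ["SynthSpec", "generate_synthetic", "ehos_like_spec", "save_spec"]

# Per-set distinct-feature profile of the reference 8-set, 700-memory
# heads-of-state dataset (first name, last name/title, century, state,
# position, dynasty/party, cause of death, reign years).
EHOS_SET_NAMES = (
    "first_name",
    "last_name_title",
    "century",
    "state",
    "position",
    "dynasty_party",
    "cause_of_death",
    "reign",
)
EHOS_TARGET_M = (328, 190, 29, 22, 24, 117, 9, 59)
EHOS_I_TOT = 700


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic dataset.

    ``planted_features`` is a list of ``(set_index, f_sim)`` pairs: in each
    named set, one feature is made to occur in exactly
    ``round(f_sim * i_tot)`` memories (the set's feature with index 0
    before first-appearance relabelling).
    """

    n_sets: int
    i_tot: int
    target_m: tuple[int, ...]
    planted_features: tuple[tuple[int, float], ...] = ()
    seed: int = 0
    set_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_sets < 2:
            raise ValueError("n_sets must be >= 2")
        if self.i_tot < 1:
            raise ValueError("i_tot must be >= 1")
        if len(self.target_m) != self.n_sets:
            raise ValueError("target_m length must equal n_sets")
        for m in self.target_m:
            if not 1 <= m <= self.i_tot:
                raise ValueError(f"target_m entry {m} outside [1, {self.i_tot}]")
        seen = set()
        for s, f_sim in self.planted_features:
            if not 0 <= s < self.n_sets:
                raise ValueError(f"planted set index {s} out of range")
            if s in seen:
                raise ValueError(f"set {s} planted twice")
            seen.add(s)
            if not 0 < f_sim <= 1:
                raise ValueError(f"f_sim {f_sim} outside (0, 1]")
            if round(f_sim * self.i_tot) < 1:
                raise ValueError(f"f_sim {f_sim} yields fewer than 1 occurrence")
        if self.set_names is not None and len(self.set_names) != self.n_sets:
            raise ValueError("set_names length must equal n_sets")

    def to_dict(self) -> dict:
        return {
            "n_sets": self.n_sets,
            "i_tot": self.i_tot,
            "target_m": list(self.target_m),
            "planted_features": [list(p) for p in self.planted_features],
            "seed": self.seed,
            "set_names": list(self.set_names) if self.set_names else None,
        }


def ehos_like_spec(seed: int, i_tot: int = EHOS_I_TOT) -> SynthSpec:
    """An 8-set spec with the reference uniqueness profile.

    For ``i_tot != 700`` the per-set counts are scaled proportionally
    (rounded, clipped to ``[1, i_tot]``) so smaller runs keep the same
    uniqueness shape.
    """
    if i_tot == EHOS_I_TOT:
        target = EHOS_TARGET_M
    else:
        target = tuple(
            int(min(i_tot, max(1, round(m * i_tot / EHOS_I_TOT)))) for m in EHOS_TARGET_M
        )
    return SynthSpec(
        n_sets=8,
        i_tot=i_tot,
        target_m=target,
        seed=seed,
        set_names=EHOS_SET_NAMES,
    )


def _generate_column(rng: np.random.Generator, i_tot: int, m: int, f_sim: float | None) -> np.ndarray:
    """One set's feature-index column with exactly ``m`` distinct values.

    Without planting: features ``0..m-1`` each appear at least once, the
    remaining rows draw uniformly, and the column is shuffled.  With
    planting, feature 0 is forced to occur in exactly
    ``round(f_sim * i_tot)`` rows while the others still realize the
    distinct count exactly.
    """
    if f_sim is None:
        col = np.concatenate(
            [np.arange(m, dtype=np.int64), rng.integers(0, m, size=i_tot - m)]
        )
    else:
        k = int(round(f_sim * i_tot))
        if m == 1:
            if k != i_tot:
                raise ValueError("planted set with target_m=1 requires f_sim=1")
            col = np.zeros(i_tot, dtype=np.int64)
        else:
            rest = i_tot - k
            if rest < m - 1:
                raise ValueError(
                    f"cannot realize {m} distinct features with a planted "
                    f"frequency of {k}/{i_tot}"
                )
            col = np.concatenate(
                [
                    np.zeros(k, dtype=np.int64),
                    np.arange(1, m, dtype=np.int64),
                    rng.integers(1, m, size=rest - (m - 1)),
                ]
            )
    return col[rng.permutation(i_tot)]


def generate_synthetic(spec: SynthSpec) -> Dataset:
    """Generate a dataset from ``spec``; a pure function of the spec.

    Columns are generated independently set by set (no cross-set
    correlation is modelled).  Feature indices are relabelled to
    first-appearance order so that CSV round-trips are the identity.
    """
    rng = np.random.default_rng(spec.seed)
    planted = dict(spec.planted_features)
    codes = np.empty((spec.i_tot, spec.n_sets), dtype=np.int64)
    for i in range(spec.n_sets):
        col = _generate_column(rng, spec.i_tot, spec.target_m[i], planted.get(i))
        # relabel to first-appearance order
        _, first_pos, inverse = np.unique(col, return_index=True, return_inverse=True)
        rank = np.argsort(np.argsort(first_pos))
        codes[:, i] = rank[inverse]

    names = spec.set_names or tuple(f"set{i}" for i in range(spec.n_sets))
    sets = tuple(
        SetSchema(
            name=names[i],
            features=tuple(f"{names[i]}_f{j}" for j in range(spec.target_m[i])),
        )
        for i in range(spec.n_sets)
    )
    schema = DatasetSchema(sets=sets)
    return Dataset(schema, [Memory(tuple(int(v) for v in row)) for row in codes])


def save_spec(spec: SynthSpec, path: str | Path) -> None:
    """Write the spec as a JSON sidecar next to a generated CSV."""
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n", encoding="utf-8")
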