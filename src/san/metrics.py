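"""Evaluation surfaces: stratified hit rate, unique memory ratio, occurrences.

The hit-rate surface is stratified by the mean uniqueness factor of the
input sets of each recall trial; the unique memory ratio counts distinct
dataset memories (shown or not) recalled during one time step's full
evaluation; the occurrence matrix counts per-memory recalls per step.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import Dataset

__all__ = ["InputCombo", "enumerate_combos", "MetricsLog", "unique_memory_ratio"]


@dataclass(frozen=True)
class InputCombo:
    """A k-subset of sets used as recall input, with its mean U-factor."""

    set_indices: tuple[int, ...]
    u_avg: float


def enumerate_combos(n: int, k: int, u: np.ndarray) -> list[InputCombo]:
    """All C(n, k) input combinations, sorted ascending by mean U-factor
    (ties broken lexicographically by set indices)."""
    if not 0 < k <= n:
        raise ValueError(f"k={k} must satisfy 0 < k <= n={n}")
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError("u must have one entry per set")
    combos = [
        InputCombo(set_indices=c, u_avg=float(u[list(c)].mean()))
        for c in itertools.combinations(range(n), k)
    ]
    combos.sort(key=lambda ic: (ic.u_avg, ic.set_indices))
    return combos


class MetricsLog:
    """Accumulates trial results over a simulation run.

    A readout is credited to a dataset memory only on full n-feature
    equality; sentinel entries never match.
    """

    def __init__(self, combos: list[InputCombo], dataset: Dataset):
        self.combos = combos
        self.dataset = dataset
        # first occurrence wins if the dataset contains duplicate rows
        self._mem_index: dict[tuple[int, ...], int] = {}
        for i, m in enumerate(dataset.memories):
            self._mem_index.setdefault(m.feature_indices, i)
        self.hit_cells: dict[tuple[int, int], list[int]] = defaultdict(lambda: [0, 0])
        self.step_unique: dict[int, set[int]] = defaultdict(set)
        self.occurrences: Counter = Counter()  # (memory index, t) -> count
        self.eval_steps: list[int] = []
        self.prediction_log: list[dict] = []
        self.erasure_log: list[dict] = []

    # -- recording -----------------------------------------------------

    def record_trial(
        self, t: int, combo_id: int, queried: int, y: np.ndarray, hit: bool
    ) -> None:
        """Record one recall trial's outcome.

        ``queried`` is the index of the memory that was partially shown;
        ``y`` is the readout's feature-index vector.  If the readout
        equals *any* dataset memory, that memory's occurrence count at
        ``t`` is incremented and it joins step ``t``'s unique-recall set.
        """
        cell = self.hit_cells[(t, combo_id)]
        cell[1] += 1
        cell[0] += int(hit)
        if np.all(y >= 0):
            idx = self._mem_index.get(tuple(int(v) for v in y))
            if idx is not None:
                self.occurrences[(idx, t)] += 1
                self.step_unique[t].add(idx)

    def record_predictions(self, t: int, count: int) -> None:
        self.prediction_log.append({"t": t, "predictions": count})

    def record_erasure(self, t: int, neurons: np.ndarray, pre_sums: np.ndarray) -> None:
        self.erasure_log.append(
            {
                "t": t,
                "neurons": [int(q) for q in neurons],
                "pre_sums": [float(s) for s in pre_sums],
            }
        )

    # -- summaries -----------------------------------------------------

    def unique_memory_ratio(self, t: int) -> float:
        """Distinct dataset memories recalled at step ``t`` divided by the
        number of memories shown so far (may exceed 1)."""
        if t < 1:
            raise ValueError("t must be >= 1")
        return len(self.step_unique.get(t, ())) / t

    def total_predictions(self) -> int:
        return sum(e["predictions"] for e in self.prediction_log)

    def erasure_events(self) -> int:
        return len(self.erasure_log)

    def hit_rate_frame(self) -> pd.DataFrame:
        """Long-form hit surface: one row per (t, combo)."""
        rows = []
        for (t, cid), (hits, trials) in sorted(self.hit_cells.items()):
            combo = self.combos[cid]
            rows.append(
                {
                    "t": t,
                    "combo_id": cid,
                    "u_avg": combo.u_avg,
                    "set_indices": "|".join(map(str, combo.set_indices)),
                    "hits": hits,
                    "trials": trials,
                    "hit_rate": hits / trials if trials else np.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["t", "combo_id", "u_avg", "set_indices", "hits", "trials", "hit_rate"],
        )

    def umr_frame(self) -> pd.DataFrame:
        rows = [
            {
                "t": t,
                "unique_recalled": len(self.step_unique.get(t, ())),
                "shown": t,
                "umr": self.unique_memory_ratio(t),
            }
            for t in self.eval_steps
        ]
        return pd.DataFrame(rows, columns=["t", "unique_recalled", "shown", "umr"])

    def occurrences_frame(self) -> pd.DataFrame:
        rows = [
            {"t": t, "memory_index": idx, "count": c}
            for (idx, t), c in sorted(self.occurrences.items(), key=lambda kv: (kv[0][1], kv[0][0]))
        ]
        return pd.DataFrame(rows, columns=["t", "memory_index", "count"])

    def occurrence_matrix(self) -> np.ndarray:
        """Dense (I_tot, n_eval_steps) recall-count matrix, columns in
        ``eval_steps`` order."""
        mat = np.zeros((self.dataset.i_tot, len(self.eval_steps)), dtype=np.int64)
        col = {t: j for j, t in enumerate(self.eval_steps)}
        for (idx, t), c in self.occurrences.items():
            mat[idx, col[t]] = c
        return mat

    # -- persistence ---------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        """Emit hit_rate.csv, umr.csv, occurrences.csv, predictions.json,
        erasures.json under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.hit_rate_frame().to_csv(out / "hit_rate.csv", index=False)
        self.umr_frame().to_csv(out / "umr.csv", index=False)
        self.occurrences_frame().to_csv(out / "occurrences.csv", index=False)
        (out / "predictions.json").write_text(
            json.dumps(self.prediction_log, indent=2) + "\n", encoding="utf-8"
        )
        (out / "erasures.json").write_text(
            json.dumps(self.erasure_log, indent=2) + "\n", encoding="utf-8"
        )


def unique_memory_ratio(step_unique_set: set, t: int) -> float:
    """Functional form of the UMR: ``|unique recalled| / t``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return len(step_unique_set) / t
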