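"""Lifelong-learning simulation loop.

One memory is introduced per time step; after each step (optionally every
j-th step) the network's recall is evaluated for every memory shown so
far under every k-of-n input combination, and the metrics log is updated.
Evaluation never mutates the stored weights.

Two evaluation paths exist: a vectorized one that computes all of a
step's first-pass output fields as one gather-sum and falls back to the
scalar recall only for trials with ties, and a trial-by-trial reference.
Both consume the tie-breaking random stream identically (trials without
ties draw nothing), so they agree exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .behaviors import BehaviorConfig, apply_erase, apply_forgetting, apply_predictive
from .metrics import InputCombo, MetricsLog, enumerate_combos
from .network import NONE, NetworkState, associate, init_network, recall
from .schema import Dataset, dataset_u_factors
from .synth import SynthSpec, generate_synthetic

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "generate_sequence",
    "evaluate_step",
    "run_simulation",
]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    dataset: Dataset | None = None
    synth_spec: SynthSpec | None = None
    v_on: float = 0.001
    e_mag: float = 1.0
    k_input: int | None = None  # defaults to n // 2
    behaviors: BehaviorConfig = field(default_factory=BehaviorConfig)
    seed_sequence: int = 0
    seed_ties: int = 0
    eval_every: int = 1
    batched: bool = True

    def validate(self, n_sets: int) -> None:
        if (self.dataset is None) == (self.synth_spec is None):
            raise ValueError("exactly one of dataset / synth_spec must be given")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")
        k = self.k_input if self.k_input is not None else n_sets // 2
        if not 1 <= k < n_sets:
            raise ValueError(f"k_input={k} must satisfy 1 <= k < n={n_sets}")


@dataclass
class SimulationResult:
    dataset: Dataset
    combos: list[InputCombo]
    log: MetricsLog
    state: NetworkState
    sequence: np.ndarray
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.log.write(out)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2) + "\n", encoding="utf-8"
        )


def generate_sequence(dataset: Dataset, seed: int) -> np.ndarray:
    """Uniformly random presentation order of all memories (each shown
    exactly once), deterministic given ``seed``."""
    return np.random.default_rng(seed).permutation(dataset.i_tot)


def evaluate_step(
    state: NetworkState,
    dataset: Dataset,
    shown: Sequence[int],
    combos: list[InputCombo],
    rng: np.random.Generator,
    log: MetricsLog,
    t: int,
    batched: bool = True,
) -> MetricsLog:
    """Run all ``len(shown) * len(combos)`` recall trials for step ``t``.

    Trial order is: combos in log order, shown memories in presentation
    order within each combo.  Weights are read-only throughout.
    """
    shown = np.asarray(shown, dtype=np.int64)
    codes = dataset.codes
    neuron_ids = state.offsets[:-1][None, :] + codes  # (I_tot, n)
    offsets = state.offsets
    n = dataset.schema.n
    e_mag = state.e_mag
    weights = state.weights
    log.eval_steps.append(t)

    for combo_id, combo in enumerate(combos):
        sets = np.asarray(combo.set_indices, dtype=np.int64)
        if not batched:
            for mem_idx in shown:
                ro, hit = recall(state, dataset.memories[mem_idx], combo.set_indices, rng)
                log.record_trial(t, combo_id, int(mem_idx), ro.y, hit)
            continue

        clamp = neuron_ids[shown][:, sets]  # (T, k), ascending within a row
        n_trials = clamp.shape[0]
        # first synchronous pass for every trial at once
        f_all = weights[clamp].sum(axis=1) * e_mag
        f_all[np.arange(n_trials)[:, None], clamp] += e_mag

        y_all = np.empty((n_trials, n), dtype=np.int64)
        has_tie = np.zeros(n_trials, dtype=bool)
        for s in range(n):
            seg = f_all[:, offsets[s] : offsets[s + 1]]
            arg = seg.argmax(axis=1)
            mx = seg[np.arange(n_trials), arg]
            dead = mx <= 0.0
            near = (seg >= (mx * (1.0 - 1e-12))[:, None]).sum(axis=1)
            has_tie |= (~dead) & (near > 1)
            y_all[:, s] = np.where(dead, NONE, arg)

        target = codes[shown]
        for r in range(n_trials):
            mem_idx = int(shown[r])
            if has_tie[r]:
                ro, hit = recall(state, dataset.memories[mem_idx], combo.set_indices, rng)
                y, ok = ro.y, hit
            else:
                y = y_all[r]
                ok = bool(np.array_equal(y, target[r]))
            log.record_trial(t, combo_id, mem_idx, y, ok)
    return log


def run_simulation(
    cfg: SimulationConfig,
    progress: Callable[[int, int], None] | None = None,
) -> SimulationResult:
    """The five-phase loop: setup once, then per step association (with
    optional forgetting / prediction / erasure) followed by a full recall
    evaluation and metric bookkeeping."""
    if (cfg.dataset is None) == (cfg.synth_spec is None):
        raise ValueError("exactly one of dataset / synth_spec must be given")
    dataset = cfg.dataset if cfg.dataset is not None else generate_synthetic(cfg.synth_spec)
    n = dataset.schema.n
    cfg.validate(n)
    k = cfg.k_input if cfg.k_input is not None else n // 2

    u = dataset_u_factors(dataset)
    combos = enumerate_combos(n, k, u)
    state = init_network(dataset.schema, v_on=cfg.v_on, e_mag=cfg.e_mag)
    sequence = generate_sequence(dataset, cfg.seed_sequence)
    rng_ties = np.random.default_rng(cfg.seed_ties)
    log = MetricsLog(combos, dataset)
    b = cfg.behaviors

    for t in range(1, dataset.i_tot + 1):
        mem_idx = int(sequence[t - 1])
        m = dataset.memories[mem_idx]
        try:
            if b.forgetting_enabled:
                apply_forgetting(state, b.d_rate)
            associate(state, m)
            if b.predictive_enabled:
                count = apply_predictive(state, m, b.p_th * state.v_on)
                log.record_predictions(t, count)
            if b.erase_enabled:
                _, erased, pre_sums = apply_erase(state, b.r_th * state.v_on)
                if erased.size:
                    log.record_erasure(t, erased, pre_sums)
            if t % cfg.eval_every == 0:
                evaluate_step(
                    state, dataset, sequence[:t], combos, rng_ties, log, t, cfg.batched
                )
        except Exception as exc:
            raise RuntimeError(f"simulation failed at time step {t}") from exc
        if progress is not None:
            progress(t, dataset.i_tot)

    manifest = {
        "v_on": cfg.v_on,
        "e_mag": cfg.e_mag,
        "n_sets": n,
        "k_input": k,
        "i_tot": dataset.i_tot,
        "eval_every": cfg.eval_every,
        "seed_sequence": cfg.seed_sequence,
        "seed_ties": cfg.seed_ties,
        "behaviors": b.to_dict(),
        "synth_spec": cfg.synth_spec.to_dict() if cfg.synth_spec else None,
        "sequence": [int(i) for i in sequence],
    }
    return SimulationResult(
        dataset=dataset,
        combos=combos,
        log=log,
        state=state,
        sequence=sequence,
        manifest=manifest,
    )
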