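"""Segmented attractor network: weight grid, Hebbian association, recall.

Neurons are features laid out set by set along one axis; the recurrent
weight grid is indexed ``(pre-synaptic, post-synaptic)`` and keeps
identically-zero blocks between features of the same set (and on the
self diagonal).  Association programs all cross-set weight pairs of a
memory's features to ``v_on``; recall clamps external input on a subset
of the memory's features, computes one synchronous output pass
``f = E + W^T E``, and resolves per-set ties by iteratively clamping a
randomly chosen tied feature and recomputing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .schema import DatasetSchema, Memory

__all__ = [
    "NONE",
    "TIE_RTOL",
    "NetworkState",
    "ActivationState",
    "Readout",
    "init_network",
    "compute_outputs",
    "associate",
    "readout",
    "recall",
]

#: Sentinel readout index for a set whose outputs are all zero.
NONE = -1

#: Relative tolerance for treating two outputs as tied.  True ties come
#: from identical sums of identical weight values and stay bit-equal in
#: practice; the tolerance only guards accumulated floating error.
TIE_RTOL = 1e-12

_PENDING = -2  # internal marker for a set awaiting tie resolution


class NetworkState:
    """Weight grid plus layout metadata.  Mutated in place by learning ops."""

    __slots__ = ("schema", "v_on", "e_mag", "weights", "_offsets", "_set_of")

    def __init__(
        self,
        schema: DatasetSchema,
        v_on: float = 0.001,
        e_mag: float = 1.0,
        weights: np.ndarray | None = None,
    ):
        if v_on <= 0:
            raise ValueError("v_on must be positive")
        if e_mag <= 0:
            raise ValueError("e_mag must be positive")
        self.schema = schema
        self.v_on = float(v_on)
        self.e_mag = float(e_mag)
        n_neurons = schema.neuron_count
        if weights is None:
            weights = np.zeros((n_neurons, n_neurons))
        elif weights.shape != (n_neurons, n_neurons):
            raise ValueError("weight array shape does not match schema")
        self.weights = weights
        self._offsets = schema.offsets
        self._set_of = schema.set_of_neuron

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def offsets(self) -> np.ndarray:
        return self._offsets

    @property
    def set_of(self) -> np.ndarray:
        return self._set_of

    def memory_neurons(self, m: Memory) -> np.ndarray:
        """Neuron ids of a memory's features, in set order (ascending)."""
        return self._offsets[:-1] + np.asarray(m.feature_indices, dtype=np.int64)

    def copy(self) -> "NetworkState":
        return NetworkState(self.schema, self.v_on, self.e_mag, self.weights.copy())

    def allowed_weight_count(self) -> int:
        """Number of directed weights not forced to zero: N^2 - sum M_i^2."""
        sizes = self.schema.set_sizes
        return int(self.n_neurons**2 - (sizes**2).sum())


def init_network(schema: DatasetSchema, v_on: float = 0.001, e_mag: float = 1.0) -> NetworkState:
    """A fresh all-zero network for ``schema``."""
    return NetworkState(schema, v_on=v_on, e_mag=e_mag)


@dataclass(frozen=True)
class ActivationState:
    """External input vector and the resulting neuron outputs."""

    e: np.ndarray
    f: np.ndarray


def compute_outputs(state: NetworkState, e: np.ndarray, passes: int = 1) -> ActivationState:
    """One (or more) synchronous output passes ``f = E + W^T f_prev``.

    ``f_prev`` starts at ``E``; with the default single pass this is
    ``f = E + W^T E``.  Entries of ``e`` must be 0 or ``e_mag``.
    """
    e = np.asarray(e, dtype=float)
    if e.shape != (state.n_neurons,):
        raise ValueError(f"expected input of shape ({state.n_neurons},), got {e.shape}")
    if not np.all((e == 0.0) | (e == state.e_mag)):
        raise ValueError("external input entries must be 0 or e_mag")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    f = e.copy()
    for _ in range(passes):
        f = e + state.weights.T @ f
    return ActivationState(e=e, f=f)


def associate(state: NetworkState, m: Memory) -> NetworkState:
    """Program all ordered cross-set weight pairs among ``m``'s features
    to ``v_on`` (unconditionally, restoring any decayed value)."""
    m.validate(state.schema)
    ids = state.memory_neurons(m)
    state.weights[np.ix_(ids, ids)] = state.v_on
    state.weights[ids, ids] = 0.0  # one feature per set: only self-pairs are intra-set
    return state


@dataclass(frozen=True)
class Readout:
    """Per-set winner indices; ``NONE`` marks an all-zero set, and
    ``tied_sets`` lists sets whose maximum was not unique."""

    y: np.ndarray
    tied_sets: tuple[int, ...] = ()

    def feature_indices(self) -> tuple[int, ...]:
        return tuple(int(v) for v in self.y)


def _analyze(f: np.ndarray, offsets: np.ndarray):
    """Per-set winners from an output vector.

    Returns ``(y, tied_sets, first_tie_candidates)`` where ``y`` holds
    local feature indices (``NONE`` for all-zero sets, ``_PENDING`` for
    tied sets) and ``first_tie_candidates`` are the global neuron ids
    tied for the maximum in the first tied set (schema order).
    """
    n = len(offsets) - 1
    y = np.empty(n, dtype=np.int64)
    tied: list[int] = []
    first_candidates: np.ndarray | None = None
    for s in range(n):
        lo, hi = offsets[s], offsets[s + 1]
        seg = f[lo:hi]
        j = int(seg.argmax())
        mx = seg[j]
        if mx <= 0.0:
            y[s] = NONE
            continue
        near = np.flatnonzero(seg >= mx - TIE_RTOL * mx)
        if near.size == 1:
            y[s] = j
        else:
            y[s] = _PENDING
            tied.append(s)
            if first_candidates is None:
                first_candidates = near + lo
    return y, tuple(tied), first_candidates


def readout(state: NetworkState, activations: ActivationState) -> Readout:
    """Winner-per-set readout of an activation state (ties signalled,
    not resolved)."""
    y, tied, _ = _analyze(activations.f, state.offsets)
    return Readout(y=y, tied_sets=tied)


def recall(
    state: NetworkState,
    m: Memory,
    input_sets: Iterable[int],
    rng: np.random.Generator | None = None,
) -> tuple[Readout, bool]:
    """Pattern completion for ``m`` clamped on ``input_sets``.

    Ties are resolved one set at a time (first tied set in schema order):
    a uniformly random tied feature receives external input, which then
    persists, and outputs are recomputed.  A hit requires the readout to
    reproduce all of ``m``'s features exactly; any all-zero set counts as
    a miss.  The stored weights are never modified.
    """
    m.validate(state.schema)
    sets = sorted(set(int(s) for s in input_sets))
    if not sets:
        raise ValueError("input_sets must be non-empty")
    if sets[0] < 0 or sets[-1] >= state.schema.n:
        raise ValueError("input_sets out of range")
    if rng is None:
        rng = np.random.default_rng()

    ids_m = state.memory_neurons(m)
    clamped = [int(ids_m[s]) for s in sets]
    e_mag, weights, offsets = state.e_mag, state.weights, state.offsets

    e = np.zeros(state.n_neurons)
    e[clamped] = e_mag
    clamped_mask = np.zeros(state.n_neurons, dtype=bool)
    clamped_mask[clamped] = True
    # Feedback row-sum maintained incrementally in clamp order, so the
    # first pass is bit-identical to the batched evaluator's gather-sum.
    row_sum = weights[clamped].sum(axis=0)

    for _ in range(state.n_neurons + 1):
        f = row_sum * e_mag
        f[clamped] += e_mag
        y, tied, candidates = _analyze(f, offsets)
        if not tied:
            target = np.asarray(m.feature_indices, dtype=np.int64)
            hit = bool(np.array_equal(y, target))
            return Readout(y=y, tied_sets=()), hit
        # A clamped neuron always beats unclamped ones while fewer than
        # 1/v_on neurons are active, so this filter is a no-op in the
        # trusted regime; it guarantees progress regardless.
        candidates = candidates[~clamped_mask[candidates]]
        if candidates.size == 0:  # pragma: no cover
            raise RuntimeError("tie among clamped neurons; outside trusted regime")
        pick = int(candidates[rng.integers(len(candidates))])
        e[pick] = e_mag
        clamped.append(pick)
        clamped_mask[pick] = True
        row_sum = row_sum + weights[pick]
    raise RuntimeError("tie resolution failed to terminate")  # pragma: no cover
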